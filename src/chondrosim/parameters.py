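"""Model parameters for the cartilage impact-response model.

All kinetic constants live in a single frozen dataclass so that every part of
the code (solver, experiments, CLI) draws its defaults from one place.  The
default values are the published calibration for the chondrocyte signalling
network: diffusion and decay of the four chemical species (ROS ``R``, DAMPs
``M``, pro-inflammatory cytokines ``F``, erythropoietin ``P``), per-cell
production rates, Hill half-saturations, cell-state transition rates, the
EPO threshold ``P_c`` above which inflammatory signalling is switched off,
and the constants of the strain-to-necrosis map.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic constants of the chemical/cellular cartilage model.

    Units: diffusion coefficients ``K_*`` in cm^2/day; decay and transition
    rates in 1/day; production coefficients ``sigma_*`` in
    nM*cm^3/(day*cells) (``sigma_U`` in nM*cm^3/(day*mg)); half-saturations
    and ``P_c`` in nM; ``tau_1``/``tau_2`` in days; strain in percent.
    """

    # chemical diffusion, cm^2/day
    K_R: float = 0.1
    K_M: float = 0.05
    K_F: float = 0.05
    K_P: float = 0.005
    # chemical decay, 1/day
    delta_R: float = 60.0
    delta_M: float = 0.5545
    delta_F: float = 0.1664
    delta_P: float = 3.326
    # ECM degradation rate, 1/day
    delta_U: float = 0.0193
    # per-cell chemical production, nM*cm^3/(day*cells)
    sigma_R: float = 0.0024
    sigma_M: float = 5.17e-7
    sigma_F: float = 2.35e-7
    sigma_P: float = 4.2e-5
    # ECM-to-DAMP production, nM*cm^3/(day*mg)
    sigma_U: float = 0.0154
    # half-saturation constants, nM
    Lambda: float = 0.5
    lambda_R: float = 5.0
    lambda_M: float = 0.5
    lambda_F: float = 0.5
    lambda_P: float = 0.5
    # cell-state transition rates, 1/day
    alpha_1: float = 1.0
    alpha_2: float = 1.0
    beta_11: float = 100.0
    beta_12: float = 50.0
    beta_13: float = 10.0
    kappa_1: float = 10.0
    kappa_2: float = 10.0
    # EPO threshold, nM
    P_c: float = 1.0
    # death / decay rates, 1/day
    mu_ST: float = 0.5
    mu_SA: float = 0.1
    mu_DN: float = 0.05
    # state-age switch centres, days
    tau_1: float = 0.5
    tau_2: float = 1.0
    # tanh age-switch height and spread (dimensionless)
    gamma_0: float = 1.0
    sigma_w: float = 0.1
    # strain-to-necrosis constants (dimensionless)
    p_0: float = 1.0
    K_U: float = 0.0545
    # normalisation of the tanh age switch; the printed form is ambiguous:
    #   "over_sigma":  (gamma_0/sigma_w) * (tanh + 1)   saturation 2*g0/s
    #   "height":       gamma_0 * (tanh + 1)            saturation 2*g0
    #   "times_sigma": (gamma_0*sigma_w) * (tanh + 1)   saturation 2*g0*s
    gamma_form: str = "over_sigma"
    # initial conditions
    rho_0: float = 100_000.0  # pre-impact chondrocyte density, cells/cm^3
    U_0: float = 30.0  # initial ECM density, mg/cm^3
    eps_min: float = 10.0  # strain death threshold, %

    def __post_init__(self) -> None:
        positive = (
            "K_R", "K_M", "K_F", "K_P",
            "delta_R", "delta_M", "delta_F", "delta_P", "delta_U",
            "sigma_R", "sigma_M", "sigma_F", "sigma_P", "sigma_U",
            "Lambda", "lambda_R", "lambda_M", "lambda_F", "lambda_P",
            "P_c", "sigma_w", "rho_0", "U_0",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        nonnegative = (
            "alpha_1", "alpha_2", "beta_11", "beta_12", "beta_13",
            "kappa_1", "kappa_2", "mu_ST", "mu_SA", "mu_DN",
            "tau_1", "tau_2", "gamma_0", "p_0", "K_U", "eps_min",
        )
        for name in nonnegative:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name!r} must be nonnegative")
        if self.gamma_form not in ("over_sigma", "height", "times_sigma"):
            raise ValueError(
                "gamma_form must be 'over_sigma', 'height' or 'times_sigma'"
            )

    @property
    def gamma_height(self) -> float:
        """Pre-tanh amplitude of the age switch under the chosen form."""
        if self.gamma_form == "over_sigma":
            return self.gamma_0 / self.sigma_w
        if self.gamma_form == "height":
            return self.gamma_0
        return self.gamma_0 * self.sigma_w

    def replace(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the named fields replaced."""
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))


#: The published default calibration.
DEFAULT_PARAMETERS = ModelParameters()
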
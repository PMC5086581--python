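"""Model core: signalling kinetics, cell-state bookkeeping, initial state.

The model tracks six chondrocyte populations on the (r, z) grid -- healthy
unsignalled ``C_U``, DAMP-signalled pre-catabolic ``C_T`` (age-structured),
EPO-producing ``C_E``, catabolic ``S_T`` (age-structured), EPOR-active
``S_A`` and necrotic ``D_N`` -- four diffusing chemicals (ROS ``R``, DAMPs
``M``, pro-inflammatory cytokines ``F``, erythropoietin ``P``) and the
extracellular matrix density ``U``.  "Age" is state age: how long a cell has
been in its current state; delayed transitions are driven by a sharp tanh
switch ``gamma`` centred at the transition age.

This module defines the algebraic pieces (Hill saturation, Heaviside gate,
the gamma switch, the strain-to-necrosis map), the per-node reaction rates
of every equation, and the construction of the impact initial condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Grid
from .parameters import ModelParameters
from .strain import StrainField

__all__ = [
    "hill",
    "heaviside",
    "gamma_switch",
    "necrosis_fraction",
    "AgeCohorts",
    "TissueState",
    "ChemicalRates",
    "chemical_reaction_rates",
    "ecm_rate",
    "unstructured_cell_rates",
    "age_loss_rates",
    "age_transfer",
    "boundary_inflow",
    "initial_state",
]


# ---------------------------------------------------------------------------
# algebraic building blocks
# ---------------------------------------------------------------------------

def hill(x, lam: float):
    """First-order Hill saturation ``x / (lam + x)``; in [0, 1) for x >= 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("hill: negative concentration")
    if lam <= 0:
        raise ValueError("hill: half-saturation must be positive")
    out = x / (lam + x)
    return out if out.ndim else float(out)


def heaviside(theta):
    """Right-continuous Heaviside step: 1 for theta >= 0, 0 otherwise."""
    theta = np.asarray(theta, dtype=float)
    out = np.where(theta >= 0, 1.0, 0.0)
    return out if out.ndim else float(out)


def gamma_switch(a, a_max: float, gamma_0: float, sigma_w: float):
    """Sharp age switch ``(gamma_0/sigma_w) * (tanh((a - a_max)/sigma_w) + 1)``.

    Rises from ~0 well below the switch age ``a_max`` to the saturation value
    ``2*gamma_0/sigma_w``; equals ``gamma_0/sigma_w`` exactly at ``a_max``.
    The height scales inversely with the spread so that a narrower switch is
    also a stronger one.
    """
    if sigma_w <= 0:
        raise ValueError("gamma_switch: spread must be positive")
    a = np.asarray(a, dtype=float)
    out = (gamma_0 / sigma_w) * (np.tanh((a - a_max) / sigma_w) + 1.0)
    return out if out.ndim else float(out)


def gamma_saturation(p: ModelParameters) -> float:
    """Large-age limit of the age switch under the parameters' chosen
    normalisation (``2 * p.gamma_height``)."""
    return 2.0 * p.gamma_height


def gamma_profile(a, tau: float, p: ModelParameters):
    """The age switch evaluated under the parameters' chosen normalisation:
    ``p.gamma_height * (tanh((a - tau)/sigma_w) + 1)``."""
    a = np.asarray(a, dtype=float)
    out = p.gamma_height * (np.tanh((a - tau) / p.sigma_w) + 1.0)
    return out if out.ndim else float(out)


def necrosis_fraction(eps, p_0: float = 1.0, K_U: float = 0.0545,
                      eps_min: float = 10.0):
    """Fraction of cells killed outright by axial strain ``eps`` (percent).

    ``0.01 * p_0 * (exp(K_U*eps) - exp(eps_min*K_U))`` above the threshold
    ``eps_min``, zero below it (moderate strains are not lethal), clamped to
    [0, 1] since it is a fraction.  Continuous at the threshold.
    """
    eps = np.asarray(eps, dtype=float)
    raw = 0.01 * p_0 * (np.exp(K_U * eps) - np.exp(eps_min * K_U))
    out = np.where(eps <= eps_min, 0.0, np.clip(raw, 0.0, 1.0))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass
class AgeCohorts:
    """Age-structured population stored as cohorts over state-age intervals.

    ``edges`` has length ``n + 1`` with ``edges[0] = 0``; cohort ``k`` spans
    state ages ``[edges[k], edges[k+1])`` and ``contents[k]`` holds its cell
    density (cells/cm^3, aggregated over the interval) at every spatial node.
    If ``terminal`` is set, the last cohort is the open-ended lump of cells
    older than the age cutoff; its gamma switch is evaluated at saturation.
    """

    edges: np.ndarray  # (n+1,), days, strictly increasing, edges[0] = 0
    contents: np.ndarray  # (n, n_r, n_z), cells/cm^3
    terminal: bool = False

    @classmethod
    def empty(cls, grid_shape: tuple[int, int]) -> "AgeCohorts":
        return cls(edges=np.array([0.0]), contents=np.zeros((0, *grid_shape)))

    @property
    def n_cohorts(self) -> int:
        return self.contents.shape[0]

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def total(self) -> np.ndarray:
        """Age-integrated density at every spatial node."""
        if self.n_cohorts == 0:
            return np.zeros(self.contents.shape[1:])
        return self.contents.sum(axis=0)

    def copy(self) -> "AgeCohorts":
        return AgeCohorts(self.edges.copy(), self.contents.copy(), self.terminal)

    def validate(self) -> None:
        if self.edges[0] != 0.0 or np.any(np.diff(self.edges) <= 0):
            raise ValueError("cohort edges must start at 0 and increase")
        if self.contents.shape[0] != self.edges.size - 1:
            raise ValueError("cohort count does not match edges")
        if np.any(self.contents < 0):
            raise ValueError("negative cohort content")


@dataclass
class TissueState:
    """All model fields at one time point."""

    grid: Grid
    t: float
    # unstructured cell populations, cells/cm^3
    C_U: np.ndarray
    C_E: np.ndarray
    S_A: np.ndarray
    D_N: np.ndarray
    # age-structured populations
    C_T: AgeCohorts
    S_T: AgeCohorts
    # chemicals, nM
    R: np.ndarray
    M: np.ndarray
    F: np.ndarray
    P: np.ndarray
    # extracellular matrix, mg/cm^3
    U: np.ndarray
    # audit accumulators (cells/cm^3 removed, per node)
    sink_apoptosis: np.ndarray = None  # type: ignore[assignment]
    sink_necrotic: np.ndarray = None  # type: ignore[assignment]
    sink_leak: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = self.grid.shape
        for name in ("sink_apoptosis", "sink_necrotic", "sink_leak"):
            if getattr(self, name) is None:
                object.__setattr__(self, name, np.zeros(shape))

    CHEMICALS = ("R", "M", "F", "P")
    UNSTRUCTURED = ("C_U", "C_E", "S_A", "D_N")

    def total_cells(self) -> np.ndarray:
        """Per-node total of all live+necrotic cells plus audit sinks."""
        return (
            self.C_U + self.C_E + self.S_A + self.D_N
            + self.C_T.total() + self.S_T.total()
            + self.sink_apoptosis + self.sink_necrotic + self.sink_leak
        )

    def copy(self) -> "TissueState":
        return TissueState(
            grid=self.grid,
            t=self.t,
            C_U=self.C_U.copy(), C_E=self.C_E.copy(),
            S_A=self.S_A.copy(), D_N=self.D_N.copy(),
            C_T=self.C_T.copy(), S_T=self.S_T.copy(),
            R=self.R.copy(), M=self.M.copy(),
            F=self.F.copy(), P=self.P.copy(),
            U=self.U.copy(),
            sink_apoptosis=self.sink_apoptosis.copy(),
            sink_necrotic=self.sink_necrotic.copy(),
            sink_leak=self.sink_leak.copy(),
        )

    def validate(self) -> None:
        shape = self.grid.shape
        for name in (*self.UNSTRUCTURED, *self.CHEMICALS, "U"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"field {name} shape {arr.shape} != {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"field {name} contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"field {name} is negative")
        self.C_T.validate()
        self.S_T.validate()


# ---------------------------------------------------------------------------
# reaction right-hand sides (per-node, diffusion excluded)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChemicalRates:
    """Local (non-diffusive) rates of change of the four chemicals, nM/day."""

    dR: np.ndarray
    dM: np.ndarray
    dF: np.ndarray
    dP: np.ndarray


def chemical_reaction_rates(state: TissueState, p: ModelParameters) -> ChemicalRates:
    """Reaction parts of the chemical equations.

    ROS and PIC are produced by the age-integrated catabolic pool; DAMPs by
    necrotic cells and by cytokine-driven ECM breakdown; EPO by ``C_E`` cells
    under ROS drive and PIC inhibition (factor ``Lambda/(Lambda+F)``).
    """
    st_total = state.S_T.total()
    dR = -p.delta_R * state.R + p.sigma_R * st_total
    dM = (
        -p.delta_M * state.M
        + p.sigma_M * state.D_N
        + p.sigma_U * state.U * hill(state.F, p.lambda_F)
    )
    dF = -p.delta_F * state.F + p.sigma_F * st_total
    dP = (
        -p.delta_P * state.P
        + p.sigma_P * state.C_E * hill(state.R, p.lambda_R)
        * p.Lambda / (p.Lambda + state.F)
    )
    return ChemicalRates(dR=dR, dM=dM, dF=dF, dP=dP)


def ecm_rate(state: TissueState, p: ModelParameters) -> np.ndarray:
    """ECM degradation rate (mg/cm^3/day, always <= 0).

    Cytokine-driven breakdown, switched off wherever EPO exceeds ``P_c``.
    """
    return (
        -p.delta_U * state.U * hill(state.F, p.lambda_F)
        * heaviside(p.P_c - state.P)
    )


def unstructured_cell_rates(
    state: TissueState, p: ModelParameters, *, heaviside_conservative: bool = False
) -> dict[str, np.ndarray]:
    """Instantaneous rates for C_U, C_E, S_A, D_N (cells/cm^3/day).

    Used for rate inspection and the fixed-point/quiescence checks; the
    solver itself advances these pools with an exact-exponential bookkeeping
    scheme (see :mod:`chondrosim.solver`).
    """
    hP = hill(state.P, p.lambda_P)
    hM = hill(state.M, p.lambda_M)
    hF = hill(state.F, p.lambda_F)
    gate_lo = heaviside(p.P_c - state.P)  # inflammation active
    gate_hi = heaviside(state.P - p.P_c)  # EPO above threshold

    dC_U = (
        p.alpha_1 * state.S_A * hP
        + p.alpha_2 * gate_hi * state.C_E
        - p.beta_13 * state.C_U * hM
    )
    dC_E = age_transfer("C_T", state, p) - p.alpha_2 * gate_hi * state.C_E
    dS_A = (
        age_transfer("S_T", state, p,
                     heaviside_conservative=heaviside_conservative)
        - p.alpha_1 * state.S_A * hP
        - p.mu_SA * hF * gate_lo * state.S_A
    )
    dD_N = -p.mu_DN * state.D_N
    return {"C_U": dC_U, "C_E": dC_E, "S_A": dS_A, "D_N": dD_N}


def age_loss_rates(
    species: str, state: TissueState, p: ModelParameters,
    *, heaviside_conservative: bool = False,
) -> dict[str, np.ndarray]:
    """Per-cohort, per-node loss rates (1/day) split by outgoing channel.

    For ``C_T``: channel ``"to_ST"`` (DAMP/PIC signalling, gated off above
    the EPO threshold) and ``"to_CE"`` (ROS-driven, gamma-delayed).  For
    ``S_T``: ``"apoptosis"`` (DAMP+PIC) and ``"to_SA"`` (PIC-driven,
    gamma-delayed; gated by the EPO threshold only when the conservative
    variant is on -- the literal equations gate the matching gain, not the
    loss).  Shapes are ``(n_cohorts, n_r, n_z)``.
    """
    hM = hill(state.M, p.lambda_M)
    hF = hill(state.F, p.lambda_F)
    gate_lo = heaviside(p.P_c - state.P)

    if species == "C_T":
        cohorts = state.C_T
        gam = _cohort_gamma(cohorts, p.tau_2, p)
        hR = hill(state.R, p.lambda_R)
        to_st = (p.beta_11 * hM + p.beta_12 * hF) * gate_lo
        return {
            "to_ST": np.broadcast_to(to_st, (cohorts.n_cohorts, *state.grid.shape)).copy(),
            "to_CE": gam[:, None, None] * (p.kappa_1 * hR)[None, :, :],
        }
    if species == "S_T":
        cohorts = state.S_T
        gam = _cohort_gamma(cohorts, p.tau_1, p)
        apop = p.mu_ST * hF * hM
        to_sa = gam[:, None, None] * (p.kappa_2 * hF)[None, :, :]
        if heaviside_conservative:
            to_sa = to_sa * gate_lo[None, :, :]
        return {
            "apoptosis": np.broadcast_to(apop, (cohorts.n_cohorts, *state.grid.shape)).copy(),
            "to_SA": to_sa,
        }
    raise ValueError(f"unknown age-structured species {species!r}")


def _cohort_gamma(cohorts: AgeCohorts, tau: float, p: ModelParameters) -> np.ndarray:
    """Gamma switch per cohort, evaluated at the cohort midpoint age; the
    terminal lump uses the saturation value."""
    if cohorts.n_cohorts == 0:
        return np.zeros(0)
    gam = np.atleast_1d(np.asarray(gamma_profile(cohorts.midpoints(), tau, p)))
    if cohorts.terminal:
        gam[-1] = gamma_saturation(p)
    return gam


def age_transfer(
    species: str, state: TissueState, p: ModelParameters,
    *, heaviside_conservative: bool = False,
) -> np.ndarray:
    """Instantaneous transfer flux out of the age-structured pool
    (cells/cm^3/day): C_T -> C_E, or S_T -> S_A.

    Computed as the cohort quadrature of the corresponding channel loss rate
    times content, so transfers out of the pool equal arrivals exactly.  In
    the literal (non-conservative) variant the S_T -> S_A arrival is gated by
    the EPO threshold even though the loss is not.
    """
    if species == "C_T":
        rates = age_loss_rates("C_T", state, p)["to_CE"]
        cohorts = state.C_T
        gate = 1.0
    elif species == "S_T":
        rates = age_loss_rates(
            "S_T", state, p, heaviside_conservative=heaviside_conservative
        )["to_SA"]
        cohorts = state.S_T
        gate = heaviside(p.P_c - state.P)
    else:
        raise ValueError(f"unknown age-structured species {species!r}")
    if cohorts.n_cohorts == 0:
        return np.zeros(state.grid.shape)
    return (rates * cohorts.contents).sum(axis=0) * gate


def boundary_inflow(species: str, state: TissueState, p: ModelParameters) -> np.ndarray:
    """Birth flux into the age-0 boundary of an age-structured pool
    (cells/cm^3/day).

    New ``C_T`` cells are healthy cells signalled by DAMPs; new ``S_T``
    cells are ``C_T`` cells signalled by DAMPs or PIC (gated off above the
    EPO threshold), integrated over the C_T age structure.
    """
    hM = hill(state.M, p.lambda_M)
    if species == "C_T":
        return p.beta_13 * state.C_U * hM
    if species == "S_T":
        rates = age_loss_rates("C_T", state, p)["to_ST"]
        if state.C_T.n_cohorts == 0:
            return np.zeros(state.grid.shape)
        return (rates * state.C_T.contents).sum(axis=0)
    raise ValueError(f"unknown age-structured species {species!r}")


# ---------------------------------------------------------------------------
# initial condition
# ---------------------------------------------------------------------------

def initial_state(strain: StrainField, p: ModelParameters, grid: Grid) -> TissueState:
    """Impact initial condition.

    The strain field partitions the pre-impact density ``rho_0`` at every
    node into surviving healthy cells and necrotic cells via the necrosis
    fraction; chemicals start at zero, the ECM at ``U_0``, and both
    age-structured pools empty.
    """
    if strain.grid != grid:
        raise ValueError("strain field grid does not match the model grid")
    gam = necrosis_fraction(strain.eps, p.p_0, p.K_U, p.eps_min)
    shape = grid.shape
    D_N = gam * p.rho_0
    # C_U as the complement of D_N keeps the partition C_U + D_N = rho_0
    # exact in floating point at every node
    return TissueState(
        grid=grid,
        t=0.0,
        C_U=p.rho_0 - D_N,
        C_E=np.zeros(shape),
        S_A=np.zeros(shape),
        D_N=D_N,
        C_T=AgeCohorts.empty(shape),
        S_T=AgeCohorts.empty(shape),
        R=np.zeros(shape),
        M=np.zeros(shape),
        F=np.zeros(shape),
        P=np.zeros(shape),
        U=np.full(shape, p.U_0),
    )
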
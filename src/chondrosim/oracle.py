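"""Independent single-point (0-D) integrator used for cross-validation.

Under a spatially uniform strain field the no-flux diffusion terms vanish
and the full 2-D model reduces to the age-structured reaction system at a
single point.  This module integrates that system with a deliberately
different discretisation from the production solver: a fine *fixed* time
step equal to the age step, a dense age grid, and the explicit midpoint
(second-order Runge-Kutta) method for the reaction terms, with age
transport applied as an exact one-slot shift after each step.  It shares
only the parameter definitions with the ADI/cohort machinery, so agreement
between the two is a meaningful check of both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import gamma_profile, necrosis_fraction
from .parameters import ModelParameters

_SCALARS = ("C_U", "C_E", "S_A", "D_N", "R", "M", "F", "P", "U")


@dataclass
class PointState:
    """State of the reaction system at one spatial point.

    ``ct`` and ``st`` hold the age-density of the two age-structured pools
    on a uniform age grid of step ``da`` (contents per slot, cells/cm^3);
    the last slot lumps all ages past the cutoff.
    """

    t: float
    C_U: float
    C_E: float
    S_A: float
    D_N: float
    R: float
    M: float
    F: float
    P: float
    U: float
    ct: np.ndarray
    st: np.ndarray
    da: float

    def as_dict(self) -> dict[str, float]:
        out = {k: getattr(self, k) for k in _SCALARS}
        out["C_T"] = float(self.ct.sum())
        out["S_T"] = float(self.st.sum())
        return out


def _hill(x: float, lam: float) -> float:
    return x / (lam + x)


def _rhs(y: np.ndarray, ages: np.ndarray, p: ModelParameters, n_a: int,
         gam1: np.ndarray, gam2: np.ndarray) -> np.ndarray:
    """Reaction right-hand side of the flattened state vector.

    Layout: [C_U, C_E, S_A, D_N, R, M, F, P, U, nb_ct, nb_st,
    ct[0..n_a-1], st[0..n_a-1]]; ``nb_*`` accumulate the newborn mass
    produced during the step (shifted into slot 0 afterwards).
    """
    C_U, C_E, S_A, D_N, R, M, F, P, U = y[:9]
    ct = y[11 : 11 + n_a]
    st = y[11 + n_a :]

    hM = _hill(max(M, 0.0), p.lambda_M)
    hF = _hill(max(F, 0.0), p.lambda_F)
    hP = _hill(max(P, 0.0), p.lambda_P)
    hR = _hill(max(R, 0.0), p.lambda_R)
    lo = 1.0 if P < p.P_c else 0.0
    hi = 1.0 - lo

    ct_to_st_rate = (p.beta_11 * hM + p.beta_12 * hF) * lo
    ct_to_ce = p.kappa_1 * gam2 * hR
    st_apop = p.mu_ST * hF * hM
    st_to_sa = p.kappa_2 * gam1 * hF

    d = np.zeros_like(y)
    transfer_ce = float((ct_to_ce * ct).sum())
    transfer_sa = float((st_to_sa * st).sum()) * lo
    inflow_st = ct_to_st_rate * float(ct.sum())
    inflow_ct = p.beta_13 * C_U * hM

    d[0] = p.alpha_1 * S_A * hP + p.alpha_2 * hi * C_E - inflow_ct
    d[1] = transfer_ce - p.alpha_2 * hi * C_E
    d[2] = transfer_sa - p.alpha_1 * S_A * hP - p.mu_SA * hF * lo * S_A
    d[3] = -p.mu_DN * D_N
    d[4] = -p.delta_R * R + p.sigma_R * float(st.sum())
    d[5] = -p.delta_M * M + p.sigma_M * D_N + p.sigma_U * U * hF
    d[6] = -p.delta_F * F + p.sigma_F * float(st.sum())
    d[7] = -p.delta_P * P + p.sigma_P * C_E * hR * p.Lambda / (p.Lambda + F)
    d[8] = -p.delta_U * U * hF * lo
    d[9] = inflow_ct
    d[10] = inflow_st
    d[11 : 11 + n_a] = -(ct_to_st_rate + ct_to_ce) * ct
    d[11 + n_a :] = -(st_apop + st_to_sa) * st
    return d


def oracle_0d(
    eps_uniform: float,
    p: ModelParameters | None = None,
    horizon: float = 14.0,
    dt: float = 5e-4,
    a_cutoff: float = 2.0,
    snapshot_times: tuple[float, ...] = (0.0, 1.0, 7.0, 14.0),
) -> dict[float, dict[str, float]]:
    """Integrate the uniform-strain reaction system at one point.

    Returns ``{time: {variable: value}}`` with ``C_T``/``S_T`` reported as
    age-integrated totals.  ``dt`` is both the fixed time step and the age
    resolution.
    """
    p = ModelParameters() if p is None else p
    n_a = int(round(a_cutoff / dt)) + 1
    ages = (np.arange(n_a) + 0.5) * dt
    gam1 = gamma_profile(ages, p.tau_1, p)
    gam2 = gamma_profile(ages, p.tau_2, p)
    # terminal slot sits at saturation
    gam1[-1] = 2.0 * p.gamma_height
    gam2[-1] = 2.0 * p.gamma_height

    frac = necrosis_fraction(eps_uniform, p.p_0, p.K_U, p.eps_min)
    y = np.zeros(11 + 2 * n_a)
    y[0] = (1.0 - frac) * p.rho_0
    y[3] = frac * p.rho_0
    y[8] = p.U_0

    out: dict[float, dict[str, float]] = {}
    snaps = sorted(set(float(s) for s in snapshot_times))
    n_steps = int(round(horizon / dt))

    def record(t: float) -> None:
        st = PointState(
            t=t, C_U=y[0], C_E=y[1], S_A=y[2], D_N=y[3],
            R=y[4], M=y[5], F=y[6], P=y[7], U=y[8],
            ct=y[11 : 11 + n_a].copy(), st=y[11 + n_a :].copy(), da=dt,
        )
        out[t] = st.as_dict()

    snap_steps: dict[int, float] = {}
    for s in snaps:
        k_s = int(round(s / dt))
        if abs(k_s * dt - s) > 1e-9:
            raise ValueError(
                f"snapshot time {s} is not a multiple of the oracle step {dt}"
            )
        snap_steps[k_s] = s

    if 0 in snap_steps:
        record(0.0)
    for k in range(n_steps):
        # explicit midpoint step of the reaction system
        k1 = _rhs(y, ages, p, n_a, gam1, gam2)
        k2 = _rhs(y + 0.5 * dt * k1, ages, p, n_a, gam1, gam2)
        y = y + dt * k2
        np.maximum(y, 0.0, out=y)
        # age transport: exact shift by one slot; newborns enter slot 0;
        # the oldest slot is a lump and absorbs its neighbour
        ct = y[11 : 11 + n_a]
        st = y[11 + n_a :]
        ct[-1] += ct[-2]
        ct[1:-1] = ct[:-2]
        ct[0] = y[9]
        st[-1] += st[-2]
        st[1:-1] = st[:-2]
        st[0] = y[10]
        y[9] = y[10] = 0.0
        if (k + 1) in snap_steps:
            record(snap_steps[k + 1])
    return out
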
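"""Time integration of the coupled cell/chemical/ECM system.

Scheme, per accepted step (first-order operator splitting):

1. cell-state bookkeeping -- every pool loses mass through exact
   exponential decay of its frozen total loss rate, and the removed mass is
   credited to its destination pools channel by channel, so live cells plus
   audit sinks are conserved to rounding;
2. age transport -- cohorts ride the characteristics ``da/dt = 1``; the age
   grid is "natural": one newborn cohort per accepted step, so the age step
   equals the accepted time step; cohorts older than ``a_cutoff`` are lumped
   into a terminal cohort whose age switch sits at saturation;
3. chemical reactions -- exact integration of linear decay with the frozen
   production source (cannot cross zero);
4. chemical diffusion -- Peaceman-Rachford ADI on the cylindrical (r, z)
   domain with no-flux boundaries, in conservative flux form (the
   r-weighted total is preserved to rounding);
5. ECM degradation -- exact exponential decay at the frozen rate.

Step size is controlled by step doubling: one full step is compared with two
half steps over the four chemical fields; the two-half-step result is
accepted when the relative discrepancy is below tolerance, and the step
grows or shrinks accordingly.  The solver contains no randomness, so reruns
are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.linalg import solve_banded

from .grid import Grid
from .kinetics import (
    AgeCohorts,
    TissueState,
    age_loss_rates,
    boundary_inflow,
    chemical_reaction_rates,
    gamma_saturation,
    heaviside,
    hill,
    initial_state,
)
from .parameters import ModelParameters
from .strain import StrainField

if TYPE_CHECKING:  # pragma: no cover
    from .config import SimulationConfig


# ---------------------------------------------------------------------------
# solver settings and diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolverSettings:
    """Adaptive step-doubling controls.

    ``tol`` is the relative acceptance tolerance of the step-doubling
    comparison over the chemical fields; a step is accepted when
    ``||full - half||_2 <= tol * ||half||_2 + atol * sqrt(N)`` for every
    chemical, where ``atol`` (nM) is the absolute concentration floor below
    which discrepancies carry no meaning (fields start at exactly zero, so
    a purely relative test would stall the controller at t = 0).
    ``a_cutoff`` (days) is the state age beyond which cohorts are lumped;
    ``age_substeps`` subdivides the cell/age update within each chemical
    step (the refinement study halves the age step by setting it to 2).
    """

    dt_init: float = 1e-3
    dt_min: float = 1e-7
    dt_max: float = 0.015
    tol: float = 5e-5
    atol: float = 1e-8
    safety: float = 0.9
    growth_max: float = 2.0
    a_cutoff: float = 2.0
    age_substeps: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.dt_min <= self.dt_init <= self.dt_max):
            raise ValueError("need 0 < dt_min <= dt_init <= dt_max")
        if self.tol <= 0 or self.atol < 0:
            raise ValueError("tol must be positive and atol nonnegative")
        if self.age_substeps < 1:
            raise ValueError("age_substeps must be >= 1")
        if not (0 < self.safety <= 1) or self.growth_max < 1:
            raise ValueError("invalid step-control factors")

    def replace(self, **kw) -> "SolverSettings":
        import dataclasses

        return dataclasses.replace(self, **kw)


@dataclass
class SolverDiagnostics:
    """Bookkeeping of the adaptive loop."""

    n_accepted: int = 0
    n_rejected: int = 0
    dt_history: list[float] = field(default_factory=list)
    err_history: list[float] = field(default_factory=list)

    @property
    def n_attempts(self) -> int:
        return self.n_accepted + self.n_rejected


@dataclass
class Trajectory:
    """Ordered snapshots of the tissue state with solver diagnostics."""

    times: list[float]
    states: list[TissueState]
    diagnostics: SolverDiagnostics

    def state_at(self, t: float) -> TissueState:
        for ti, s in zip(self.times, self.states):
            if abs(ti - t) < 1e-9:
                return s
        raise KeyError(f"no snapshot at t = {t}")


# ---------------------------------------------------------------------------
# cylindrical diffusion: explicit operator and ADI sweeps
# ---------------------------------------------------------------------------

def _radial_face_coeffs(grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Face radii divided by node radius: conservative flux weights.

    For cell-centred nodes ``r_i = (i+1/2) dr`` the faces sit at ``i dr``
    and ``(i+1) dr``; the axis face (i = 0) carries radius 0, so the no-flux
    condition there is automatic, and the outer face flux is set to zero.
    """
    i = np.arange(grid.n_r)
    r = grid.r
    lo = (i * grid.dr) / r  # r_{i-1/2} / r_i, equals 0 at the axis
    hi = ((i + 1) * grid.dr) / r
    hi[-1] = 0.0  # no flux through the outer boundary
    return lo, hi


def laplacian_cyl(fld: np.ndarray, K: float, grid: Grid) -> np.ndarray:
    """Conservative discretisation of ``(1/r) d_r (r K d_r X) + K d_zz X``
    with no-flux boundaries; the r-weighted sum of the result is zero to
    rounding."""
    if K < 0:
        raise ValueError("diffusion coefficient must be nonnegative")
    fld = np.asarray(fld, dtype=float)
    if fld.shape != grid.shape:
        raise ValueError("field shape does not match grid")
    lo, hi = _radial_face_coeffs(grid)
    out = np.zeros_like(fld)
    # radial part
    cr = K / grid.dr**2
    out[:-1] += cr * hi[:-1, None] * (fld[1:] - fld[:-1])
    out[1:] -= cr * lo[1:, None] * (fld[1:] - fld[:-1])
    # axial part (zero-flux at both faces)
    cz = K / grid.dz**2
    out[:, :-1] += cz * (fld[:, 1:] - fld[:, :-1])
    out[:, 1:] -= cz * (fld[:, 1:] - fld[:, :-1])
    return out


def _tridiag_r(grid: Grid, K: float, dt: float, decay: float = 0.0) -> np.ndarray:
    """Banded matrix of ``I - (dt/2)(A_r - (decay/2) I)`` for
    :func:`scipy.linalg.solve_banded`."""
    lo, hi = _radial_face_coeffs(grid)
    c = 0.5 * dt * K / grid.dr**2
    n = grid.n_r
    ab = np.zeros((3, n))
    ab[0, 1:] = -c * hi[:-1]          # superdiagonal
    ab[1, :] = 1.0 + c * (lo + hi) + 0.25 * dt * decay    # diagonal
    ab[2, :-1] = -c * lo[1:]          # subdiagonal
    return ab


def _tridiag_z(grid: Grid, K: float, dt: float, decay: float = 0.0) -> np.ndarray:
    """Banded matrix of ``I - (dt/2)(A_z - (decay/2) I)``."""
    c = 0.5 * dt * K / grid.dz**2
    n = grid.n_z
    diag = np.full(n, 1.0 + 2.0 * c + 0.25 * dt * decay)
    diag[0] = 1.0 + c + 0.25 * dt * decay
    diag[-1] = 1.0 + c + 0.25 * dt * decay
    ab = np.zeros((3, n))
    ab[0, 1:] = -c
    ab[1, :] = diag
    ab[2, :-1] = -c
    return ab


def _apply_r(fld: np.ndarray, K: float, grid: Grid) -> np.ndarray:
    lo, hi = _radial_face_coeffs(grid)
    cr = K / grid.dr**2
    out = np.zeros_like(fld)
    out[:-1] += cr * hi[:-1, None] * (fld[1:] - fld[:-1])
    out[1:] -= cr * lo[1:, None] * (fld[1:] - fld[:-1])
    return out


def _apply_z(fld: np.ndarray, K: float, grid: Grid) -> np.ndarray:
    cz = K / grid.dz**2
    out = np.zeros_like(fld)
    out[:, :-1] += cz * (fld[:, 1:] - fld[:, :-1])
    out[:, 1:] -= cz * (fld[:, 1:] - fld[:, :-1])
    return out


def adi_step(
    fld: np.ndarray,
    K: float,
    dt: float,
    grid: Grid,
    source: np.ndarray | None = None,
    decay: float = 0.0,
) -> np.ndarray:
    """One Peaceman-Rachford ADI step of ``X_t = div(K grad X) - decay*X + s``
    on the cylindrical domain with no-flux boundaries.

    Implicit tridiagonal solve in r with explicit z, then implicit in z with
    explicit r; the linear decay is folded symmetrically into both sweeps
    (so a reaction-diffusion quasi-equilibrium ``div(K grad X) - decay*X + s
    = 0`` is an exact fixed point of the step) and the source (rate, per
    day) enters explicitly, half on each sweep.  Unconditionally stable; a
    spatially constant field with zero source and zero decay is reproduced
    exactly, and with ``decay = 0`` the r-weighted total is conserved to
    rounding.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if K < 0:
        raise ValueError("diffusion coefficient must be nonnegative")
    if decay < 0:
        raise ValueError("decay rate must be nonnegative")
    fld = np.asarray(fld, dtype=float)
    if K == 0.0 and decay == 0.0:
        return fld if source is None else fld + dt * source
    src = 0.0 if source is None else 0.5 * dt * source
    half_decay = 0.25 * dt * decay
    # sweep 1: implicit r
    rhs = fld + 0.5 * dt * _apply_z(fld, K, grid) - half_decay * fld + src
    star = solve_banded((1, 1), _tridiag_r(grid, K, dt, decay), rhs)
    # sweep 2: implicit z
    rhs = star + 0.5 * dt * _apply_r(star, K, grid) - half_decay * star + src
    out = solve_banded((1, 1), _tridiag_z(grid, K, dt, decay), rhs.T).T
    return out


# ---------------------------------------------------------------------------
# age-cohort transport
# ---------------------------------------------------------------------------

def advance_age_cohorts(
    cohorts: AgeCohorts,
    loss_rates: np.ndarray,
    inflow: np.ndarray,
    dt: float,
    a_cutoff: float = math.inf,
) -> AgeCohorts:
    """Advance an age-structured pool by ``dt`` along characteristics.

    Existing cohorts age by ``dt`` and decay by ``exp(-loss * dt)`` with the
    loss frozen at the step's evaluation point; a newborn cohort ``[0, dt)``
    receives ``inflow * dt``; cohorts whose lower edge has passed
    ``a_cutoff`` are merged into the terminal lump.

    This is the generic transport operation; the full model update in
    :func:`simulate` uses the same aging/merging path but credits newborn
    cohorts with the exactly-removed donor mass (see `_cell_substep`).
    """
    inflow = np.asarray(inflow, dtype=float)
    if np.any(inflow < 0):
        raise ValueError("negative boundary inflow")
    if loss_rates.shape != cohorts.contents.shape:
        raise ValueError("loss-rate shape does not match cohorts")
    survived = cohorts.contents * np.exp(-loss_rates * dt)
    out = _age_and_prepend(cohorts, [inflow * dt], dt, contents=survived)
    return _lump_old_cohorts(out, a_cutoff)


def _age_and_prepend(
    cohorts: AgeCohorts,
    newborn: list[np.ndarray],
    dt: float,
    contents: np.ndarray | None = None,
) -> AgeCohorts:
    """Shift every cohort ``dt`` older and insert newborn cohorts that
    partition ``[0, dt)`` evenly (youngest first)."""
    contents = cohorts.contents if contents is None else contents
    k = len(newborn)
    new_edges = np.concatenate([np.arange(k) * (dt / k), cohorts.edges + dt])
    new_contents = np.concatenate([np.stack(newborn), contents])
    return AgeCohorts(new_edges, new_contents, cohorts.terminal)


def _lump_old_cohorts(cohorts: AgeCohorts, a_cutoff: float) -> AgeCohorts:
    """Merge every cohort whose lower edge is at or past the cutoff into a
    single open-ended terminal cohort."""
    n = cohorts.n_cohorts
    lower = cohorts.edges[:-1]
    old = lower >= a_cutoff
    n_old = int(old.sum())
    if n_old <= (1 if cohorts.terminal else 0):
        return cohorts
    k0 = n - n_old
    lump = cohorts.contents[k0:].sum(axis=0)
    contents = np.concatenate([cohorts.contents[:k0], lump[None]])
    edges = np.concatenate([cohorts.edges[: k0 + 1], cohorts.edges[-1:]])
    return AgeCohorts(edges, contents, terminal=True)


def _merge_newborn_pairs(cohorts: AgeCohorts, n_keep: int) -> AgeCohorts:
    """Merge the ``2*n_keep`` youngest cohorts pairwise into ``n_keep``
    cohorts (restores one newborn cohort per accepted step after the
    two-half-step update)."""
    if cohorts.n_cohorts < 2 * n_keep:
        return cohorts
    young = cohorts.contents[: 2 * n_keep]
    merged = young[0::2] + young[1::2]
    contents = np.concatenate([merged, cohorts.contents[2 * n_keep:]])
    edges = np.concatenate(
        [cohorts.edges[: 2 * n_keep + 1: 2], cohorts.edges[2 * n_keep + 1:]]
    )
    return AgeCohorts(edges, contents, cohorts.terminal)


# ---------------------------------------------------------------------------
# the operator-split basic step
# ---------------------------------------------------------------------------

def _log_cosh(x: np.ndarray) -> np.ndarray:
    """Numerically stable ``log(cosh(x))``."""
    ax = np.abs(x)
    return ax + np.log1p(np.exp(-2.0 * ax)) - math.log(2.0)


def _gamma_step_average(
    midpoints: np.ndarray, tau: float, dt: float, p: ModelParameters,
    terminal: bool,
) -> np.ndarray:
    """Exact average of the gamma switch along the aging characteristic.

    A cohort with midpoint age ``a`` spans ages ``[a, a + dt]`` during the
    step; the time average of ``g*(tanh((x - tau)/s) + 1)`` over that
    interval has the closed form ``g*(1 + (s/dt)(logcosh((a + dt - tau)/s)
    - logcosh((a - tau)/s)))`` with ``g`` the switch amplitude.  Using it instead of the frozen
    midpoint value makes the cohort transfer second-order accurate through
    the sharp switch.  The terminal lump sits at saturation.
    """
    if midpoints.size == 0:
        return midpoints
    s = p.sigma_w
    x0 = (midpoints - tau) / s
    x1 = (midpoints + dt - tau) / s
    avg = p.gamma_height * (1.0 + (s / dt) * (_log_cosh(x1) - _log_cosh(x0)))
    if terminal:
        avg[-1] = gamma_saturation(p)
    return np.maximum(avg, 0.0)


def _pool_decay(contents: np.ndarray, total_rate: np.ndarray, dt: float):
    """Exact exponential decay; returns ``(survived, removed)`` with
    ``survived + removed == contents`` to rounding."""
    survived = contents * np.exp(-total_rate * dt)
    return survived, contents - survived


def _cohort_update_numpy(
    contents: np.ndarray,  # (k, n) cohort contents, flattened space
    base: np.ndarray,  # (n,) age-independent channel rate
    gated: np.ndarray,  # (n,) spatial factor of the gamma channel
    gam: np.ndarray,  # (k,) per-cohort gamma average
    dt: float,
):
    """Decay cohorts under ``base + gam*gated`` and split the removed mass.

    Returns ``(survived, removed_base, removed_gamma)`` where the removal
    sums are per spatial node; ``survived + removals`` equals the initial
    contents to rounding.
    """
    total = base[None, :] + gam[:, None] * gated[None, :]
    survived = contents * np.exp(-total * dt)
    removed = contents - survived
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(
            total > 0,
            (gam[:, None] * gated[None, :]) / np.where(total > 0, total, 1.0),
            0.0,
        )
    rem_gamma = (removed * share).sum(axis=0)
    rem_base = removed.sum(axis=0) - rem_gamma
    return survived, rem_base, rem_gamma


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=True, fastmath=False)
    def _cohort_update_numba(contents, base, gated, gam, dt):  # noqa: ANN001
        k, n = contents.shape
        survived = np.empty_like(contents)
        rem_base = np.zeros(n)
        rem_gamma = np.zeros(n)
        for i in range(k):
            gi = gam[i]
            for j in range(n):
                gch = gi * gated[j]
                total = base[j] + gch
                x = contents[i, j]
                s = x * math.exp(-total * dt)
                survived[i, j] = s
                rem = x - s
                if total > 0.0:
                    rg = rem * (gch / total)
                else:
                    rg = 0.0
                rem_gamma[j] += rg
                rem_base[j] += rem - rg
        return survived, rem_base, rem_gamma

    _cohort_update = _cohort_update_numba
except Exception:  # pragma: no cover
    _cohort_update = _cohort_update_numpy


def _cell_substep(
    state: TissueState,
    dt: float,
    p: ModelParameters,
    a_cutoff: float,
    heaviside_conservative: bool,
) -> None:
    """One cell/age update of size ``dt`` (in place); chemicals are frozen.

    Every pool decays exponentially at its frozen total loss rate and the
    removed mass is credited to its destinations channel by channel, so the
    grand total of cells plus audit sinks is invariant to rounding.  The
    gamma switches are averaged exactly along the aging characteristic, and
    newborn cohorts are midpoint-corrected: born on average at mid-step,
    they experience half a step of their age-independent onward losses
    (their gamma channels are vacuously small at age < dt).
    """
    hM = hill(state.M, p.lambda_M)
    hF = hill(state.F, p.lambda_F)
    hP = hill(state.P, p.lambda_P)
    gate_lo = heaviside(p.P_c - state.P)
    gate_hi = heaviside(state.P - p.P_c)
    shape = state.grid.shape

    # --- C_T cohorts: channels to S_T (age-independent) and to C_E ------
    ct = state.C_T
    b_ct = (p.beta_11 * hM + p.beta_12 * hF) * gate_lo  # (nr, nz)
    c_ce = p.kappa_1 * hill(state.R, p.lambda_R)
    gam2 = _gamma_step_average(ct.midpoints(), p.tau_2, dt, p, ct.terminal)
    ct_survived, rem_to_st, rem_to_ce = _cohort_update(
        ct.contents.reshape(ct.n_cohorts, b_ct.size),
        b_ct.ravel(), c_ce.ravel(), gam2, dt,
    )
    ct_survived = ct_survived.reshape(ct.contents.shape)
    to_ce = rem_to_ce.reshape(shape)
    st_inflow_mass = rem_to_st.reshape(shape)

    # --- S_T cohorts: apoptosis and (gamma-delayed) to S_A --------------
    st = state.S_T
    m_st = p.mu_ST * hF * hM
    c_sa = p.kappa_2 * hF
    if heaviside_conservative:
        c_sa = c_sa * gate_lo
    gam1 = _gamma_step_average(st.midpoints(), p.tau_1, dt, p, st.terminal)
    st_survived, rem_apop, rem_to_sa = _cohort_update(
        st.contents.reshape(st.n_cohorts, m_st.size),
        m_st.ravel(), c_sa.ravel(), gam1, dt,
    )
    st_survived = st_survived.reshape(st.contents.shape)
    to_sa_raw = rem_to_sa.reshape(shape)
    apop_st = rem_apop.reshape(shape)

    if heaviside_conservative:
        to_sa = to_sa_raw
        leak = 0.0
    else:
        # the literal equations gate the S_A arrival but not the S_T loss:
        # mass removed while EPO is above threshold leaks; route it to the
        # audit sink so the books still balance
        to_sa = to_sa_raw * gate_lo
        leak = to_sa_raw * (1.0 - gate_lo)

    # --- unstructured pools ---------------------------------------------
    cu_survived, cu_removed = _pool_decay(state.C_U, p.beta_13 * hM, dt)
    ce_survived, ce_removed = _pool_decay(state.C_E, p.alpha_2 * gate_hi, dt)
    rate_sa_cu = p.alpha_1 * hP
    rate_sa_ap = p.mu_SA * hF * gate_lo
    total_sa = rate_sa_cu + rate_sa_ap
    sa_survived, sa_removed = _pool_decay(state.S_A, total_sa, dt)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_cu = np.where(
            total_sa > 0, rate_sa_cu / np.where(total_sa > 0, total_sa, 1.0), 0.0
        )
    sa_to_cu = sa_removed * frac_cu
    sa_apop = sa_removed - sa_to_cu
    dn_survived = state.D_N * math.exp(-p.mu_DN * dt)
    dn_removed = state.D_N - dn_survived

    # --- newborn cohorts, midpoint-corrected -----------------------------
    # C_T newborns (mass removed from C_U) are exposed to the
    # age-independent C_T -> S_T channel for half a step on average; the
    # escaping mass joins this step's S_T inflow.  S_T newborns likewise
    # see half a step of apoptosis pressure.
    ct_newborn_factor = np.exp(-b_ct * (0.5 * dt))
    ct_newborn = cu_removed * ct_newborn_factor
    st_inflow_mass = st_inflow_mass + (cu_removed - ct_newborn)
    st_newborn_factor = np.exp(-m_st * (0.5 * dt))
    st_newborn = st_inflow_mass * st_newborn_factor
    apop_st = apop_st + (st_inflow_mass - st_newborn)

    # --- apply ----------------------------------------------------------
    state.C_U = cu_survived + ce_removed + sa_to_cu
    state.C_E = ce_survived + to_ce
    state.S_A = sa_survived + to_sa
    state.D_N = dn_survived
    state.sink_apoptosis = state.sink_apoptosis + apop_st + sa_apop
    state.sink_necrotic = state.sink_necrotic + dn_removed
    state.sink_leak = state.sink_leak + leak

    ct_new = AgeCohorts(ct.edges, ct_survived, ct.terminal)
    st_new = AgeCohorts(st.edges, st_survived, st.terminal)
    ct_new = _age_and_prepend(ct_new, [ct_newborn], dt)
    st_new = _age_and_prepend(st_new, [st_newborn], dt)
    state.C_T = _lump_old_cohorts(ct_new, a_cutoff)
    state.S_T = _lump_old_cohorts(st_new, a_cutoff)


def _productions(state: TissueState, p: ModelParameters) -> dict[str, np.ndarray]:
    """Chemical production terms (nM/day) from the current cell state, with
    the chemical saturation factors taken from the state's own chemicals."""
    st_total = state.S_T.total()
    return {
        "R": p.sigma_R * st_total,
        "M": p.sigma_M * state.D_N + p.sigma_U * state.U * hill(state.F, p.lambda_F),
        "F": p.sigma_F * st_total,
        "P": p.sigma_P * state.C_E * hill(state.R, p.lambda_R)
        * p.Lambda / (p.Lambda + state.F),
    }


def _advance(
    state: TissueState,
    dt: float,
    p: ModelParameters,
    settings: SolverSettings,
    heaviside_conservative: bool,
) -> TissueState:
    """One basic operator-split step of size ``dt`` (returns a new state).

    The cell update sees midpoint-predicted chemicals (a half-step ADI
    predictor), making the cell/chemical coupling second order; the
    chemicals are then advanced over the full step with their linear decay
    folded into the ADI sweeps and the cell-derived production interpolated
    linearly between the pre- and post-update cell state; the ECM decays
    exactly at its frozen rate.
    """
    state = state.copy()
    ecm_coeff = (
        p.delta_U * hill(state.F, p.lambda_F) * heaviside(p.P_c - state.P)
    )
    prod0 = _productions(state, p)
    decay = {"R": p.delta_R, "M": p.delta_M, "F": p.delta_F, "P": p.delta_P}
    diff = {"R": p.K_R, "M": p.K_M, "F": p.K_F, "P": p.K_P}

    # midpoint predictor for the chemical fields seen by the cell update
    chem0 = {name: getattr(state, name) for name in TissueState.CHEMICALS}
    for name in TissueState.CHEMICALS:
        d = decay[name]
        m = max(1, math.ceil(d * (0.5 * dt) / 0.5))
        x = chem0[name]
        for _ in range(m):
            x = adi_step(
                x, diff[name], 0.5 * dt / m, state.grid,
                source=prod0[name], decay=d,
            )
        setattr(state, name, np.maximum(x, 0.0))

    # cells and age cohorts (chemical fields frozen at the midpoint)
    sub = dt / settings.age_substeps
    for _ in range(settings.age_substeps):
        _cell_substep(state, sub, p, settings.a_cutoff, heaviside_conservative)
    prod1 = _productions(state, p)
    for name in TissueState.CHEMICALS:
        setattr(state, name, chem0[name])

    for name in ("R", "M", "F", "P"):
        d = decay[name]
        # substep the ADI so the per-sweep stiffness d*dt stays moderate
        # (keeps the rational decay factor close to the exponential); the
        # production source is interpolated linearly across the step
        m = max(1, math.ceil(d * dt / 0.5))
        x = getattr(state, name)
        p0_, p1_ = prod0[name], prod1[name]
        for j in range(m):
            w = (j + 0.5) / m
            x = adi_step(
                x,
                diff[name],
                dt / m,
                state.grid,
                source=(1.0 - w) * p0_ + w * p1_,
                decay=d,
            )
        setattr(state, name, _snap_nonnegative(x, name))

    # ECM: exact exponential decay at the frozen rate
    state.U = state.U * np.exp(-ecm_coeff * dt)
    state.t += dt
    return state


def _snap_nonnegative(x: np.ndarray, name: str, rel_tol: float = 1e-9) -> np.ndarray:
    """Snap rounding-level negative values to zero; larger ones are a bug."""
    m = x.min()
    if m < 0.0:
        scale = max(float(x.max()), 1.0)
        if m < -rel_tol * scale:
            raise FloatingPointError(
                f"field {name} went negative ({m:g}) beyond tolerance"
            )
        x = np.maximum(x, 0.0)
    return x


# ---------------------------------------------------------------------------
# step-doubling controller
# ---------------------------------------------------------------------------

def _pair_error(full: TissueState, half: TissueState,
                settings: SolverSettings) -> float:
    """Scaled L2 discrepancy between the one-step and two-half-step results,
    maximised over the chemical fields.

    The scale is ``||half||_2 + (atol/tol) * sqrt(N)``, so a returned value
    of ``tol`` marks the acceptance boundary
    ``||diff||_2 = tol * ||half||_2 + atol * sqrt(N)``.
    """
    err = 0.0
    n = None
    for name in TissueState.CHEMICALS:
        a = getattr(full, name)
        b = getattr(half, name)
        if n is None:
            n = math.sqrt(a.size)
        diff = float(np.linalg.norm(a - b))
        scale = float(np.linalg.norm(b)) + (settings.atol / settings.tol) * n
        err = max(err, diff / scale)
    return err


def step_doubling_control(
    state: TissueState,
    dt: float,
    p: ModelParameters,
    settings: SolverSettings,
    heaviside_conservative: bool = False,
) -> tuple[TissueState, float, float, float, int]:
    """Attempt steps of decreasing size until one is accepted.

    Returns ``(accepted_state, dt_taken, suggested_next_dt, error_estimate,
    n_rejected)``.
    The accepted state is the two-half-step result with its two newborn
    cohort groups merged so the age grid keeps one cohort per accepted step.
    """
    n_rejected = 0
    while True:
        full = _advance(state, dt, p, settings, heaviside_conservative)
        half = _advance(state, dt / 2, p, settings, heaviside_conservative)
        half = _advance(half, dt / 2, p, settings, heaviside_conservative)
        err = _pair_error(full, half, settings)
        if err <= settings.tol:
            half.C_T = _merge_newborn_pairs(half.C_T, settings.age_substeps)
            half.S_T = _merge_newborn_pairs(half.S_T, settings.age_substeps)
            if err == 0.0:
                factor = settings.growth_max
            else:
                # exponent 1/3: the split scheme's local error is O(dt^3)
                factor = min(
                    settings.growth_max,
                    max(0.2, settings.safety * (settings.tol / err) ** (1.0 / 3.0)),
                )
            dt_next = min(max(dt * factor, settings.dt_min), settings.dt_max)
            return half, dt, dt_next, err, n_rejected
        n_rejected += 1
        dt = dt / 2
        if dt < settings.dt_min:
            raise RuntimeError(
                f"step size underflow below dt_min={settings.dt_min} "
                f"(error estimate {err:g} at t={state.t:g})"
            )


def simulate(
    config: "SimulationConfig",
    strain: StrainField,
    p: ModelParameters | None = None,
) -> Trajectory:
    """Run the full model and return snapshots at the requested times.

    Steps are shortened to land exactly on snapshot times and the horizon.
    Deterministic: identical inputs give identical outputs.
    """
    p = config.parameters if p is None else p
    settings = config.solver
    grid = config.grid
    if strain.grid != grid:
        raise ValueError("strain grid does not match the configured grid")

    snap_times = sorted(set(float(t) for t in config.snapshot_times))
    horizon = float(config.horizon)
    if snap_times and (snap_times[0] < 0 or snap_times[-1] > horizon):
        raise ValueError("snapshot times must lie within [0, horizon]")

    if settings.a_cutoff <= max(p.tau_1, p.tau_2) + 5.0 * p.sigma_w:
        raise ValueError(
            "a_cutoff must exceed the latest age switch plus 5 spreads"
        )

    state = initial_state(strain, p, grid)
    diag = SolverDiagnostics()
    times: list[float] = []
    states: list[TissueState] = []

    def emit(t: float, s: TissueState) -> None:
        times.append(t)
        states.append(s.copy())

    if snap_times and snap_times[0] == 0.0:
        emit(0.0, state)

    events = [t for t in snap_times if t > 0.0]
    if not events or events[-1] < horizon:
        events.append(horizon)

    t = 0.0
    dt_ctrl = settings.dt_init
    conservative = bool(getattr(config, "heaviside_conservative", False))
    for t_event in events:
        while t < t_event - 1e-12:
            dt_try = min(dt_ctrl, t_event - t)
            accepted, dt_taken, dt_next, err, n_rej = step_doubling_control(
                state, dt_try, p, settings, conservative
            )
            state = accepted
            t = t_event if t_event - (t + dt_taken) < 1e-12 else t + dt_taken
            state.t = t
            diag.n_accepted += 1
            diag.n_rejected += n_rej
            diag.dt_history.append(dt_taken)
            diag.err_history.append(err)
            # keep the controller's own suggestion when the step was merely
            # shortened to hit an event
            dt_ctrl = dt_next if dt_try >= dt_ctrl else max(dt_ctrl, dt_next)
            if not np.all(np.isfinite(state.P)):
                raise FloatingPointError(f"non-finite field at t={t:g}")
        if t_event in snap_times:
            emit(t_event, state)
    return Trajectory(times=times, states=states, diagnostics=diag)
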
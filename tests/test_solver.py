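"""Diffusion operator, ADI stepping, cohort transport and the full loop."""

import math

import numpy as np
import pytest

import chondrosim as cs
from chondrosim.kinetics import AgeCohorts
from chondrosim.solver import step_doubling_control, _merge_newborn_pairs


# ---------------------------------------------------------------------------
# cylindrical Laplacian
# ---------------------------------------------------------------------------

def test_laplacian_constant_field_is_zero(small_grid):
    fld = np.full(small_grid.shape, 3.7)
    out = cs.laplacian_cyl(fld, 0.1, small_grid)
    assert np.allclose(out, 0.0, atol=1e-13)


def test_laplacian_discrete_conservation(small_grid):
    rng = np.random.default_rng(0)
    fld = rng.random(small_grid.shape)
    out = cs.laplacian_cyl(fld, 0.05, small_grid)
    weighted = (out * small_grid.r[:, None]).sum() * small_grid.dr * small_grid.dz
    assert abs(weighted) < 1e-12 * np.abs(fld).max()


def test_laplacian_z_cosine_eigenmode():
    grid = cs.Grid(n_r=4, n_z=64)
    K = 0.05
    mode = np.cos(np.pi * grid.z / grid.z_max)
    fld = np.broadcast_to(mode, (grid.n_r, grid.n_z)).copy()
    out = cs.laplacian_cyl(fld, K, grid)
    lam_exact = -K * (np.pi / grid.z_max) ** 2
    ratio = out[0] / fld[0]
    assert np.allclose(ratio, lam_exact, rtol=(np.pi * grid.dz / grid.z_max) ** 2)


def test_laplacian_rejects_negative_diffusivity(small_grid):
    with pytest.raises(ValueError):
        cs.laplacian_cyl(np.zeros(small_grid.shape), -1.0, small_grid)


# ---------------------------------------------------------------------------
# ADI step
# ---------------------------------------------------------------------------

def test_adi_identity_when_idle(small_grid):
    rng = np.random.default_rng(1)
    fld = rng.random(small_grid.shape)
    out = cs.adi_step(fld, 0.0, 0.01, small_grid)
    assert np.array_equal(out, fld)


def test_adi_preserves_constant_field(small_grid):
    fld = np.full(small_grid.shape, 2.5)
    out = cs.adi_step(fld, 0.1, 0.05, small_grid)
    assert np.allclose(out, 2.5, rtol=1e-14)


def test_adi_point_release_conserves_mass(small_grid):
    fld = np.zeros(small_grid.shape)
    fld[3, 4] = 1.0
    w = small_grid.r[:, None]
    total0 = (fld * w).sum()
    for _ in range(50):
        fld = cs.adi_step(fld, 0.1, 0.02, small_grid)
    total = (fld * w).sum()
    assert abs(total - total0) / total0 < 1e-10


def test_adi_decay_fixed_point():
    # diffusion-decay-source equilibrium is reproduced exactly
    grid = cs.Grid(n_r=12, n_z=10)
    rng = np.random.default_rng(2)
    src = rng.random(grid.shape) + 0.5
    decay = 7.0
    # solve for the discrete equilibrium by iteration
    x = src / decay
    for _ in range(4000):
        x = x + (cs.laplacian_cyl(x, 0.05, grid) - decay * x + src) / (4 * decay)
    out = cs.adi_step(x, 0.05, 0.03, grid, source=src, decay=decay)
    assert np.allclose(out, x, rtol=1e-6)


def test_adi_uniform_decay_matches_scalar_ode(small_grid):
    fld = np.full(small_grid.shape, 4.0)
    decay, dt = 3.0, 0.01
    out = fld.copy()
    for _ in range(100):
        out = cs.adi_step(out, 0.1, dt, small_grid, decay=decay)
    assert np.allclose(out, 4.0 * math.exp(-decay), rtol=1e-4)


# ---------------------------------------------------------------------------
# age-cohort transport
# ---------------------------------------------------------------------------

def _cohorts(shape, widths, values):
    edges = np.concatenate([[0.0], np.cumsum(widths)])
    contents = np.stack([np.full(shape, float(v)) for v in values])
    return AgeCohorts(edges=edges, contents=contents)


def test_cohort_pure_transport(small_grid):
    c = _cohorts(small_grid.shape, [0.1, 0.1], [5.0, 7.0])
    out = cs.advance_age_cohorts(
        c, np.zeros(c.contents.shape), np.zeros(small_grid.shape), 0.05
    )
    assert out.n_cohorts == 3
    assert out.edges == pytest.approx([0.0, 0.05, 0.15, 0.25])
    assert np.all(out.contents[0] == 0.0)
    assert np.all(out.contents[1] == 5.0)
    assert np.all(out.contents[2] == 7.0)


def test_cohort_exponential_decay(small_grid):
    c = _cohorts(small_grid.shape, [0.1], [10.0])
    mu = 2.0
    out = cs.advance_age_cohorts(
        c, np.full(c.contents.shape, mu), np.zeros(small_grid.shape), 0.25
    )
    assert out.contents[1] == pytest.approx(10.0 * math.exp(-mu * 0.25))


def test_cohort_constant_inflow_accumulates(small_grid):
    c = AgeCohorts.empty(small_grid.shape)
    b, dt, n = 40.0, 0.05, 60
    for _ in range(n):
        c = cs.advance_age_cohorts(
            c, np.zeros(c.contents.shape), np.full(small_grid.shape, b), dt
        )
    assert c.total() == pytest.approx(b * dt * n)


def test_cohort_terminal_lumping(small_grid):
    c = _cohorts(small_grid.shape, [1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    out = cs.advance_age_cohorts(
        c, np.zeros(c.contents.shape), np.zeros(small_grid.shape), 0.5,
        a_cutoff=2.0,
    )
    # only the cohort whose lower edge passed 2.0 after aging is lumped
    assert out.terminal
    assert out.contents[-1] == pytest.approx(3.0)
    assert out.total() == pytest.approx(6.0)


def test_cohort_negative_inflow_rejected(small_grid):
    c = AgeCohorts.empty(small_grid.shape)
    with pytest.raises(ValueError):
        cs.advance_age_cohorts(
            c, np.zeros(c.contents.shape), np.full(small_grid.shape, -1.0), 0.1
        )


def test_merge_newborn_pairs():
    c = _cohorts((2, 2), [0.025, 0.025, 0.025, 0.025], [1.0, 2.0, 3.0, 4.0])
    merged = _merge_newborn_pairs(c, 1)
    assert merged.n_cohorts == 3
    assert merged.edges == pytest.approx([0.0, 0.05, 0.075, 0.1])
    assert np.all(merged.contents[0] == 3.0)


# ---------------------------------------------------------------------------
# step control and the full loop
# ---------------------------------------------------------------------------

def test_quiescent_state_accepts_at_dt_max(small_grid, params):
    state = cs.initial_state(cs.zero_strain_field(small_grid), params, small_grid)
    settings = cs.SolverSettings()
    new, dt_taken, dt_next, err, n_rej = step_doubling_control(
        state, settings.dt_max, params, settings
    )
    assert err == 0.0 and n_rej == 0
    assert dt_taken == settings.dt_max and dt_next == settings.dt_max


def test_simulate_quiescence_full_horizon(params):
    cfg = cs.SimulationConfig(
        grid=cs.Grid(n_r=10, n_z=8), horizon=14.0, snapshot_times=(0.0, 7.0, 14.0)
    )
    traj = cs.simulate(cfg, cs.zero_strain_field(cfg.grid))
    s0 = traj.states[0]
    for s in traj.states[1:]:
        for name in ("C_U", "C_E", "S_A", "D_N", "U"):
            assert np.array_equal(getattr(s, name), getattr(s0, name))
        for name in ("R", "M", "F", "P"):
            assert np.abs(getattr(s, name)).max() <= 1e-12


def test_simulate_deterministic_rerun(small_grid):
    cfg = cs.SimulationConfig(grid=small_grid, horizon=1.0, snapshot_times=(1.0,))
    strain = cs.synthetic_strain_field(cs.SyntheticStrainParams(), small_grid)
    a = cs.simulate(cfg, strain).state_at(1.0)
    b = cs.simulate(cfg, strain).state_at(1.0)
    for name in ("C_U", "C_E", "S_A", "D_N", "R", "M", "F", "P", "U"):
        assert np.array_equal(getattr(a, name), getattr(b, name))
    assert np.array_equal(a.S_T.contents, b.S_T.contents)


def test_simulate_uniform_field_stays_uniform(small_grid):
    cfg = cs.SimulationConfig(grid=small_grid, horizon=2.0, snapshot_times=(2.0,))
    traj = cs.simulate(cfg, cs.uniform_strain_field(small_grid, 40.0))
    s = traj.state_at(2.0)
    for name in ("C_U", "C_E", "S_A", "D_N", "R", "M", "F", "P", "U"):
        arr = getattr(s, name)
        spread = arr.max() - arr.min()
        scale = max(abs(arr).max(), 1e-12)
        assert spread / scale < 1e-9, name


def test_simulate_conserves_cells_with_sinks(small_grid, params):
    cfg = cs.SimulationConfig(grid=small_grid, horizon=3.0, snapshot_times=(3.0,))
    strain = cs.synthetic_strain_field(cs.SyntheticStrainParams(), small_grid)
    for conservative in (False, True):
        traj = cs.simulate(cfg.replace(heaviside_conservative=conservative), strain)
        s = traj.state_at(3.0)
        total = s.total_cells()
        assert np.abs(total - params.rho_0).max() / params.rho_0 < 1e-12


def test_simulate_snapshot_times_validated(small_grid):
    with pytest.raises(ValueError):
        cs.SimulationConfig(
            grid=small_grid, horizon=14.0, snapshot_times=(0.0, 15.0)
        )


def test_simulate_dn_matches_closed_form(small_grid, params):
    cfg = cs.SimulationConfig(grid=small_grid, horizon=14.0, snapshot_times=(0.0, 14.0))
    traj = cs.simulate(cfg, cs.uniform_strain_field(small_grid, 60.0))
    d0 = traj.states[0].D_N[0, 0]
    d14 = traj.state_at(14.0).D_N[0, 0]
    assert d14 == pytest.approx(d0 * math.exp(-params.mu_DN * 14.0), rel=1e-6)


def test_diffusion_mass_conserved_over_horizon(small_grid):
    # a single chemical, diffusion only, 14 simulated days
    rng = np.random.default_rng(3)
    fld = rng.random(small_grid.shape)
    w = small_grid.r[:, None]
    total0 = (fld * w).sum()
    dt, steps = 0.05, 280
    for _ in range(steps):
        fld = cs.adi_step(fld, 0.1, dt, small_grid)
    assert abs((fld * w).sum() - total0) / total0 < 1e-8
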
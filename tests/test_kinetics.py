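"""Algebraic building blocks, reaction rates and the initial condition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chondrosim as cs
from chondrosim.kinetics import AgeCohorts, TissueState


# ---------------------------------------------------------------------------
# Hill saturation, Heaviside, gamma switch, necrosis map
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "x, lam, expected",
    [(0.0, 0.5, 0.0), (0.5, 0.5, 0.5), (4.5, 0.5, 0.9)],
)
def test_hill_values(x, lam, expected):
    assert cs.hill(x, lam) == pytest.approx(expected, abs=1e-15)


def test_hill_domain_errors():
    with pytest.raises(ValueError):
        cs.hill(-0.1, 0.5)
    with pytest.raises(ValueError):
        cs.hill(1.0, 0.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    x=st.floats(0, 1e6, allow_nan=False),
    y=st.floats(0, 1e6, allow_nan=False),
    lam=st.floats(1e-3, 1e3),
)
def test_hill_bounded_and_monotone(x, y, lam):
    hx, hy = cs.hill(x, lam), cs.hill(y, lam)
    assert 0.0 <= hx < 1.0
    if x <= y:
        assert hx <= hy


@pytest.mark.parametrize("theta, expected", [(0.0, 1.0), (-0.001, 0.0), (5.0, 1.0)])
def test_heaviside(theta, expected):
    assert cs.heaviside(theta) == expected


def test_gamma_switch_shape():
    # at the switch age the value is exactly gamma_0/sigma
    assert cs.gamma_switch(1.0, 1.0, 1.0, 0.1) == pytest.approx(10.0)
    # saturates at twice that, vanishes far below
    assert cs.gamma_switch(50.0, 1.0, 1.0, 0.1) == pytest.approx(20.0)
    assert cs.gamma_switch(-50.0, 1.0, 1.0, 0.1) == pytest.approx(0.0, abs=1e-12)
    a = np.linspace(0, 3, 301)
    g = cs.gamma_switch(a, 1.0, 1.0, 0.1)
    assert np.all(np.diff(g) >= 0)
    with pytest.raises(ValueError):
        cs.gamma_switch(1.0, 1.0, 1.0, 0.0)


def test_necrosis_fraction_values():
    # vanishes at and below the 10% threshold, continuous there
    assert cs.necrosis_fraction(10.0, 1.0, 0.0545, 10.0) == 0.0
    assert cs.necrosis_fraction(5.0) == 0.0
    assert cs.necrosis_fraction(10.0 + 1e-9) == pytest.approx(0.0, abs=1e-9)
    # direct evaluation of the exponential law at 60% strain
    expected = 0.01 * (np.exp(0.0545 * 60) - np.exp(0.545))
    assert cs.necrosis_fraction(60.0, 1.0, 0.0545, 10.0) == pytest.approx(expected)
    assert expected == pytest.approx(0.2459, abs=5e-4)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(eps=st.floats(0, 300, allow_nan=False), eps2=st.floats(0, 300, allow_nan=False))
def test_necrosis_fraction_monotone_bounded(eps, eps2):
    f1, f2 = cs.necrosis_fraction(eps), cs.necrosis_fraction(eps2)
    assert 0.0 <= f1 <= 1.0
    if eps <= eps2:
        assert f1 <= f2


def test_necrosis_fraction_clamped_at_extreme_strain():
    assert cs.necrosis_fraction(200.0) == 1.0


# ---------------------------------------------------------------------------
# reaction rates
# ---------------------------------------------------------------------------

def _state_with(grid, p, **overrides) -> TissueState:
    state = cs.initial_state(cs.zero_strain_field(grid), p, grid)
    for name, value in overrides.items():
        if name in ("C_T", "S_T"):
            setattr(state, name, value)
        else:
            setattr(state, name, np.full(grid.shape, float(value)))
    return state


def _single_cohort(grid, age, width, content) -> AgeCohorts:
    return AgeCohorts(
        edges=np.array([0.0, age, age + width]),
        contents=np.stack(
            [np.zeros(grid.shape), np.full(grid.shape, float(content))]
        ),
    )


def test_chemical_rates_production_by_catabolic_pool(small_grid, params):
    st_pool = _single_cohort(small_grid, 0.2, 0.1, 1000.0)
    state = _state_with(small_grid, params, S_T=st_pool)
    rates = cs.chemical_reaction_rates(state, params)
    # sigma_R = 0.0024 nM cm^3/(day cells) times 1000 cells/cm^3
    assert rates.dR == pytest.approx(np.full(small_grid.shape, 2.4))
    assert rates.dF == pytest.approx(np.full(small_grid.shape, 2.35e-4))


def test_chemical_rates_decay_only_terms(small_grid, params):
    state = _state_with(small_grid, params, M=0.3, U=0.0)
    rates = cs.chemical_reaction_rates(state, params)
    assert rates.dM == pytest.approx(-params.delta_M * 0.3)
    # EPO production needs ROS: C_E alone produces nothing
    state = _state_with(small_grid, params, C_E=500.0, P=0.2)
    rates = cs.chemical_reaction_rates(state, params)
    assert rates.dP == pytest.approx(-params.delta_P * 0.2)


def test_ecm_rate_gating(small_grid, params):
    # EPO above threshold blocks degradation entirely
    state = _state_with(small_grid, params, F=50.0, P=2.0 * params.P_c)
    assert np.all(cs.ecm_rate(state, params) == 0.0)
    # no cytokines, no degradation
    state = _state_with(small_grid, params, F=0.0)
    assert np.all(cs.ecm_rate(state, params) == 0.0)
    # saturated Hill: rate = -delta_U * U
    state = _state_with(small_grid, params, F=1e9)
    rate = cs.ecm_rate(state, params)
    assert rate == pytest.approx(-0.0193 * 30.0 * (1e9 / (0.5 + 1e9)))
    assert np.all(rate <= 0)


def test_unstructured_rates_necrotic_decay_only(small_grid, params):
    state = _state_with(small_grid, params, D_N=20000.0)
    rates = cs.unstructured_cell_rates(state, params)
    assert rates["D_N"] == pytest.approx(-1000.0)
    for name in ("C_U", "C_E", "S_A"):
        assert np.all(rates[name] == 0.0)


def test_unstructured_rates_epo_rescue_channel(small_grid, params):
    state = _state_with(small_grid, params, C_E=500.0, P=2.0 * params.P_c)
    rates = cs.unstructured_cell_rates(state, params)
    # above threshold C_E reverts to C_U at rate alpha_2
    assert rates["C_U"] == pytest.approx(500.0)
    assert rates["C_E"] == pytest.approx(-500.0)


def test_age_loss_rates_half_saturated_damp_channel(small_grid, params):
    ct = _single_cohort(small_grid, 0.1, 0.05, 100.0)
    state = _state_with(small_grid, params, C_T=ct, M=params.lambda_M)
    rates = cs.age_loss_rates("C_T", state, params)
    # beta_11 = 100 at half saturation, beta_12 and kappa_1 channels idle
    assert rates["to_ST"][1] == pytest.approx(50.0)
    assert np.all(rates["to_CE"] == 0.0)


def test_age_loss_rates_young_catabolic_cohort(small_grid, params):
    st_pool = _single_cohort(small_grid, 0.01, 0.01, 100.0)
    state = _state_with(small_grid, params, S_T=st_pool, M=1e9, F=1e9)
    rates = cs.age_loss_rates("S_T", state, params)
    # gamma ~ 0 well below tau_1 suppresses the S_A channel
    assert rates["apoptosis"][1] == pytest.approx(params.mu_ST, rel=1e-6)
    assert np.all(rates["to_SA"][1] < 0.05 * params.mu_ST)


def test_age_transfer_matches_cohort_quadrature(small_grid, params):
    # single cohort exactly at tau_2 with saturated ROS drive
    ct = _single_cohort(small_grid, params.tau_2 - 0.025, 0.05, 200.0)
    state = _state_with(small_grid, params, C_T=ct, R=1e9)
    flux = cs.age_transfer("C_T", state, params)
    gamma_mid = cs.gamma_switch(
        params.tau_2, params.tau_2, params.gamma_0, params.sigma_w
    )
    hill_r = 1e9 / (params.lambda_R + 1e9)
    assert flux == pytest.approx(params.kappa_1 * gamma_mid * hill_r * 200.0)
    # internal consistency: equals sum over cohorts of rate * content
    rates = cs.age_loss_rates("C_T", state, params)["to_CE"]
    assert flux == pytest.approx((rates * state.C_T.contents).sum(axis=0))


def test_age_transfer_empty_cohorts(small_grid, params):
    state = _state_with(small_grid, params, R=1e9, F=1e9)
    assert np.all(cs.age_transfer("C_T", state, params) == 0.0)
    assert np.all(cs.age_transfer("S_T", state, params) == 0.0)


def test_boundary_inflow(small_grid, params):
    state = _state_with(small_grid, params, M=params.lambda_M)
    state.C_U = np.full(small_grid.shape, 80000.0)
    # beta_13 = 10 at half saturation on 80,000 cells
    assert cs.boundary_inflow("C_T", state, params) == pytest.approx(400000.0)
    state.M = np.zeros(small_grid.shape)
    assert np.all(cs.boundary_inflow("C_T", state, params) == 0.0)
    # S_T inflow is gated off above the EPO threshold
    ct = _single_cohort(small_grid, 0.1, 0.05, 100.0)
    state = _state_with(small_grid, params, C_T=ct, M=1e9, P=2 * params.P_c)
    assert np.all(cs.boundary_inflow("S_T", state, params) == 0.0)


# ---------------------------------------------------------------------------
# initial condition
# ---------------------------------------------------------------------------

def test_initial_state_partition_and_zeros(small_grid, params):
    strain = cs.synthetic_strain_field(cs.SyntheticStrainParams(), small_grid)
    state = cs.initial_state(strain, params, small_grid)
    assert np.all(state.C_U + state.D_N == params.rho_0)
    assert np.all(state.U == params.U_0)
    for name in ("R", "M", "F", "P", "C_E", "S_A"):
        assert np.all(getattr(state, name) == 0.0)
    assert state.C_T.n_cohorts == 0 and state.S_T.n_cohorts == 0


def test_initial_state_zero_strain_is_fixed_point(small_grid, params):
    state = cs.initial_state(cs.zero_strain_field(small_grid), params, small_grid)
    assert np.all(state.C_U == params.rho_0)
    assert np.all(state.D_N == 0.0)
    rates = cs.chemical_reaction_rates(state, params)
    for arr in (rates.dR, rates.dM, rates.dF, rates.dP):
        assert np.all(arr == 0.0)
    cell_rates = cs.unstructured_cell_rates(state, params)
    for arr in cell_rates.values():
        assert np.all(arr == 0.0)
    assert np.all(cs.ecm_rate(state, params) == 0.0)


def test_initial_state_known_fraction(small_grid, params):
    # Gamma(60%) ~ 0.24587 partitions the density accordingly
    strain = cs.uniform_strain_field(small_grid, 60.0)
    state = cs.initial_state(strain, params, small_grid)
    frac = cs.necrosis_fraction(60.0, params.p_0, params.K_U, params.eps_min)
    assert state.D_N[0, 0] == pytest.approx(frac * params.rho_0)
    assert state.C_U[0, 0] == pytest.approx((1 - frac) * params.rho_0)


def test_initial_state_grid_mismatch(small_grid, params):
    strain = cs.zero_strain_field(small_grid)
    with pytest.raises(ValueError):
        cs.initial_state(strain, params, cs.Grid(n_r=4, n_z=4))
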
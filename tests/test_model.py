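"""Kinetic building blocks, parameter handling and the vector field."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from emtquad.model import (
    IDX,
    N_SPECIES,
    SPECIES,
    IntegrationError,
    ModelState,
    ParameterError,
    ParameterSet,
    apply_loop_knockdown,
    count_mutual_inhibition_loops,
    effective_rates,
    hill_activation,
    hill_repression,
    influence_edges,
    integrate,
    jacobian,
    mirna_occupancy,
    rhs,
)


# -- Hill kinetics ---------------------------------------------------------

@pytest.mark.parametrize("x,J,n,expected", [
    (0.0, 1.0, 4, 1.0),        # zero input, no repression
    (3.7, 3.7, 2, 0.5),        # half-saturation by definition
    (2.0, 1.0, 2, 0.2),        # 1/(1+4)
])
def test_hill_repression_values(x, J, n, expected):
    assert hill_repression(x, J, n) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("x,J,n,expected", [
    (0.0, 1.0, 4, 0.0),
    (0.8, 0.8, 3, 0.5),
    (2.0, 1.0, 2, 0.8),        # 4/5
])
def test_hill_activation_values(x, J, n, expected):
    assert hill_activation(x, J, n) == pytest.approx(expected, rel=1e-12)


@given(x=st.floats(0, 1e3), J=st.floats(1e-3, 1e2), n=st.floats(1, 8))
def test_hill_factors_are_complementary(x, J, n):
    up = hill_activation(x, J, n)
    down = hill_repression(x, J, n)
    assert 0.0 <= up <= 1.0 and 0.0 <= down <= 1.0
    assert up + down == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("bad", [
    dict(x=1.0, J=0.0, n=2),
    dict(x=1.0, J=-1.0, n=2),
    dict(x=1.0, J=1.0, n=0.5),
    dict(x=-0.1, J=1.0, n=2),
])
def test_hill_rejects_invalid_arguments(bad):
    with pytest.raises(ParameterError):
        hill_repression(**bad)
    with pytest.raises(ParameterError):
        hill_activation(**bad)


# -- miRNA occupancy -------------------------------------------------------

def test_occupancy_no_mirna_is_unbound():
    assert mirna_occupancy(0.0, 2, 1.0) == pytest.approx([1.0, 0.0, 0.0])


def test_occupancy_at_mu0_is_symmetric_binomial():
    w = mirna_occupancy(0.7, 2, 0.7)    # per-site probability 1/2
    assert w == pytest.approx([0.25, 0.5, 0.25], rel=1e-12)


@given(mu=st.floats(0, 1e3), n=st.integers(1, 8), mu0=st.floats(1e-3, 10))
def test_occupancy_weights_normalise(mu, n, mu0):
    w = mirna_occupancy(mu, n, mu0)
    assert len(w) == n + 1
    assert np.all(w >= 0)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)


def test_occupancy_rejects_negative_mirna():
    with pytest.raises(ParameterError):
        mirna_occupancy(-1.0, 2, 1.0)


# -- occupancy-weighted rates ---------------------------------------------

def test_effective_rates_unrepressed_limit():
    lt, ld = [1.0, 0.4, 0.1], [1.0, 2.0, 5.0]
    tr, dg = effective_rates(0.37, 0.0, 2, 1.0, lt, ld)
    assert tr == pytest.approx(0.37 * lt[0])
    assert dg == pytest.approx(0.37 * ld[0])


@pytest.mark.parametrize("mu", [0.0, 0.3, 1.0, 10.0])
def test_effective_rates_constant_coefficients(mu):
    # equal coefficients: occupancy weights normalise away
    tr, dg = effective_rates(2.0, mu, 3, 0.5, [0.7] * 4, [0.7] * 4)
    assert tr == pytest.approx(2.0 * 0.7, rel=1e-12)
    assert dg == pytest.approx(2.0 * 0.7, rel=1e-12)


def test_effective_rates_half_occupied_example():
    # weights [1/4, 1/2, 1/4] against translation coefficients [1, .5, 0]
    tr, _ = effective_rates(1.0, 1.0, 2, 1.0, [1.0, 0.5, 0.0], [1.0, 1.0, 1.0])
    assert tr == pytest.approx(0.5, rel=1e-12)


def test_effective_rates_rejects_nonmonotone_coefficients():
    with pytest.raises(ParameterError):
        effective_rates(1.0, 1.0, 2, 1.0, [1.0, 1.2, 0.1], [1, 2, 3])
    with pytest.raises(ParameterError):
        effective_rates(1.0, 1.0, 2, 1.0, [1.0, 0.5, 0.1], [3, 2, 1])
    with pytest.raises(ParameterError):
        effective_rates(1.0, 1.0, 2, 1.0, [1.0, 0.5], [1, 2, 3])


# -- ParameterSet ----------------------------------------------------------

def test_parameterset_roundtrip(params, tmp_path):
    path = tmp_path / "p.json"
    params.to_json(path)
    again = ParameterSet.from_json(path)
    assert again == params


def test_parameterset_missing_symbol_named(params):
    d = params.to_dict()
    del d["J_O"]
    with pytest.raises(ParameterError, match="J_O"):
        ParameterSet.from_dict(d)


def test_parameterset_unknown_symbol_named(params):
    d = params.to_dict()
    d["totally_new"] = 1.0
    with pytest.raises(ParameterError, match="totally_new"):
        ParameterSet.from_dict(d)


def test_parameterset_validation_enumerates_problems(params):
    with pytest.raises(ParameterError, match="kd_S.*J_O|J_O.*kd_S"):
        params.replace(kd_S=-1.0, J_O=0.0)


def test_table1_symbols_are_addressable(params):
    for sym in ("K_SR", "J1_34", "K_1", "J2_200", "J_O", "J2_zeb"):
        assert hasattr(params, sym)


# -- right-hand side -------------------------------------------------------

def test_rhs_origin_fixed_point_without_production(params):
    tiny = {f: 1e-300 for f in ("k_T", "k_sm", "k_S", "k_34", "k_zm", "k_Z",
                                "k_200", "ovol2_basal", "k_E", "k_V")}
    tiny.update({f: 0.0 for f in ("k0_sm", "k0_34", "k0_zm", "k0_200",
                                  "k0_E", "k0_V")})
    p = params.replace(**tiny)
    assert np.abs(rhs(np.zeros(N_SPECIES), p)).max() < 1e-250


def test_ovol2_derivative_without_repressor(params):
    x = np.zeros(N_SPECIES)
    x[IDX["OVOL2"]] = 1.234
    d = rhs(x, params)[IDX["OVOL2"]]
    assert d == pytest.approx(params.ovol2_basal - params.kd_O * 1.234, rel=1e-12)


def test_rhs_is_pure_and_deterministic(params, rng):
    x = rng.uniform(0, 5, size=(7, N_SPECIES))
    x_copy = x.copy()
    d1 = rhs(x, params)
    d2 = rhs(x, params)
    assert np.array_equal(d1, d2)
    assert np.array_equal(x, x_copy)


def test_rhs_rejects_nonfinite_state(params):
    x = np.zeros(N_SPECIES)
    x[3] = np.nan
    with pytest.raises(IntegrationError):
        rhs(x, params)


def test_integration_preserves_nonnegativity(params, rng):
    x0 = 10 ** rng.uniform(-3, 1, size=(100, N_SPECIES))
    from emtquad.steady import _relax
    end = _relax(params, x0, t_end=150.0, dt=0.02)
    assert np.all(end >= 0)
    assert np.all(np.isfinite(end))


def test_integrate_wrapper_matches_relaxation(params):
    x0 = np.full(N_SPECIES, 0.5)
    t, xs = integrate(params, x0, t_end=200.0)
    from emtquad.steady import _relax
    end = _relax(params, x0[None, :], t_end=400.0)[0]
    assert np.allclose(xs[-1], end, rtol=1e-3, atol=1e-6)


def test_jacobian_matches_directional_derivative(params, rng):
    x = rng.uniform(0.05, 2.0, size=N_SPECIES)
    J = jacobian(x, params)
    v = rng.standard_normal(N_SPECIES)
    v /= np.linalg.norm(v)
    eps = 1e-6
    dd = (rhs(x + eps * v, params) - rhs(x - eps * v, params)) / (2 * eps)
    assert np.allclose(J @ v, dd, rtol=1e-4, atol=1e-6)


# -- loop knockdowns -------------------------------------------------------

def test_knockdown_complete_ovol2_zeb(params):
    p = apply_loop_knockdown(params, "ovol2_zeb",
                             {"1/J_O": 0.001, "1/J2_zeb": 0.001})
    assert p.J_O == pytest.approx(params.J_O * 1000)
    assert p.J2_zeb == pytest.approx(params.J2_zeb * 1000)
    # the input set is untouched
    assert params.J_O != p.J_O


def test_knockdown_identity(params):
    p = apply_loop_knockdown(params, "mir200_zeb", {"K_1": 1.0, "1/J2_200": 1.0})
    assert p == params


def test_knockdown_mixed_strength_and_hill(params):
    p = apply_loop_knockdown(params, "mir34_snail", {"K_SR": 0.5, "1/J1_34": 0.5})
    assert p.K_SR == pytest.approx(params.K_SR * 0.5)
    assert p.J1_34 == pytest.approx(params.J1_34 * 2.0)


def test_knockdown_rejects_unknown_symbol(params):
    with pytest.raises(ParameterError, match="K_bogus"):
        apply_loop_knockdown(params, "mir34_snail", {"K_bogus": 0.5})
    with pytest.raises(ParameterError):
        apply_loop_knockdown(params, "not_a_loop", {"K_SR": 0.5})
    with pytest.raises(ParameterError):
        apply_loop_knockdown(params, "mir34_snail", {"K_SR": 0.0})


def test_silencing_strength_knockout_removes_repression(params):
    """K_SR scaled to 0.1% makes snail1 translation nearly insensitive
    to miR-34a, while at basal strength the same miR-34a level silences
    translation almost completely."""
    p = apply_loop_knockdown(params, "mir34_snail", {"K_SR": 0.001})
    mu = 2.0
    basal_tr, _ = effective_rates(1.0, mu, 2, params.mu0_34, params.l_34,
                                  params.gamma_34, strength=params.K_SR)
    kd_tr, _ = effective_rates(1.0, mu, 2, p.mu0_34, p.l_34,
                               p.gamma_34, strength=p.K_SR)
    free_tr, _ = effective_rates(1.0, 0.0, 2, p.mu0_34, p.l_34, p.gamma_34)
    assert basal_tr < 0.1 * free_tr
    assert kd_tr > 0.95 * free_tr


# -- influence graph -------------------------------------------------------

def test_exactly_three_mutual_inhibition_loops():
    assert count_mutual_inhibition_loops() == 3


def test_mutual_loops_are_the_published_ones():
    edges = influence_edges()
    pairs = {frozenset(p) for p in [("SNAIL", "MIR34"), ("ZEB", "MIR200"),
                                    ("ZEB", "OVOL2")]}
    found = {
        frozenset((a, b))
        for (a, b), sign in edges.items()
        if a != b and sign < 0 and edges.get((b, a), 0) < 0
    }
    assert found == pairs


def test_model_state_round_trip():
    x = np.linspace(0.1, 1.0, N_SPECIES)
    ms = ModelState.from_array(x)
    assert np.array_equal(ms.to_array(), x)
    with pytest.raises(ValueError):
        ModelState.from_array(-x)
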
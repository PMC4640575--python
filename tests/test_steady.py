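"""Steady-state enumeration, stability and phenotype labelling."""

import numpy as np
import pytest

from emtquad.model import N_SPECIES, ParameterError, rhs
from emtquad.steady import (
    RESIDUAL_TOL,
    SteadyState,
    classify_phenotype,
    classify_phenotypes,
    find_steady_states,
    _relax,
    _sample_starts,
)


@pytest.fixture(scope="module")
def green_states(green_params):
    return find_steady_states(green_params, n_starts=400, seed=0)


def test_four_stable_states_in_the_multistable_window(green_states):
    stable = [s for s in green_states if s.stable]
    saddles = [s for s in green_states if not s.stable]
    assert len(stable) == 4
    assert len(saddles) >= 3


def test_residuals_below_tolerance(green_states):
    assert all(s.residual < RESIDUAL_TOL for s in green_states)


def test_stability_flag_agrees_with_forward_integration(green_params, green_states):
    """Perturb each stable root by 1% and integrate ~10x the slowest
    timescale; stable roots must re-converge."""
    rng = np.random.default_rng(7)
    for s in green_states:
        if not s.stable:
            continue
        x0 = s.array * (1 + 0.01 * rng.uniform(-1, 1, N_SPECIES))
        end = _relax(green_params, x0[None, :], t_end=200.0)[0]
        rel = np.abs(np.log10(np.maximum(end, 1e-9))
                     - np.log10(np.maximum(s.array, 1e-9))).max()
        assert rel < 0.02


def test_determinism_under_fixed_seed(green_params):
    a = find_steady_states(green_params, n_starts=150, seed=42)
    b = find_steady_states(green_params, n_starts=150, seed=42)
    assert len(a) == len(b)
    for sa, sb in zip(a, b):
        assert np.array_equal(sa.array, sb.array)
        assert sa.stable == sb.stable


def test_no_missed_attractors_at_test_scale(green_params, green_states):
    """Every attractor reached by 200 random-start long-time
    integrations lies within tolerance of a returned stable root."""
    rng = np.random.default_rng(11)
    ends = _relax(green_params, _sample_starts(200, rng), t_end=500.0)
    stable = np.stack([s.array for s in green_states if s.stable])
    le = np.log10(np.maximum(ends, 1e-6))
    ls = np.log10(np.maximum(stable, 1e-6))
    d = np.abs(le[:, None, :] - ls[None, :, :]).max(axis=2).min(axis=1)
    assert np.all(d < 0.05)


def test_single_steady_state_without_production(params):
    tiny = {f: 1e-12 for f in ("k_T", "k_sm", "k_34", "k_zm",
                               "k_200", "ovol2_basal", "k_E", "k_V")}
    tiny.update({f: 0.0 for f in ("k0_sm", "k0_34", "k0_zm", "k0_200",
                                  "k0_E", "k0_V")})
    p = params.replace(**tiny)
    states = find_steady_states(p, n_starts=60, seed=0)
    stable = [s for s in states if s.stable]
    assert len(stable) == 1
    assert np.abs(stable[0].array).max() < 1e-6


def test_phenotype_labels_partition_the_four_states(green_states, reference):
    labelled = classify_phenotypes(green_states)
    stable_labels = [s.phenotype for s in labelled if s.stable]
    assert sorted(stable_labels) == ["E", "I1", "I2", "M"]
    # E-cadherin ordering defines the sequence
    by_label = {s.phenotype: s.state.ECAD for s in labelled if s.stable}
    assert by_label["E"] > by_label["I1"] > by_label["I2"] > by_label["M"]


def test_monostable_mesenchymal_at_high_tgfb(params, reference):
    states = find_steady_states(params.replace(tgfb_exo=10.0), n_starts=200, seed=0)
    stable = [s for s in states if s.stable]
    assert len(stable) == 1
    assert classify_phenotype(stable[0], reference) == "M"


def test_degenerate_duplicate_states_unclassified(green_states, reference):
    s = [x for x in green_states if x.stable][0]
    twin = SteadyState(s.state, True, s.eigen_max_real)
    labelled = classify_phenotypes([s, twin], reference)
    assert all(x.phenotype == "unclassified" for x in labelled)


def test_reference_required_for_partial_sets(green_states):
    stable = [s for s in green_states if s.stable][:2]
    with pytest.raises(ParameterError):
        classify_phenotypes(stable, None)


def test_nstarts_validation(green_params):
    with pytest.raises(ParameterError):
        find_steady_states(green_params, n_starts=0)


def test_ovol2_loop_removal_recovers_three_state_structure(params, reference):
    """With both Ovol2-Zeb1 edges effectively removed the remaining
    circuit is the two-miRNA-switch framework: at most 3 stable states
    anywhere along the TGF-β axis."""
    from emtquad.model import apply_loop_knockdown
    p = apply_loop_knockdown(params, "ovol2_zeb",
                             {"1/J_O": 0.001, "1/J2_zeb": 0.001})
    for tg in (0.0, 0.5, 1.5, 2.5, 5.0):
        states = find_steady_states(p.replace(tgfb_exo=tg), n_starts=150, seed=2)
        assert sum(s.stable for s in states) <= 3
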
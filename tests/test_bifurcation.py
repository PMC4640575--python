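"""Continuation, fold detection, region maps and knockdown verdicts."""

import numpy as np
import pytest

from emtquad.bifurcation import (
    RegionMap,
    _merged,
    _verdict,
    continue_branch,
    knockdown_scan,
    region_map,
    sweep_states,
)
from emtquad.model import apply_loop_knockdown
from emtquad.steady import find_steady_states


@pytest.fixture(scope="module")
def e_branch(params):
    """Continuation of the epithelial branch in external TGF-β."""
    states = find_steady_states(params, n_starts=200, seed=1)
    e_state = max((s for s in states if s.stable), key=lambda s: s.state.ECAD)
    return continue_branch(params, "tgfb_exo", (0.0, 10.0), e_state.array,
                           max_step=0.1)


def test_epithelial_branch_has_a_saddle_node(e_branch):
    assert e_branch.truncated is None
    assert len(e_branch.folds) >= 1
    # stability changes only at the detected fold
    flips = np.flatnonzero(np.diff(e_branch.stable.astype(int)) != 0)
    assert len(flips) <= len(e_branch.folds) + 1


def test_fold_location_agrees_with_grid_scan_oracle(params, e_branch):
    """The continuation fold must sit within 1% (of the sweep range
    scale) of where a dense multistart scan sees the epithelial state
    count drop."""
    fold = min(f[0] for f in e_branch.folds)
    values = np.linspace(max(fold - 0.2, 0.0), fold + 0.2, 17)
    counts = [sum(s.stable and s.state.ECAD > 1.0 for s in states)
              for states in sweep_states(params, "tgfb_exo", values, seed=3)]
    drops = np.flatnonzero(np.diff(counts) < 0)
    assert len(drops) >= 1
    grid_fold = 0.5 * (values[drops[0]] + values[drops[0] + 1])
    assert abs(grid_fold - fold) <= 0.01 * 10.0 + (values[1] - values[0])


def test_consecutive_samples_bounded_by_max_step(e_branch):
    gaps = np.abs(np.diff(e_branch.values))
    assert np.all(gaps <= 0.1 + 1e-9)


def test_decoupled_linear_branch_has_no_folds(params):
    """With the Ovol2 edges removed, OVOL2 is a linear birth-death
    species: its branch in ovol2_basal is single-valued, fold-free."""
    p = apply_loop_knockdown(params, "ovol2_zeb",
                             {"1/J_O": 0.001, "1/J2_zeb": 0.001})
    p = p.replace(J_OT=1e6, J_vo=1e6)
    states = find_steady_states(p.replace(ovol2_basal=0.1), n_starts=150, seed=1)
    start = max((s for s in states if s.stable), key=lambda s: s.state.ECAD)
    br = continue_branch(p.replace(ovol2_basal=0.1), "ovol2_basal",
                         (0.1, 3.0), start.array, max_step=0.1)
    assert len(br.folds) == 0
    # OVOL2 responds linearly to its basal production rate
    o = br.states[:, 7]
    fit = np.polyfit(br.values, o, 1)
    assert np.allclose(np.polyval(fit, br.values), o, rtol=1e-3, atol=1e-6)


# -- region maps -----------------------------------------------------------

@pytest.fixture(scope="module")
def basal_map(params, reference):
    return region_map(params, resolution=16, seed=0, reference=reference)


def test_region_map_contains_tetrastable_zone(basal_map):
    sets = {basal_map.labels[i][j]
            for i in range(16) for j in range(16)}
    assert frozenset({"E", "I1", "I2", "M"}) in sets


def test_region_map_cells_all_carry_a_phenotype(basal_map):
    assert basal_map.failed == []
    for i in range(16):
        for j in range(16):
            assert len(basal_map.labels[i][j]) >= 1


def test_region_masks_consistent_with_label_sets(basal_map):
    m = basal_map.mask("M")
    for i in range(16):
        for j in range(16):
            assert m[i, j] == ("M" in basal_map.labels[i][j])


def test_region_map_invariant_to_seed_up_to_boundary(params, reference):
    a = region_map(params, resolution=12, seed=0, reference=reference)
    b = region_map(params, resolution=12, seed=99, reference=reference)
    same = sum(a.labels[i][j] == b.labels[i][j]
               for i in range(12) for j in range(12))
    assert same >= 0.95 * 144


def test_region_map_resolution_validation(params, reference):
    with pytest.raises(Exception):
        region_map(params, resolution=4, reference=reference)


# -- knockdown scans -------------------------------------------------------

def test_verdict_thresholds():
    assert _verdict(0, 50) == "disappearance"
    assert _verdict(39, 50) == "decrease"     # -22%
    assert _verdict(40, 50) == "decrease"     # exactly -20%
    assert _verdict(45, 50) == "unchanged"
    assert _verdict(61, 50) == "increase"


def test_merge_detector_on_synthetic_maps():
    g = np.linspace(0, 1, 8)
    both = [[frozenset({"I1", "I2"}) for _ in g] for _ in g]
    basal = RegionMap("a", "b", g, g, both)
    single = [[frozenset({"I1"}) for _ in g] for _ in g]
    merged_map = RegionMap("a", "b", g, g, single)
    assert _merged(merged_map, basal)
    assert not _merged(basal, basal)


def test_ovol2_zeb_blockage_collapses_I2(params, reference):
    """Complete Ovol2-Zeb1 blockage removes the low-Ovol2 intermediate:
    its region shrinks drastically relative to basal."""
    basal = region_map(params, resolution=16, seed=0, reference=reference)
    p = apply_loop_knockdown(params, "ovol2_zeb",
                             {"1/J_O": 0.001, "1/J2_zeb": 0.001})
    kd = region_map(p, resolution=16, seed=0, reference=reference)
    assert kd.area("I2") <= 0.25 * basal.area("I2")


def test_weakened_ovol2_repression_of_zeb_expands_I2(params, reference):
    """Halving 1/J_O (weaker Ovol2 repression of zeb1) enlarges the I2
    region."""
    basal = region_map(params, resolution=16, seed=0, reference=reference)
    p = apply_loop_knockdown(params, "ovol2_zeb", {"1/J_O": 0.5})
    kd = region_map(p, resolution=16, seed=0, reference=reference)
    assert kd.area("I2") >= 1.2 * basal.area("I2")


def test_partial_mir34_knockdown_shrinks_I1(params, reference):
    basal = region_map(params, resolution=16, seed=0, reference=reference)
    p = apply_loop_knockdown(params, "mir34_snail",
                             {"K_SR": 0.25, "1/J1_34": 0.25})
    kd = region_map(p, resolution=16, seed=0, reference=reference)
    assert kd.area("I1") <= 0.8 * basal.area("I1")


def test_identity_condition_reports_unchanged(params):
    df = knockdown_scan(
        params,
        {"identity": [("ovol2_zeb", {"1/J_O": 1.0, "1/J2_zeb": 1.0})]},
        resolution=12, seed=0,
    )
    row = df[df.condition == "identity"].iloc[0]
    assert row.verdict_I1 == "unchanged"
    assert row.verdict_I2 == "unchanged"
    assert not row.merged
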
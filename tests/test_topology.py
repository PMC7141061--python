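import numpy as np
import pytest

from itop.matrix import build_distance_matrix
from itop.topology import (
    BinaryMask, threshold_filter, label_components, count_holes,
    coherence_statistic, scan_thresholds, find_critical_threshold,
)
from itop.simulate import SimulationConfig, simulate_gaze

from conftest import make_recording, random_mask
from oracles import flood_components, flood_holes, holes_per_component


# ---------------------------------------------------------------------------
# threshold filtration
# ---------------------------------------------------------------------------

def test_filter_at_zero_keeps_only_the_valid_diagonal():
    rng = np.random.default_rng(0)
    rec = make_recording(rng.uniform(0, 10, (12, 2)))  # a.s. distinct
    D = build_distance_matrix(rec)
    mask = threshold_filter(D, 0.0)
    assert np.array_equal(mask.foreground, np.eye(12, dtype=bool))


def test_filter_endpoint_is_full_valid_foreground():
    rec = make_recording([(0, 0), (np.nan, np.nan), (2, 0), (5, 5)])
    D = build_distance_matrix(rec)
    mask = threshold_filter(D, D.max_finite)
    expected = np.isfinite(D.values)
    assert np.array_equal(mask.foreground, expected)
    assert not mask.foreground[1].any()  # sentinel row never foreground


def test_filtration_is_nested():
    rng = np.random.default_rng(1)
    rec = make_recording(rng.uniform(0, 5, (15, 2)))
    D = build_distance_matrix(rec)
    ts = np.quantile(D.finite_values, [0.1, 0.3, 0.5, 0.8, 1.0])
    prev = None
    for t in ts:
        fg = threshold_filter(D, t).foreground
        if prev is not None:
            assert (fg | prev == fg).all()  # prev subset of fg
        prev = fg


def test_filter_rejects_negative_threshold():
    D = build_distance_matrix(make_recording([(0, 0), (1, 1)]))
    with pytest.raises(ValueError):
        threshold_filter(D, -0.5)


# ---------------------------------------------------------------------------
# components and holes
# ---------------------------------------------------------------------------

def test_full_mask_is_one_component_without_holes():
    mask = BinaryMask(np.ones((6, 6), bool), 1.0)
    lab = label_components(mask)
    assert lab.n_components == 1
    comp = lab.components[0]
    assert comp.touches_diagonal
    assert comp.diagonal_runs == [(0, 5)]
    assert comp.holes == 0


def test_two_disjoint_diagonal_squares():
    fg = np.zeros((8, 8), bool)
    fg[0:3, 0:3] = True
    fg[5:8, 5:8] = True
    lab = label_components(BinaryMask(fg, 1.0))
    assert lab.n_components == 2
    assert [c.diagonal_runs for c in lab.components] == [[(0, 2)], [(5, 7)]]
    assert all(c.touches_diagonal for c in lab.components)
    assert lab.diagonal_partition() == [(0, 2), (5, 7)]


def test_corner_touching_squares_stay_separate():
    """4-connected foreground: corner contact does not merge blocks."""
    fg = np.zeros((6, 6), bool)
    fg[0:3, 0:3] = True
    fg[3:6, 3:6] = True
    lab = label_components(BinaryMask(fg, 1.0))
    assert lab.n_components == 2
    assert lab.diagonal_partition() == [(0, 2), (3, 5)]


def test_solid_square_has_no_holes_and_ring_has_one():
    solid = BinaryMask(np.ones((5, 5), bool), 1.0)
    assert sum(count_holes(solid).values()) == 0
    ring = np.ones((5, 5), bool)
    ring[2, 2] = False
    holes = count_holes(BinaryMask(ring, 1.0))
    assert holes == {1: 1}


def test_background_touching_border_is_never_a_hole():
    fg = np.ones((5, 5), bool)
    fg[0, 2] = False  # notch open to the border
    fg[2, 0] = False
    assert sum(count_holes(BinaryMask(fg, 1.0)).values()) == 0


@pytest.mark.parametrize("n,p", [(12, 0.35), (12, 0.5), (20, 0.45)])
def test_components_and_holes_match_flood_fill_oracles(n, p):
    rng = np.random.default_rng(n * 100 + int(p * 100))
    for _ in range(150):
        fg = random_mask(rng, n, p)
        mask = BinaryMask(fg, 1.0)
        lab = label_components(mask)
        oracle_labels = flood_components(fg)
        assert np.array_equal(lab.labels, oracle_labels)
        _, oracle_nholes = flood_holes(fg)
        got = count_holes(mask)
        assert sum(got.values()) == oracle_nholes
        oracle_counts, _ = holes_per_component(fg)
        assert got == oracle_counts


# ---------------------------------------------------------------------------
# coherence statistic
# ---------------------------------------------------------------------------

def test_constant_recording_is_coherent_at_every_threshold():
    rec = make_recording([(2, 2)] * 10)
    D = build_distance_matrix(rec)
    for t in (0.0, 0.5, 3.0):
        assert coherence_statistic(D, t) == 0


def test_interior_double_void_counts_via_the_hole_oracle():
    """A diagonal block missing the interior pixels (2,3) and (3,2).

    The two voids are diagonally adjacent, so under the 8-connected
    background convention they form a single enclosed region; the oracle
    agrees.
    """
    fg = np.zeros((7, 7), bool)
    fg[0:5, 0:5] = True
    fg[2, 3] = fg[3, 2] = False
    _, oracle_nholes = flood_holes(fg)
    assert oracle_nholes == 1
    got = count_holes(BinaryMask(fg, 1.0))
    assert sum(got.values()) == oracle_nholes


def test_full_foreground_has_no_holes():
    rng = np.random.default_rng(5)
    rec = make_recording(rng.uniform(0, 4, (9, 2)))
    D = build_distance_matrix(rec)
    assert coherence_statistic(D, D.max_finite) == 0


# ---------------------------------------------------------------------------
# the event-driven scan
# ---------------------------------------------------------------------------

def test_scan_visits_every_unique_distance(six_sample_recording):
    D = build_distance_matrix(six_sample_recording)
    scan = scan_thresholds(D)
    # distance multiset of the two-cluster configuration
    expected = np.unique([0.0, 1.0, 10.0, np.sqrt(101.0)])
    assert np.allclose(scan.thresholds, expected)
    assert (np.diff(scan.thresholds) > 0).all()
    assert scan.hole_counts[-1] == 0


def test_scan_threshold_count_is_number_of_distinct_distances():
    rec = make_recording([(0, 0), (1, 0), (3, 0)])  # distances 1,2,3 and 0
    scan = scan_thresholds(build_distance_matrix(rec))
    assert len(scan.thresholds) == 4  # 0 joins the three pair distances


@pytest.mark.parametrize("seed,loss", [(0, []), (1, [(12, 4)]), (2, [(5, 3)])])
def test_incremental_scan_equals_naive_recomputation(seed, loss):
    cfg = SimulationConfig(seed=seed, n_fixations=3, noise_sd=0.3,
                           fixation_duration=(12, 20), loss_gaps=loss,
                           id="scan-eq")
    rec, _ = simulate_gaze(cfg)
    D = build_distance_matrix(rec)
    fast = scan_thresholds(D, "incremental")
    naive = scan_thresholds(D, "naive")
    assert np.array_equal(fast.thresholds, naive.thresholds)
    assert np.array_equal(fast.hole_counts, naive.hole_counts)
    assert ([(e.index, e.runs) for e in fast.partition_events]
            == [(e.index, e.runs) for e in naive.partition_events])


def test_scan_requires_a_valid_sample():
    rec = make_recording([(np.nan, np.nan)], valid=[False])
    with pytest.raises(ValueError):
        scan_thresholds(build_distance_matrix(rec))


# ---------------------------------------------------------------------------
# critical thresholds
# ---------------------------------------------------------------------------

def test_all_identical_samples_fall_back_to_tc_zero():
    rec = make_recording([(1, 1)] * 8)
    scan = scan_thresholds(build_distance_matrix(rec))
    c = find_critical_threshold(scan, 1)
    assert c.tc == 0.0 and c.rule == "fallback"
    assert scan.partition_at(c.index).runs == ((0, 7),)


def test_two_cluster_fallback_selects_the_persistent_partition(
        six_sample_recording):
    """Exhaustive-enumeration example: hole-free data, persistence fallback.

    Unique distances are {0, 1, 10, sqrt(101)}; the partition {[0,2],[3,5]}
    holds on [1, sqrt(101)) giving persistence ratio ~10, which dominates
    every other plateau, so tc = 1 with two blocks.
    """
    D = build_distance_matrix(six_sample_recording)
    scan = scan_thresholds(D)
    assert (scan.hole_counts == 0).all()
    c = find_critical_threshold(scan, 1)
    assert c.rule == "fallback"
    assert c.tc == pytest.approx(1.0)
    assert scan.partition_at(c.index).runs == ((0, 2), (3, 5))


def test_noisy_burst_rule_recovers_planted_blocks(noisy_recording):
    rec, truth = noisy_recording
    scan = scan_thresholds(build_distance_matrix(rec))
    c = find_critical_threshold(scan, 1)
    assert c.rule == "burst"
    assert (scan.hole_counts[:c.index] > 0).any()
    assert scan.hole_counts[c.index] == 0
    blocks = [r for r in scan.partition_at(c.index).runs if r[1] > r[0]]
    assert blocks == truth.fixation_intervals()


def test_critical_threshold_levels_are_ordered():
    from itop.simulate import preset_config
    rec, _ = simulate_gaze(preset_config("abcdec", 0))
    scan = scan_thresholds(build_distance_matrix(rec))
    c1 = find_critical_threshold(scan, 1)
    c2 = find_critical_threshold(scan, 2)
    assert c1.tc < c2.tc


def test_find_critical_threshold_rejects_bad_level(six_sample_recording):
    scan = scan_thresholds(build_distance_matrix(six_sample_recording))
    with pytest.raises(ValueError):
        find_critical_threshold(scan, 3)
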
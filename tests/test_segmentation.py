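import numpy as np
import pytest

import itop
from itop.matrix import build_distance_matrix
from itop.topology import scan_thresholds
from itop.segmentation import (
    detect_fixations, detect_dwells,
    COHERENT, TRANSITION_GAP, DATA_LOSS_GAP,
)
from itop.simulate import SimulationConfig, simulate_gaze, preset_config
from itop.io import events_to_frame

from conftest import make_recording


def assert_tiling(result, level, n):
    events = result.levels[level].events
    covered = []
    for e in events:
        covered.extend(range(e.onset_index, e.offset_index + 1))
    assert covered == list(range(n)), "events of one level must tile [0, n-1]"


def test_identical_samples_yield_one_fixation_and_no_gaps():
    rec = make_recording([(3, 3)] * 20)
    result, scan = detect_fixations(rec)
    assert [(e.kind, e.onset_index, e.offset_index)
            for e in result.levels[1].events] == [(COHERENT, 0, 19)]
    assert result.fixations[0].centroid == pytest.approx((3.0, 3.0))


def test_planted_fixations_are_recovered_with_tight_boundaries():
    cfg = SimulationConfig(seed=11, n_fixations=5, noise_sd=0.25,
                           min_separation=3.0, fixation_duration=(20, 30),
                           id="plant5")
    rec, truth = simulate_gaze(cfg)
    result, _ = detect_fixations(rec)
    got = [(f.onset_index, f.offset_index) for f in result.fixations]
    want = truth.fixation_intervals()
    assert len(got) == 5
    for (a, b), (ta, tb) in zip(got, want):
        assert abs(a - ta) <= 2 and abs(b - tb) <= 2
    assert_tiling(result, 1, rec.n)


def test_loss_gap_splits_a_fixation_without_interpolation():
    rec, truth = simulate_gaze(preset_config("loss", 0))
    result, scan = detect_fixations(rec)
    kinds = [e.kind for e in result.levels[1].events]
    assert kinds == [COHERENT, DATA_LOSS_GAP, COHERENT]
    gap = result.levels[1].events[1]
    assert (~rec.valid[gap.onset_index:gap.offset_index + 1]).all()
    assert gap.n_samples == 10
    # the no-gap-filling contract: invalid samples stay NaN, none are added
    assert rec.n == len(truth.sample_kind)
    assert np.isnan(rec.positions[~rec.valid]).all()


def test_gap_kinds_distinguish_transit_from_loss():
    cfg = SimulationConfig(seed=5, fixation_centers=[(0, 0), (8, 0)],
                           fixation_duration=20, noise_sd=0.15,
                           transit_samples=3, id="kinds")
    rec, _ = simulate_gaze(cfg)
    result, _ = detect_fixations(rec)
    kinds = [e.kind for e in result.levels[1].events]
    assert kinds == [COHERENT, TRANSITION_GAP, COHERENT]
    assert_tiling(result, 1, rec.n)


def test_merge_tree_single_leaf_and_temporal_order():
    rec = make_recording([(0, 0)] * 10)
    result, scan = detect_fixations(rec)
    assert result.merge_tree.is_leaf
    rec2, _ = simulate_gaze(SimulationConfig(
        seed=2, n_fixations=4, noise_sd=0.2, fixation_duration=(15, 20),
        id="tree"))
    res2, _ = detect_fixations(rec2)
    assert res2.merge_tree.leaves() == list(range(len(res2.fixations)))


def test_merge_tree_two_cluster_example(six_sample_recording):
    """The two 3-sample blocks join when a bridging distance enters.

    The nearest cross pair is 10 apart, but under 4-connectivity a single
    cross pixel attaches to one block only; the runs fuse at sqrt(101),
    confirmed by the naive per-threshold oracle scan.
    """
    result, scan = detect_fixations(six_sample_recording)
    tree = result.merge_tree
    assert not tree.is_leaf
    assert [c.is_leaf for c in tree.children] == [True, True]
    assert tree.threshold == pytest.approx(np.sqrt(101.0))
    D = build_distance_matrix(six_sample_recording)
    naive = scan_thresholds(D, "naive")
    merged = [e for e in naive.partition_events if ((0, 5),) == e.runs]
    assert naive.thresholds[merged[0].index] == pytest.approx(np.sqrt(101.0))


def test_merge_thresholds_do_not_decrease_toward_root():
    rec, _ = simulate_gaze(SimulationConfig(
        seed=9, n_fixations=6, noise_sd=0.25, fixation_duration=(15, 25),
        id="mono"))
    result, _ = detect_fixations(rec)

    def check(node, bound=np.inf):
        if node.is_leaf:
            return
        assert node.threshold <= bound + 1e-12
        for c in node.children:
            check(c, node.threshold)

    check(result.merge_tree)


def test_dwell_visits_group_the_abcdec_construction():
    rec, truth = simulate_gaze(preset_config("abcdec", 3))
    result, scan = detect_fixations(rec)
    detect_dwells(rec, result, scan)
    visits = result.levels[2].coherent_events
    assert len(visits) == 3
    # visit membership: fixations 0-2, 3-4, 5
    member = []
    for v in visits:
        member.append([i for i, f in enumerate(result.fixations)
                       if v.onset_index <= f.onset_index <= v.offset_index])
    assert member == [[0, 1, 2], [3, 4], [5]]
    assert_tiling(result, 2, rec.n)


def test_single_tight_cluster_gives_a_single_visit():
    cfg = SimulationConfig(seed=4, fixation_centers=[(0, 0), (1.5, 0), (0.7, 1.2)],
                           fixation_duration=25, noise_sd=0.15,
                           id="cluster")
    rec, _ = simulate_gaze(cfg)
    result, scan = detect_fixations(rec)
    detect_dwells(rec, result, scan)
    if result.levels[2].present:
        assert len(result.levels[2].coherent_events) == 1


def test_two_separated_groups_give_two_visits():
    centers = [(0, 0), (3, 0), (1.5, 2.5), (20, 0), (23, 0), (21.5, 2.5)]
    cfg = SimulationConfig(seed=6, fixation_centers=centers,
                           fixation_duration=(20, 30), noise_sd=0.3,
                           dwell_groups=[1, 1, 1, 2, 2, 2], id="groups")
    rec, truth = simulate_gaze(cfg)
    result, scan = detect_fixations(rec)
    detect_dwells(rec, result, scan)
    assert result.levels[2].present
    visits = result.levels[2].coherent_events
    assert len(visits) == 2
    assert visits[0].offset_index < visits[1].onset_index


def test_every_fixation_nests_in_exactly_one_visit():
    for seed in range(3):
        rec, _ = simulate_gaze(preset_config("abcdec", seed))
        result, scan = detect_fixations(rec)
        detect_dwells(rec, result, scan)
        assert result.levels[1].tc < result.levels[2].tc
        for f in result.fixations:
            owners = [v for v in result.levels[2].coherent_events
                      if v.onset_index <= f.onset_index
                      and f.offset_index <= v.offset_index]
            assert len(owners) == 1


def test_rigid_motion_leaves_all_integer_fields_identical():
    rec, _ = simulate_gaze(SimulationConfig(
        seed=13, n_fixations=4, noise_sd=0.3, fixation_duration=(15, 25),
        id="rigid"))
    base, _, sp = itop.segment(rec)
    theta = 2.1
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    moved = make_recording(rec.positions @ R.T + np.array([-55.0, 13.0]),
                           valid=rec.valid, rate=rec.sampling_rate,
                           rid=rec.id)
    got, _, sp2 = itop.segment(moved)
    a = events_to_frame(base).drop(columns=["centroid_x", "centroid_y"])
    b = events_to_frame(got).drop(columns=["centroid_x", "centroid_y"])
    assert a.equals(b)
    assert sp.string_form == sp2.string_form


def test_time_reversal_mirrors_the_segmentation_exactly():
    rec, _ = simulate_gaze(SimulationConfig(
        seed=17, n_fixations=4, noise_sd=0.25, fixation_duration=(15, 25),
        id="rev"))
    fwd, _ = detect_fixations(rec)
    bwd, _ = detect_fixations(rec.reversed())
    n = rec.n
    mirrored = [(n - 1 - b, n - 1 - a) for a, b in reversed(
        [(f.onset_index, f.offset_index) for f in bwd.fixations])]
    assert mirrored == [(f.onset_index, f.offset_index)
                        for f in fwd.fixations]


def test_detect_requires_valid_samples():
    rec = make_recording(np.full((3, 2), np.nan), valid=[False] * 3)
    with pytest.raises(ValueError):
        detect_fixations(rec)


def test_detect_dwells_requires_level_one():
    rec = make_recording([(0, 0)] * 5)
    result, scan = detect_fixations(rec)
    result.levels.pop(1)
    with pytest.raises(ValueError):
        detect_dwells(rec, result, scan)
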
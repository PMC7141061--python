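"""itop — parameter-free topological segmentation of raw gaze trajectories.

The trajectory is represented as the time-indexed matrix of all
combinatorial 2-point distances; a threshold filtration of that matrix,
monitored through connected components and holes of the binary mask, yields
the critical coherence thresholds that segment the recording into fixations
(level 1) and dwell visits (level 2), plus recurrence structure and
scanpath strings — with no smoothing, gap filling, velocity thresholds or
post-hoc event merging.
"""

from __future__ import annotations

from .recording import GazeRecording, GazeSample
from .metrics import (
    Metric, EUCLIDEAN, DISCRETE, RGB,
    euclidean_distance, discrete_distance, rgb_distance,
    check_metric_axioms, get_metric,
)
from .matrix import DistanceMatrix, build_distance_matrix, render_distance_image
from .topology import (
    BinaryMask, ComponentLabeling, ThresholdScan, CriticalThreshold,
    threshold_filter, label_components, count_holes,
    coherence_statistic, scan_thresholds, find_critical_threshold,
)
from .segmentation import (
    EventRecord, SegmentationResult, MergeNode,
    detect_fixations, detect_dwells, build_merge_tree,
)
from .scanpath import (
    ScanpathMatrix, label_recurrences, scanpath_string, dwell_string,
    coupling_matrix,
)
from .simulate import SimulationConfig, GroundTruth, simulate_gaze, preset_config
from .io import (
    read_gaze_recording, write_events, read_events, write_hierarchy,
    read_hierarchy,
)

__version__ = "0.1.0"


def segment(
    recording: GazeRecording,
    metric: Metric = EUCLIDEAN,
    levels: int = 2,
    stability: int = 1,
):
    """Run the full pipeline on a recording.

    Returns ``(result, scan, scanpath)`` where ``result`` holds the level-1
    fixations (and level-2 dwell visits when ``levels >= 2`` and a second
    coherence scale exists), ``scan`` the threshold filtration record, and
    ``scanpath`` the coupling matrix with the string encodings (None when
    the recording yields no fixation).
    """
    result, scan = detect_fixations(recording, metric, stability)
    if levels >= 2 and result.levels[1].present and result.fixations:
        detect_dwells(recording, result, scan, stability)
    sp = None
    if result.levels[1].present and result.fixations:
        sp = coupling_matrix(result)
    return result, scan, sp
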
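"""From critical thresholds to events: fixations, merge tree, dwell visits.

Level 1: at tc(1) every diagonal run of >= 2 samples is a fixation (a single
sample carries no 2-point coherence, so isolated transit samples fall into
the surrounding gap — consistent with event tables that report gaps across
the saccadic samples).  Index ranges between fixations are gaps, classified
as data-loss gaps when they contain any invalid sample and transition gaps
otherwise.  There is no minimum-duration filter beyond the 2-sample
coherence requirement, no merging and no smoothing.

Level 2: the same extraction at tc(2) yields the dwell visits; a visit is
the time interval spanned by the whole level-1 fixations its block contains
(internal gaps included).  Blocks at tc(2) containing no fixation are gap
time at level 2 as well.

The merge tree records, for the level-1 fixations, the thresholds at which
their blocks coalesce — the scaling hierarchy of the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .matrix import build_distance_matrix, DistanceMatrix
from .metrics import Metric, EUCLIDEAN
from .recording import GazeRecording
from .topology import (
    ThresholdScan,
    CriticalThreshold,
    scan_thresholds,
    find_critical_threshold,
)

__all__ = [
    "EventRecord",
    "LevelResult",
    "MergeNode",
    "SegmentationResult",
    "detect_fixations",
    "detect_dwells",
    "build_merge_tree",
    "extract_level",
]

COHERENT = "coherent-event"
TRANSITION_GAP = "transition-gap"
DATA_LOSS_GAP = "data-loss-gap"

#: A coherent block needs at least one off-diagonal foreground pixel,
#: i.e. two samples.
MIN_EVENT_SAMPLES = 2


@dataclass
class EventRecord:
    """One event of the per-sample event table (inclusive sample bounds)."""

    level: int
    kind: str
    onset_index: int
    offset_index: int
    onset_ms: float
    offset_ms: float
    centroid: tuple[float, float] | None = None
    label: str | None = None
    dwell_id: int | None = None

    @property
    def n_samples(self) -> int:
        return self.offset_index - self.onset_index + 1


@dataclass
class LevelResult:
    level: int
    present: bool
    tc: float | None
    rule: str
    events: list[EventRecord] = field(default_factory=list)

    @property
    def coherent_events(self) -> list[EventRecord]:
        return [e for e in self.events if e.kind == COHERENT]


@dataclass
class MergeNode:
    """Dendrogram node over level-1 fixations.

    Leaves carry ``fixation`` (temporal fixation index); internal nodes carry
    the smallest threshold at which their children's blocks lie in a single
    component.  Thresholds are non-decreasing toward the root, and reading
    the leaves left to right gives temporal order.
    """

    threshold: float | None = None
    fixation: int | None = None
    children: list["MergeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.fixation is not None

    def leaves(self) -> list[int]:
        if self.is_leaf:
            return [self.fixation]
        out: list[int] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"fixation": self.fixation}
        return {
            "threshold": self.threshold,
            "children": [c.to_dict() for c in self.children],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MergeNode":
        if "fixation" in d:
            return cls(fixation=d["fixation"])
        return cls(
            threshold=d["threshold"],
            children=[cls.from_dict(c) for c in d["children"]],
        )


@dataclass
class SegmentationResult:
    recording_id: str
    sampling_rate: float
    n: int
    levels: dict[int, LevelResult] = field(default_factory=dict)
    merge_tree: MergeNode | None = None

    def level(self, k: int) -> LevelResult:
        return self.levels[k]

    @property
    def fixations(self) -> list[EventRecord]:
        return self.levels[1].coherent_events


def _ms(index: int, rate: float) -> float:
    return index / rate * 1000.0


def extract_level(
    recording: GazeRecording,
    scan: ThresholdScan,
    critical: CriticalThreshold | None,
    level: int,
) -> LevelResult:
    """Turn the diagonal partition at a critical threshold into an event list."""
    rate = recording.sampling_rate
    n = recording.n
    if critical is None:
        return LevelResult(level, False, None, "absent", [])
    runs = scan.partition_at(critical.index).runs
    blocks = [r for r in runs if r[1] - r[0] + 1 >= MIN_EVENT_SAMPLES]
    events: list[EventRecord] = []
    cursor = 0
    for a, b in blocks:
        if a > cursor:
            events.append(_gap(recording, level, cursor, a - 1))
        centroid = tuple(recording.positions[a:b + 1].mean(axis=0))
        events.append(
            EventRecord(level, COHERENT, a, b, _ms(a, rate), _ms(b, rate),
                        centroid=(float(centroid[0]), float(centroid[1])))
        )
        cursor = b + 1
    if cursor <= n - 1:
        events.append(_gap(recording, level, cursor, n - 1))
    return LevelResult(level, True, critical.tc, critical.rule, events)


def _gap(recording: GazeRecording, level: int, a: int, b: int) -> EventRecord:
    rate = recording.sampling_rate
    kind = DATA_LOSS_GAP if (~recording.valid[a:b + 1]).any() else TRANSITION_GAP
    return EventRecord(level, kind, a, b, _ms(a, rate), _ms(b, rate))


def detect_fixations(
    recording: GazeRecording,
    metric: Metric = EUCLIDEAN,
    stability: int = 1,
    D: DistanceMatrix | None = None,
    scan_method: str = "incremental",
) -> tuple[SegmentationResult, ThresholdScan]:
    """Level-1 pipeline: distance matrix -> scan -> tc(1) -> fixation blocks."""
    if not recording.valid.any():
        raise ValueError("recording has no valid samples")
    if D is None:
        D = build_distance_matrix(recording, metric)
    scan = scan_thresholds(D, method=scan_method)
    c1 = find_critical_threshold(scan, 1, stability)
    result = SegmentationResult(recording.id, recording.sampling_rate,
                                recording.n)
    result.levels[1] = extract_level(recording, scan, c1, 1)
    if result.levels[1].present and result.fixations:
        result.merge_tree = build_merge_tree(scan, result)
    return result, scan


def detect_dwells(
    recording: GazeRecording,
    result: SegmentationResult,
    scan: ThresholdScan,
    stability: int = 1,
) -> SegmentationResult:
    """Add level 2 (dwell visits) to a level-1 segmentation.

    Visits are the blocks at tc(2), expressed as intervals of whole level-1
    fixations plus their internal gaps; a block containing no fixation
    contributes gap time.  Marks level 2 absent when no second coherence
    scale can be established.
    """
    if 1 not in result.levels or not result.levels[1].present:
        raise ValueError("level-1 segmentation required first")
    c2 = find_critical_threshold(scan, 2)
    if c2 is None:
        result.levels[2] = LevelResult(2, False, None, "absent", [])
        return result
    raw = extract_level(recording, scan, c2, 2)
    fixations = result.fixations
    rate = recording.sampling_rate
    events: list[EventRecord] = []
    visit_bounds = []
    for ev in raw.coherent_events:
        inside = [f for f in fixations
                  if f.onset_index >= ev.onset_index
                  and f.offset_index <= ev.offset_index]
        if inside:
            visit_bounds.append((inside[0].onset_index,
                                 inside[-1].offset_index))
    cursor = 0
    for a, b in visit_bounds:
        if a > cursor:
            events.append(_gap(recording, 2, cursor, a - 1))
        centroid = tuple(recording.positions[a:b + 1].mean(axis=0))
        events.append(
            EventRecord(2, COHERENT, a, b, _ms(a, rate), _ms(b, rate),
                        centroid=(float(centroid[0]), float(centroid[1])))
        )
        cursor = b + 1
    if cursor <= recording.n - 1:
        events.append(_gap(recording, 2, cursor, recording.n - 1))
    result.levels[2] = LevelResult(2, True, c2.tc, c2.rule, events)
    return result


def build_merge_tree(scan: ThresholdScan, result: SegmentationResult) -> MergeNode:
    """Dendrogram of level-1 fixations over the merge thresholds of the scan.

    For each pair of temporally adjacent fixations the merge threshold is the
    smallest scanned threshold at which one diagonal run contains both; the
    tree is assembled bottom-up in threshold order (ties merge left to
    right), so thresholds are non-decreasing along every root path.
    """
    fixations = result.fixations
    k = len(fixations)
    if k == 0:
        raise ValueError("no fixations to build a tree over")
    nodes: list[MergeNode] = [MergeNode(fixation=i) for i in range(k)]
    if k == 1:
        return nodes[0]
    merge_t: list[float | None] = [None] * (k - 1)
    anchors = [f.onset_index for f in fixations]
    for ev in scan.partition_events:
        t = float(scan.thresholds[ev.index])
        for b in range(k - 1):
            if merge_t[b] is not None:
                continue
            if any(a <= anchors[b] and anchors[b + 1] <= bb
                   for a, bb in ev.runs):
                merge_t[b] = t
    last_t = float(scan.thresholds[-1])
    merge_t = [last_t if t is None else t for t in merge_t]
    # bottom-up agglomeration over the adjacency chain
    order = sorted(range(k - 1), key=lambda b: (merge_t[b], b))
    groups = list(nodes)
    bound_of = list(range(k - 1))  # boundary ids between consecutive groups
    for b in order:
        # locate the two groups flanking boundary b
        gi = 0
        while bound_of[gi] != b:
            gi += 1
        left, right = groups[gi], groups[gi + 1]
        parent = MergeNode(threshold=merge_t[b], children=[left, right])
        groups[gi:gi + 2] = [parent]
        del bound_of[gi]
    return groups[0]
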
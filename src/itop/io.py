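"""Reading raw gaze tables, writing event tables and hierarchy reports.

Input is plain delimited text (CSV/TSV), one row per sample.  Parsing never
drops a row: rows with missing or non-numeric coordinates, a false validity
flag, or (when a screen size is declared) out-of-screen coordinates become
``valid=False`` samples.  When a time column is mapped it is only used to
verify a constant sampling interval (relative jitter <= 1e-3 of the period);
all reported times derive from the sample index and the sampling rate.

Output is an events CSV with the fixed column order
``level, kind, onset_index, offset_index, onset_ms, offset_ms, centroid_x,
centroid_y, label, dwell_id`` (empty fields where not applicable) and a JSON
hierarchy report; see :data:`HIERARCHY_SCHEMA` for the report layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import GazeRecording
from .segmentation import SegmentationResult, MergeNode
from .topology import ThresholdScan

__all__ = [
    "read_gaze_recording",
    "write_events",
    "read_events",
    "events_to_frame",
    "write_hierarchy",
    "read_hierarchy",
    "EVENT_COLUMNS",
    "HIERARCHY_SCHEMA",
]

EVENT_COLUMNS = [
    "level", "kind", "onset_index", "offset_index", "onset_ms", "offset_ms",
    "centroid_x", "centroid_y", "label", "dwell_id",
]

#: JSON layout of the hierarchy report (versioned; field names are stable).
HIERARCHY_SCHEMA = {
    "schema": "itop-hierarchy/1",
    "recording_id": "str",
    "sampling_rate": "float (Hz)",
    "n": "int (samples)",
    "levels": [
        {
            "level": "int (1=fixations, 2=dwell visits)",
            "present": "bool ('absent' levels have tc=null and no events)",
            "tc": "float | null (critical threshold, metric units)",
            "rule": "'burst' | 'fallback' | 'absent'",
            "events": "event records as in the events CSV",
        }
    ],
    "scan": {
        "thresholds": "sorted unique finite distances",
        "hole_counts": "H(t) per threshold",
        "partition_changes": [
            {"threshold_index": "int", "blocks": "[[onset, offset], ...]"}
        ],
    },
    "merge_tree": "nested {threshold, children} / {fixation} dendrogram",
}


def _resolve_column(df: pd.DataFrame, key) -> pd.Series:
    if isinstance(key, int):
        if key >= df.shape[1]:
            raise ValueError(f"column position {key} out of range")
        return df.iloc[:, key]
    if key not in df.columns:
        raise ValueError(f"mapped column {key!r} not found in file")
    return df[key]


def read_gaze_recording(
    path,
    sampling_rate: float,
    column_map: dict | None = None,
    units: str = "px",
    delimiter: str | None = None,
    screen_size: tuple[float, float] | None = None,
    recording_id: str | None = None,
) -> GazeRecording:
    """Parse a delimited gaze table into a :class:`GazeRecording`.

    ``column_map`` maps the roles ``time``/``x``/``y``/``valid`` to column
    names or 0-based positions; defaults to columns named ``x``/``y`` (plus
    ``time``/``t`` and ``valid`` when present) or positional 0/1/2.  The
    delimiter is auto-detected unless given.  Raises on unreadable files,
    missing mapped columns, zero data rows and non-monotone timestamps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, engine="python")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    cmap = dict(column_map or {})
    cols_lower = {str(c).lower(): c for c in df.columns}
    if "x" not in cmap:
        cmap["x"] = cols_lower.get("x", 1)  # positional t,x,y convention
    if "y" not in cmap:
        cmap["y"] = cols_lower.get("y", 2)
    if "time" not in cmap:
        for alias in ("time", "t", "timestamp"):
            if alias in cols_lower:
                cmap["time"] = cols_lower[alias]
                break
    if "valid" not in cmap and "valid" in cols_lower:
        cmap["valid"] = cols_lower["valid"]

    x = pd.to_numeric(_resolve_column(df, cmap["x"]), errors="coerce")
    y = pd.to_numeric(_resolve_column(df, cmap["y"]), errors="coerce")
    valid = np.isfinite(x.to_numpy()) & np.isfinite(y.to_numpy())
    if "valid" in cmap:
        flag = _resolve_column(df, cmap["valid"])
        truthy = flag.map(
            lambda v: str(v).strip().lower() not in
            ("0", "0.0", "false", "f", "no", "nan", "")
        ).to_numpy()
        valid &= truthy
    if "time" in cmap:
        t = pd.to_numeric(_resolve_column(df, cmap["time"]),
                          errors="coerce").to_numpy(dtype=float)
        dt = np.diff(t)
        if len(dt) and not (dt > 0).all():
            raise ValueError(f"{path}: non-monotone timestamps")
        if len(dt):
            period = np.median(dt)
            if np.abs(dt - period).max() > 1e-3 * period:
                raise ValueError(
                    f"{path}: timestamps not equally spaced "
                    f"(jitter > 1e-3 of the sample period)"
                )
    positions = np.column_stack([x.to_numpy(float), y.to_numpy(float)])
    if screen_size is not None:
        w, h = screen_size
        inside = (
            (positions[:, 0] >= 0) & (positions[:, 0] <= w)
            & (positions[:, 1] >= 0) & (positions[:, 1] <= h)
        )
        valid &= np.where(np.isfinite(positions).all(axis=1), inside, False)
    positions[~valid] = np.nan
    return GazeRecording(
        id=recording_id or path.stem,
        positions=positions,
        valid=valid,
        sampling_rate=sampling_rate,
        units=units,
    )


def events_to_frame(result: SegmentationResult) -> pd.DataFrame:
    rows = []
    for level in sorted(result.levels):
        lres = result.levels[level]
        for e in lres.events:
            rows.append({
                "level": e.level,
                "kind": e.kind,
                "onset_index": e.onset_index,
                "offset_index": e.offset_index,
                "onset_ms": e.onset_ms,
                "offset_ms": e.offset_ms,
                "centroid_x": None if e.centroid is None else e.centroid[0],
                "centroid_y": None if e.centroid is None else e.centroid[1],
                "label": e.label,
                "dwell_id": e.dwell_id,
            })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(result: SegmentationResult, path) -> int:
    """Write the event table as CSV; returns the number of event rows."""
    if not result.levels:
        raise ValueError("result holds no levels")
    df = events_to_frame(result)
    df.to_csv(path, index=False, float_format="%.12g")
    return len(df)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_hierarchy(result: SegmentationResult, scan: ThresholdScan,
                    path) -> None:
    """Write the machine-parseable hierarchy report (JSON)."""
    if scan.recording_id != result.recording_id:
        raise ValueError(
            f"scan is for {scan.recording_id!r}, result for "
            f"{result.recording_id!r}"
        )
    doc = {
        "schema": "itop-hierarchy/1",
        "recording_id": result.recording_id,
        "sampling_rate": result.sampling_rate,
        "n": result.n,
        "levels": [
            {
                "level": lres.level,
                "present": lres.present,
                "tc": lres.tc,
                "rule": lres.rule,
                "events": json.loads(
                    events_to_frame_level(result, lres.level).to_json(
                        orient="records"
                    )
                ),
            }
            for lres in (result.levels[k] for k in sorted(result.levels))
        ],
        "scan": {
            "thresholds": scan.thresholds.tolist(),
            "hole_counts": scan.hole_counts.tolist(),
            "partition_changes": [
                {
                    "threshold_index": ev.index,
                    "blocks": [list(r) for r in ev.runs],
                }
                for ev in scan.partition_events
            ],
        },
        "merge_tree": None if result.merge_tree is None
        else result.merge_tree.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def events_to_frame_level(result: SegmentationResult, level: int) -> pd.DataFrame:
    df = events_to_frame(result)
    return df[df["level"] == level].reset_index(drop=True)


def read_hierarchy(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != "itop-hierarchy/1":
        raise ValueError("not an itop hierarchy report")
    if doc.get("merge_tree") is not None:
        doc["merge_tree_node"] = MergeNode.from_dict(doc["merge_tree"])
    return doc
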
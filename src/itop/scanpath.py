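"""Recurrence labeling and symbolic scanpath representations.

Shrinking the diagonal squares of the distance matrix to single points turns
it into the adjacency matrix of the scanpath: the off-diagonal entries are
the coupling — recurrences of fixations.  Two fixations recur when their
centroids are within tc of each other; the transitive closure of that
relation partitions the fixations into location classes, lettered A, B, C,
... by first temporal occurrence (continuing AA, AB, ... past Z).  Reading
the letters in time order gives the classical scanpath string (e.g.
"ABCDEC"); grouping them by dwell visit with a shared-location identity
numeral gives the dwell string (e.g. "(ABC)1(DE)2C1").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import SegmentationResult

__all__ = [
    "ScanpathMatrix",
    "label_recurrences",
    "scanpath_string",
    "dwell_string",
    "coupling_matrix",
    "letter_label",
]


def letter_label(i: int) -> str:
    """0 -> 'A', 25 -> 'Z', 26 -> 'AA', 27 -> 'AB', ... (bijective base 26)."""
    if i < 0:
        raise ValueError("label index must be >= 0")
    out = []
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        out.append(chr(ord("A") + r))
    return "".join(reversed(out))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def label_recurrences(
    result: SegmentationResult, tc: float | None = None
) -> tuple[list[str], np.ndarray]:
    """Assign location letters to fixations from centroid recurrence.

    coupling[i, j] is True iff the centroids of fixations i and j are within
    tc (default: the level-1 critical threshold); labels are the transitive
    closure of the coupling, lettered by first temporal occurrence.  The
    labels are written onto the level-1 event records and returned.
    """
    fixations = result.fixations
    if any(f.centroid is None for f in fixations):
        raise ValueError("fixations lack centroids")
    if tc is None:
        tc = result.levels[1].tc
    k = len(fixations)
    cents = np.array([f.centroid for f in fixations], dtype=float)
    coupling = np.zeros((k, k), dtype=bool)
    uf = _UnionFind(k)
    for i in range(k):
        coupling[i, i] = True
        for j in range(i + 1, k):
            if np.hypot(*(cents[i] - cents[j])) <= tc:
                coupling[i, j] = coupling[j, i] = True
                uf.union(i, j)
    class_letter: dict[int, str] = {}
    labels: list[str] = []
    for i in range(k):
        root = uf.find(i)
        if root not in class_letter:
            class_letter[root] = letter_label(len(class_letter))
        labels.append(class_letter[root])
    for f, lab in zip(fixations, labels):
        f.label = lab
    return labels, coupling


def scanpath_string(result: SegmentationResult) -> str:
    """Fixation labels concatenated in temporal order, one symbol each."""
    labels = [f.label for f in result.fixations]
    if any(lab is None for lab in labels):
        raise ValueError("run label_recurrences first")
    return "".join(labels)


def dwell_string(result: SegmentationResult) -> str:
    """Dwell-grouped scanpath string with dwell-identity superscript numerals.

    Each level-2 visit contributes its fixation labels (parenthesized unless
    the visit holds a single fixation) followed by its dwell identity.  Two
    visits share an identity iff their label sets intersect (transitively
    closed); identities are numbered by first occurrence.  Writes dwell ids
    onto the level-2 records and member fixations.
    """
    if 2 not in result.levels or not result.levels[2].present:
        raise ValueError("level 2 is absent; no dwell string")
    if any(f.label is None for f in result.fixations):
        raise ValueError("run label_recurrences first")
    visits = result.levels[2].coherent_events
    members = []
    for v in visits:
        labs = [f.label for f in result.fixations
                if v.onset_index <= f.onset_index
                and f.offset_index <= v.offset_index]
        members.append(labs)
    uf = _UnionFind(len(visits))
    for i in range(len(visits)):
        for j in range(i + 1, len(visits)):
            if set(members[i]) & set(members[j]):
                uf.union(i, j)
    ident: dict[int, int] = {}
    parts = []
    for i, (v, labs) in enumerate(zip(visits, members)):
        root = uf.find(i)
        if root not in ident:
            ident[root] = len(ident) + 1
        v.dwell_id = ident[root]
        for f in result.fixations:
            if v.onset_index <= f.onset_index <= v.offset_index:
                f.dwell_id = v.dwell_id
        body = "".join(labs)
        if len(labs) > 1:
            body = f"({body})"
        parts.append(f"{body}{v.dwell_id}")
    return "".join(parts)


@dataclass
class ScanpathMatrix:
    """Shrunk adjacency/coupling matrix over fixations plus string forms."""

    k: int
    coupling: np.ndarray
    labels: list[str]
    string_form: str
    dwell_string: str | None = None

    def to_frame(self) -> pd.DataFrame:
        idx = [f"{i}:{lab}" for i, lab in enumerate(self.labels)]
        return pd.DataFrame(self.coupling.astype(int), index=idx, columns=idx)


def coupling_matrix(result: SegmentationResult) -> ScanpathMatrix:
    """Boolean coupling matrix (true diagonal) with labels and strings."""
    labels, coupling = label_recurrences(result)
    ds = None
    if 2 in result.levels and result.levels[2].present:
        ds = dwell_string(result)
    return ScanpathMatrix(
        k=len(labels),
        coupling=coupling,
        labels=labels,
        string_form=scanpath_string(result),
        dwell_string=ds,
    )
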
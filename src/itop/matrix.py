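"""The time-indexed matrix D of all combinatorial 2-point distances.

Entry (i, j) is the metric distance between samples i and j; the full matrix
is the maximal-window generalization of dispersion algorithms and the basis
of the whole analysis.  It is invariant under rigid motions of the stimulus
plane (distances are the invariants of Euclidean geometry).  Pairs involving
an invalid sample carry an infinite sentinel: data loss is never allowed to
fabricate coherence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .metrics import Metric, EUCLIDEAN
from .recording import GazeRecording

__all__ = ["DistanceMatrix", "build_distance_matrix", "render_distance_image",
           "SENTINEL_GRAY"]

#: Gray level used for sentinel (invalid-pair) pixels in raw-mode renderings.
SENTINEL_GRAY = 127


@dataclass
class DistanceMatrix:
    """Symmetric n x n distance grid with ``inf`` sentinel for invalid pairs."""

    values: np.ndarray
    valid: np.ndarray
    units: str
    recording_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("values must be a square matrix")
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != (self.n,):
            raise ValueError("valid must have one flag per sample")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def finite_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]

    @property
    def max_finite(self) -> float:
        fin = self.finite_values
        return float(fin.max()) if fin.size else 0.0


def build_distance_matrix(
    recording: GazeRecording,
    metric: Metric = EUCLIDEAN,
    features: np.ndarray | None = None,
) -> DistanceMatrix:
    """Compute all combinatorial 2-point distances of a recording.

    ``features`` overrides the per-sample feature vectors (default: the 2D
    positions), which is how the analysis is moved into an abstract feature
    space.  Entries touching an invalid sample are the ``inf`` sentinel; the
    diagonal of valid samples is exactly zero.
    """
    if recording.n < 1:
        raise ValueError("empty recording")
    feats = recording.positions if features is None else np.asarray(features)
    if feats.shape[0] != recording.n:
        raise ValueError("one feature vector per sample required")
    n = recording.n
    valid = recording.valid
    if metric.pairwise is not None:
        safe = np.where(valid[:, None], feats, 0.0)
        vals = np.asarray(metric.pairwise(safe), dtype=float)
        if vals.shape != (n, n):
            raise ValueError("metric.pairwise returned a non (n, n) matrix")
    else:
        vals = np.zeros((n, n))
        idx = np.nonzero(valid)[0]
        for a, i in enumerate(idx):
            for j in idx[a + 1:]:
                vals[i, j] = vals[j, i] = metric.distance(feats[i], feats[j])
    if not np.isfinite(vals[np.ix_(valid, valid)]).all():
        raise ValueError("metric produced a non-finite distance on valid samples")
    invalid = ~valid
    vals[invalid, :] = np.inf
    vals[:, invalid] = np.inf
    np.fill_diagonal(vals, np.where(valid, 0.0, np.inf))
    # enforce exact symmetry against metric round-off
    iu = np.triu_indices(n, 1)
    vals[(iu[1], iu[0])] = vals[iu]
    return DistanceMatrix(vals, valid.copy(), recording.units, recording.id)


def render_distance_image(
    D: DistanceMatrix,
    mode: str = "raw",
    threshold: float | None = None,
    path=None,
) -> tuple[int, int]:
    """Render img(D) as an n x n grayscale PNG; returns (height, width).

    raw mode
        Linear min-max gray mapping over the finite entries: distance 0 is
        black, the maximum finite distance white, so brightness increases
        monotonically with distance (short within-fixation distances are near
        black, wide saccadic jumps bright).  Sentinel pixels are drawn at the
        fixed mid-gray :data:`SENTINEL_GRAY`.
    filtered mode
        The binary mask of the threshold filtration: foreground
        (distance <= threshold) white, background black.  Sentinel pixels are
        always background.
    """
    vals = D.values
    finite = np.isfinite(vals)
    if mode == "raw":
        dmax = D.max_finite
        img = np.full(vals.shape, SENTINEL_GRAY, dtype=np.uint8)
        if dmax > 0:
            img[finite] = np.round(255.0 * vals[finite] / dmax).astype(np.uint8)
        else:
            img[finite] = 0
    elif mode == "filtered":
        if threshold is None:
            raise ValueError("filtered mode requires a threshold")
        if threshold < 0:
            raise ValueError("threshold must be >= 0")
        img = np.where(finite & (vals <= threshold), 255, 0).astype(np.uint8)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if path is not None:
        Image.fromarray(img, mode="L").save(path, format="PNG")
    return img.shape
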
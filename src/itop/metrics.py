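"""Distance functions parameterizing the trajectory representation.

The segmentation core never inspects coordinates — it only consumes pairwise
distances.  Swapping the metric therefore moves the whole analysis into a
different feature space (display plane, color space, any user-supplied
feature space) for free.  Every metric must satisfy the usual axioms:
positiveness (d(x,y) >= 0, = 0 iff x = y), symmetry, and the triangle
inequality; :func:`check_metric_axioms` tests them on random triples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Metric",
    "EUCLIDEAN",
    "DISCRETE",
    "RGB",
    "euclidean_distance",
    "discrete_distance",
    "rgb_distance",
    "check_metric_axioms",
    "get_metric",
]


@dataclass(frozen=True)
class Metric:
    """A named distance function over per-sample feature values.

    ``pairwise``, when given, is a vectorized fast path mapping an (n, d)
    feature array to the full (n, n) distance matrix; it must agree with
    ``distance`` element-wise.
    """

    name: str
    distance: Callable[[Any, Any], float]
    feature_dim: int = 2
    pairwise: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False
    )


def euclidean_distance(p, q) -> float:
    """Planar Euclidean distance between two display-space points."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise ValueError("euclidean_distance requires finite coordinates")
    return float(np.hypot(*(p - q))) if p.shape == (2,) else float(
        np.linalg.norm(p - q)
    )


def discrete_distance(x, y) -> float:
    """The structure-free metric: 0 iff the values are equal, else 1."""
    eq = np.array_equal(np.asarray(x), np.asarray(y))
    return 0.0 if eq else 1.0


def rgb_distance(c1, c2) -> float:
    """Euclidean distance between two RGB triples with components in [0, 255]."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    for c in (c1, c2):
        if c.shape != (3,):
            raise ValueError("rgb_distance expects RGB triples")
        if (c < 0).any() or (c > 255).any():
            raise ValueError("RGB components must lie in [0, 255]")
    return float(np.linalg.norm(c1 - c2))


def _pairwise_euclidean(x: np.ndarray) -> np.ndarray:
    return cdist(x, x)


def _pairwise_discrete(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim == 1:
        x = x[:, None]
    eq = (x[:, None, :] == x[None, :, :]).all(axis=2)
    return (~eq).astype(float)


EUCLIDEAN = Metric("euclidean", euclidean_distance, 2, _pairwise_euclidean)
DISCRETE = Metric("discrete", discrete_distance, 1, _pairwise_discrete)
RGB = Metric("rgb", rgb_distance, 3, _pairwise_euclidean)

_REGISTRY = {m.name: m for m in (EUCLIDEAN, DISCRETE, RGB)}


def get_metric(name: str) -> Metric:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown metric {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


@dataclass(frozen=True)
class AxiomReport:
    """Outcome of randomized metric-axiom testing.

    ``failures`` maps an axiom name ("positiveness", "identity", "symmetry",
    "triangle") to the first witness tuple found against it.
    """

    passed: bool
    trials: int
    failures: dict[str, tuple]


def check_metric_axioms(
    metric: Metric, points, trials: int = 1000, seed: int = 0
) -> AxiomReport:
    """Test the metric axioms on seeded random triples from ``points``.

    Deterministic under a fixed seed.  Returns the first counterexample per
    axiom, if any.  Requires at least 3 points and ``trials >= 1``.
    """
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("need at least 3 points to test the axioms")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    failures: dict[str, tuple] = {}
    tol = 1e-9
    for _ in range(trials):
        i, j, k = rng.integers(0, len(pts), size=3)
        x, y, z = pts[i], pts[j], pts[k]
        dxy = metric.distance(x, y)
        dyx = metric.distance(y, x)
        dxz = metric.distance(x, z)
        dzy = metric.distance(z, y)
        if "positiveness" not in failures:
            same = np.array_equal(np.asarray(x), np.asarray(y))
            if dxy < 0 or (same and abs(dxy) > tol) or (not same and dxy <= 0):
                failures["positiveness"] = (x, y, dxy)
        if "symmetry" not in failures and not math.isclose(
            dxy, dyx, rel_tol=tol, abs_tol=tol
        ):
            failures["symmetry"] = (x, y, dxy, dyx)
        if "triangle" not in failures and dxy > dxz + dzy + tol * (
            1 + abs(dxz) + abs(dzy)
        ):
            failures["triangle"] = (x, y, z, dxy, dxz, dzy)
    return AxiomReport(passed=not failures, trials=trials, failures=failures)
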
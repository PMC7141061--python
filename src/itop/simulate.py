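"""Synthetic gaze recordings with exact ground truth.

The generator emulates the structure the segmentation assumes: temporally
contiguous fixations with small isotropic Gaussian positional noise (and
optional linear drift), short saccadic transits with linearly interpolated
positions (optionally followed by a damped post-saccadic oscillation),
revisits of earlier locations, and data-loss gaps.  Fixational movement is
only qualitatively "random-like", so the simplest exchangeable model —
isotropic Gaussian scatter about a center — is used; transit kinematics are
irrelevant to a purely distance-based detector, so transits are plain
linear interpolants.  All randomness flows through one seeded generator:
a fixed seed reproduces the recording byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import GazeRecording

__all__ = [
    "SimulationConfig",
    "TrueEvent",
    "GroundTruth",
    "simulate_gaze",
    "preset_config",
    "PRESETS",
]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic recording.

    Units are display units (arbitrary; think degrees-scale numbers).
    When ``fixation_centers`` is None, ``n_fixations`` centers are placed
    uniformly in a ``field_size``-sided square, rejection-sampled to keep
    every pairwise separation >= ``min_separation``.
    ``fixation_duration`` is either a fixed sample count or an inclusive
    (lo, hi) range sampled per fixation.  ``revisit_plan`` is a visit order
    over the centers (enables recurrences); ``dwell_groups`` optionally
    gives the ground-truth dwell group per visit.  ``loss_gaps`` are
    (onset, length) stretches marked invalid.
    """

    seed: int = 0
    sampling_rate: float = 500.0
    fixation_centers: list[tuple[float, float]] | None = None
    n_fixations: int = 5
    min_separation: float = 3.0
    field_size: float = 15.0
    fixation_duration: int | tuple[int, int] = (20, 45)
    fixation_durations: list[int] | None = None  # explicit per-visit override
    noise_sd: float = 0.3
    drift_rate: float = 0.0
    transit_samples: int = 0
    pso_amplitude: float = 0.0
    pso_cycles: float = 0.0
    pso_samples: int = 0
    revisit_plan: list[int] | None = None
    dwell_groups: list[int] | None = None
    loss_gaps: list[tuple[int, int]] = field(default_factory=list)
    units: str = "px"
    id: str = "sim"


@dataclass
class TrueEvent:
    kind: str  # "fixation" | "transit"
    onset: int
    offset: int
    center: tuple[float, float] | None = None
    visit_index: int | None = None
    dwell_group: int | None = None


@dataclass
class GroundTruth:
    """Exactly what was generated: per-sample ids and per-event intervals."""

    sample_event: np.ndarray  # (n,) index into events
    sample_kind: list[str]
    events: list[TrueEvent]
    config: SimulationConfig

    def fixation_intervals(self) -> list[tuple[int, int]]:
        return [(e.onset, e.offset) for e in self.events if e.kind == "fixation"]


def _draw_centers(rng, cfg: SimulationConfig) -> list[np.ndarray]:
    if cfg.fixation_centers is not None:
        return [np.asarray(c, dtype=float) for c in cfg.fixation_centers]
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < cfg.n_fixations:
        c = rng.uniform(0, cfg.field_size, 2)
        if all(np.linalg.norm(c - o) >= cfg.min_separation for o in centers):
            centers.append(c)
        attempts += 1
        if attempts > 100000:
            raise ValueError("cannot place centers at this separation/field size")
    return centers


def _duration(rng, cfg: SimulationConfig) -> int:
    if isinstance(cfg.fixation_duration, tuple):
        lo, hi = cfg.fixation_duration
        return int(rng.integers(lo, hi + 1))
    return int(cfg.fixation_duration)


def simulate_gaze(cfg: SimulationConfig) -> tuple[GazeRecording, GroundTruth]:
    """Generate one recording and its exact ground truth."""
    rng = np.random.default_rng(cfg.seed)
    centers = _draw_centers(rng, cfg)
    plan = cfg.revisit_plan if cfg.revisit_plan is not None else list(
        range(len(centers))
    )
    if not plan:
        raise ValueError("need at least one fixation visit")
    chunks: list[np.ndarray] = []
    events: list[TrueEvent] = []
    sample_kind: list[str] = []
    sample_event: list[int] = []
    pos_cursor = 0

    def push(kind, block, center=None, visit=None, group=None):
        nonlocal pos_cursor
        onset = pos_cursor
        offset = onset + len(block) - 1
        chunks.append(block)
        events.append(TrueEvent(kind, onset, offset, center, visit, group))
        sample_kind.extend([kind] * len(block))
        sample_event.extend([len(events) - 1] * len(block))
        pos_cursor = offset + 1

    for v, ci in enumerate(plan):
        center = centers[ci]
        if cfg.fixation_durations is not None:
            dur = int(cfg.fixation_durations[v])
        else:
            dur = _duration(rng, cfg)
        if dur < 1:
            raise ValueError("fixation durations must be positive")
        block = center + rng.normal(0.0, cfg.noise_sd, (dur, 2))
        if cfg.drift_rate > 0:
            direction = rng.normal(size=2)
            direction /= np.linalg.norm(direction)
            block += np.outer(np.arange(dur) * cfg.drift_rate, direction)
        group = cfg.dwell_groups[v] if cfg.dwell_groups is not None else None
        push("fixation", block, tuple(center), v, group)
        if v < len(plan) - 1:
            nxt = centers[plan[v + 1]]
            if cfg.transit_samples > 0:
                frac = np.arange(1, cfg.transit_samples + 1) / (
                    cfg.transit_samples + 1
                )
                trans = center[None, :] + frac[:, None] * (nxt - center)[None, :]
                push("transit", trans)
            if cfg.pso_samples > 0 and cfg.pso_amplitude > 0:
                tau = np.arange(1, cfg.pso_samples + 1) / cfg.pso_samples
                direction = nxt - center
                direction = direction / np.linalg.norm(direction)
                wobble = (cfg.pso_amplitude * np.exp(-3 * tau)
                          * np.cos(2 * np.pi * cfg.pso_cycles * tau))
                push("transit", nxt[None, :] + np.outer(wobble, direction))

    positions = np.vstack(chunks)
    n = len(positions)
    valid = np.ones(n, dtype=bool)
    occupied = np.zeros(n, dtype=bool)
    for onset, length in cfg.loss_gaps:
        if length < 1 or onset < 0 or onset + length > n:
            raise ValueError(f"loss gap ({onset}, {length}) out of range")
        if occupied[onset:onset + length].any():
            raise ValueError("overlapping loss gaps")
        occupied[onset:onset + length] = True
        valid[onset:onset + length] = False
    positions = positions.copy()
    positions[~valid] = np.nan
    recording = GazeRecording(
        id=f"{cfg.id}-seed{cfg.seed}",
        positions=positions,
        valid=valid,
        sampling_rate=cfg.sampling_rate,
        units=cfg.units,
    )
    truth = GroundTruth(
        sample_event=np.asarray(sample_event),
        sample_kind=sample_kind,
        events=events,
        config=cfg,
    )
    return recording, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _abcdec_config(seed: int) -> SimulationConfig:
    # Five locations: an equilateral-ish proximate triple (pairwise 2 units),
    # a proximate pair (2 units), the two groups >= 10 units apart; visit
    # order revisits the third location last.
    centers = [(0.0, 0.0), (2.0, 0.0), (1.0, 1.7),
               (12.0, 0.0), (14.0, 0.0)]
    return SimulationConfig(
        seed=seed,
        fixation_centers=centers,
        revisit_plan=[0, 1, 2, 3, 4, 2],
        dwell_groups=[1, 1, 1, 2, 2, 1],
        fixation_duration=30,
        noise_sd=0.1,
        transit_samples=2,
        id="abcdec",
    )


PRESETS = {
    # low-noise, well separated, no transit samples
    "clean": lambda seed: SimulationConfig(
        seed=seed, n_fixations=5, noise_sd=0.05, min_separation=3.0,
        fixation_duration=40, id="clean",
    ),
    # the parameter-recovery conditions: 3-8 fixations, noise sd 0.3,
    # center separation >= 3 units
    "noisy": lambda seed: SimulationConfig(
        seed=seed,
        n_fixations=int(np.random.default_rng(seed).integers(3, 9)),
        noise_sd=0.3, min_separation=3.0, fixation_duration=(20, 45),
        id="noisy",
    ),
    # the worked dwell-hierarchy example
    "abcdec": _abcdec_config,
    # one fixation interrupted by a 10-sample data-loss gap
    "loss": lambda seed: SimulationConfig(
        seed=seed, fixation_centers=[(5.0, 5.0)], fixation_duration=100,
        noise_sd=0.2, loss_gaps=[(45, 10)], id="loss",
    ),
    # exactly 633 samples (93 + 6 x 90) for the matrix-dimension example
    "matrix-demo": lambda seed: SimulationConfig(
        seed=seed, n_fixations=7, noise_sd=0.3, min_separation=3.0,
        fixation_durations=[93, 90, 90, 90, 90, 90, 90], id="matrix-demo",
    ),
}


def preset_config(name: str, seed: int = 0) -> SimulationConfig:
    try:
        return PRESETS[name](seed)
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
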
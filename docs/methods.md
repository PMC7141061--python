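# Methods

## The model

A gaze recording is treated as a *protocol*: an ordered sequence of points
of regard P_0, ..., P_{n-1} sampled at a constant rate, so that time is a
pure ordering parameter (the sample index).  The central representation is
the time-indexed matrix **D** of all combinatorial 2-point distances,
d_ij = d(P_i, P_j) — the maximal-window generalization of dispersion
algorithms.  Because only distances enter, the representation (and hence
every downstream result) is invariant under rigid motions of the stimulus
plane, and the whole analysis transfers unchanged to any metric feature
space (color space, or user-supplied feature vectors) by swapping the
distance function.

Sweeping a threshold t over D yields a nested family of binary masks
("flooding a landscape"): pixel (i, j) is foreground iff d_ij is defined
and d_ij ≤ t.  Spatio-temporal structure appears as blocks: square blocks
on the diagonal are candidate events (their side length is the event
duration), off-diagonal rectangles are recurrences (revisits).  Coherence
is read off the first two Betti numbers of the mask: noise punches holes
(β1 > 0) into the forming blocks; the critical threshold tc is the smallest
t at which the block structure is hole-free again.  Fixations are the
diagonal blocks at the first such scale, dwell visits the blocks at the
second.  No velocity or dispersion threshold, duration filter, smoothing,
interpolation or post-hoc merging is applied anywhere.

### Digital topology

Foreground is 4-connected and background 8-connected.  The orientation of
this standard complementary pairing matters: diagonal pixels (i, i) and
(i+1, i+1) are corner-adjacent, so an 8-connected foreground could never
separate adjacent blocks at all.  Under the (4, 8) pairing two squares
touching at a corner are distinct components and fuse exactly when a
bridging distance enters the foreground.  A *hole* is a background
component that cannot reach the matrix border through background.  One
consequence worth noting: two diagonally adjacent interior voids coalesce
into a single hole (the background slips through the corner).

Holes are counted globally rather than per diagonal-touching component.
The off-diagonal recurrence rectangles fill at the same spatial scale as
their diagonal blocks (both reflect within-fixation scatter), so the
restriction would not change tc; globally counted holes also admit an
exact event-driven algorithm (below) without per-hole attribution, which
is ill-defined when a hole is pinched by foreground islands.

### Invalid samples

Rows with data loss (blinks, dropouts) stay in the recording with
`valid=False`; every matrix entry touching them is an infinite sentinel and
therefore permanent background.  Such full-width background bands always
reach the border, so loss can never close a hole or fabricate coherence —
it splits blocks, and re-identification across the gap is left to
recurrence labeling.

## The threshold scan

The filtration is evaluated at every realized distance value (no step size
is invented for the *record*): `scan_thresholds` returns H(t) — the number
of enclosed background regions — and the diagonal block partition at each
of the O(n²) unique distances.  Two independent routes exist and must agree
exactly:

* **naive** — at each threshold, rebuild the mask and run connected-
  component labeling (scikit-image) for foreground components and
  border-flooded background; this is the oracle;
* **incremental** — two union-find sweeps over pixels sorted by distance:
  ascending for the foreground partition (pixels only ever appear), and
  *descending* for holes (background pixels only ever appear as t drops;
  a virtual border ring tracks which background components can escape).
  This makes the exact scan O(n² α(n²)) instead of O(n⁴).

## Critical-threshold detection

**Burst rule** (the generic case).  Incoherence must first appear
(H > 0); the threshold is then raised *in steps of 1% of the maximum
realized distance* until an inspection step with H = 0 is found and
confirmed by `stability` further hole-free steps (default 1).  tc is then
refined downward to the exact start of that hole-free run of thresholds,
so the reported tc is still an exact realized distance, not a grid value.

The coarse inspection grid is essential, not an optimization.  The exact
H(t) signal exhibits transient hole-free dips at the sub-fixation scale:
fixational scatter forms solid micro-blocks whose structure is
topologically self-similar to the fixation scale, and between the birth of
the first micro-hole and the full speckle phase H can touch zero.  Measured
on the synthetic conditions used throughout (noise sd 0.3, separation 3),
these dips are at most ~0.6% of the distance range wide, while genuine
coherence windows span ≥ 8% of it.  A 1% grid with one confirming step
therefore never resolves a dip but always lands at least two points inside
a true window; both margins are comfortable.  Purely local alternatives
(stability windows counted in thresholds, solidity tests of the blocks)
were evaluated and fail, precisely because the micro-blocks are genuinely
solid and the dip length in threshold counts overlaps that of true windows.

Level 2 applies the same rule to the part of the scan beyond tc(1): holes
must reappear (the merging of proximate blocks punches new ones) and close
again.  By mask nestedness every level-1 block lies inside exactly one
level-2 block, and tc(1) < tc(2) whenever both exist.

**Persistence fallback** (hole-free data, e.g. noise-free simulations).
When no incoherence burst exists the hole criterion is vacuous and the
scale must be chosen by persistence: among plateaus — maximal threshold
intervals with H = 0 and an unchanged partition — the one maximizing
t_end / t_start is selected (a plateau starting at 0 is scored with the
smallest positive threshold; ties prefer the smaller t_start).  On
noise-free data with a *single* separation scale this provably recovers
the planted fixations; with several distinct separation scales the most
persistent partition may legitimately be a coarser grouping.  This is an
inherent property of parameter-free scale selection on degenerate input —
real recordings always carry the noise that defines the fixation scale —
and is documented rather than patched.

## Events

At tc, every maximal contiguous diagonal run of a foreground component
with **≥ 2 samples** becomes a coherent event; a single sample carries no
2-point coherence, so isolated saccadic transit samples fall into the
surrounding gap rather than forming one-sample "fixations" (consistent
with event tables whose gaps span the transit samples).  Index ranges
between events are gaps — `data-loss-gap` when they contain an invalid
sample, `transition-gap` otherwise — so each level tiles [0, n-1] exactly.
A fixation's representative point is the unweighted centroid of its member
samples.  Level-2 visits are expressed as intervals of whole level-1
fixations (internal gaps included); a level-2 block containing no fixation
contributes gap time.  The merge tree records, per adjacent fixation pair,
the smallest scanned threshold at which one diagonal run contains both,
agglomerated bottom-up so thresholds never decrease toward the root.

## Scanpath encodings

Shrinking the diagonal blocks to points turns D into the adjacency matrix
of the scanpath.  Two fixations *recur* when their centroids are within
tc(1); labels are the transitive closure of this coupling, lettered A, B,
C, ... by first temporal occurrence (AA, AB, ... past Z).  The scanpath
string concatenates the labels in time order (e.g. `ABCDEC`); the dwell
string groups them per level-2 visit with a dwell-identity numeral, two
visits sharing an identity iff their label sets intersect (e.g.
`(ABC)1(DE)2C1`).  A full-rectangle foreground test instead of the
centroid rule would be strictly harder to satisfy and already breaks the
six-fixation revisit construction at realistic noise, which is why the
shrunk-block (centroid) reading is used.

## Synthetic data

The generator emulates exactly the structure the detector assumes:

| parameter | default | meaning |
|---|---|---|
| `noise_sd` | 0.3 units | isotropic Gaussian scatter within a fixation |
| `min_separation` | 3 units | smallest center distance (rejection sampling) |
| `fixation_duration` | 20–45 samples | per-fixation duration range |
| `transit_samples` | 0 | linearly interpolated samples per saccade |
| `drift_rate` | 0 | optional linear drift within fixations |
| `pso_amplitude/cycles/samples` | 0 | optional damped post-saccadic wobble |
| `sampling_rate` | 500 Hz | converts indices to milliseconds only |

Units are arbitrary display units; with the defaults they read naturally
as degrees.  Fixational movement is modeled as exchangeable Gaussian
scatter because the detector consumes only pairwise distances — temporal
autocorrelation within a fixation (tremor, drift microstructure) is not
emulated, so passing tests say nothing about separating those sub-fixation
events.  Transits are linear interpolants: the detector never uses
velocity, so saccade kinematics are irrelevant; the optional damped
oscillation exists solely to exercise complex-stopping splits.  The
recovery conditions (3–8 fixations, noise sd 0.3, separation ≥ 3) use
instantaneous jumps: with ≥ 2 interpolated samples at separation 3 the
transit step (~1 unit) falls below the fixation diameter (~1.4 units) and
the transit chain genuinely bridges adjacent blocks — no detector honoring
the no-postprocessing contract can split it.  The six-fixation revisit
preset (`abcdec`) does use 2 transit samples per saccade at within-group
spacing 2 and verifies that they land in gaps.  All randomness flows
through one `numpy` generator seeded per configuration; a fixed seed
reproduces recordings byte for byte.

Problem sizes used by the test suite and the acceptance script — masks of
20×20 for oracle equivalence, recordings of ~40–500 samples for scan
self-consistency, 50 recordings of ~100–350 samples for recovery, one
633-sample rendering — were chosen so the full exact scan (which is
quadratic in n per recording) completes in seconds per case on a single
core.

## Numerical choices and degenerate inputs

* Closed threshold comparison (d ≤ t): ties join the foreground, so tc can
  be read directly off the realized-distance grid.
* Gray rendering is linear min–max over finite distances (0 → black,
  maximum → white); sentinel pixels are fixed mid-gray 127 in raw mode and
  background in filtered mode.  The mapping is order-preserving.
* All-identical samples: H ≡ 0, single plateau, fallback yields tc = 0 and
  one fixation spanning the recording.
* A single-sample recording yields one event row (a gap: one sample has no
  2-point coherence).
* Component ids, hole numbering and label letters are deterministic
  (row-major first-pixel order, first temporal occurrence); identical
  input yields byte-identical output, and near-equal distances are handled
  exactly since the scan is event-driven.

## Known limitations

* Smooth pursuit has no block signature and is not modeled; sub-fixation
  classification (tremor/drift/microsaccades) is out of scope.
* Alternating revisit patterns (A B A B ...) can enclose background
  between recurrence rectangles and diagonal blocks, keeping H > 0 up to
  the saccade-amplitude scale; such pathological trajectories may segment
  at a coarser scale.
* Full n×n storage caps practical recordings at n ≈ 20k samples on desk
  hardware; banded/chunked computation is future work.
* Noise-free multi-scale data may segment at a coarser scale under the
  persistence fallback (see above).
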
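# Methods

This note documents the models, parameter choices and numerical conventions
behind `actogram`, and what its synthetic benchmarks do and do not
establish.

## Motion detection

**Background model.** The detector keeps, for every pixel, a statistical
summary of the *N* frames preceding the current one and flags the pixel when
its squared Mahalanobis distance (SMD) from that background distribution
reaches a threshold *T*:

    SMD = (x − μ)² / max(σ², σ²_floor),    changed ⇔ SMD ≥ T

Defaults: `history` N = 28 frames (2 s at the nominal 14 Hz), `threshold`
T = 20, `variance_floor` 4.0 intensity². The floor prevents division by
zero on perfectly static pixels and implicitly sets the minimum detectable
step on a clean background: a jump of √(20·4) ≈ 9 grey levels. Day footage
is colour and night footage grayscale IR; both are reduced to one BT.601
luma channel first so a single model serves around the clock.

Two maintenance strategies share this decision rule:

* **window** (default): μ and σ² are the exact population mean and variance
  of a sliding window of the previous N frames. The implementation keeps
  integer running sums (uint8 data, int64 accumulators), so the statistics
  are exact — no floating-point drift — and the mode is fully reproducible
  by a brute-force per-frame recomputation, which the test suite exploits.
  The population (divide-by-N) estimator is used; the sample estimator
  would scale every SMD by N/(N−1) ≈ 1.037 and shift the effective
  threshold accordingly.
* **adaptive**: a recursive per-pixel Gaussian mixture (≤5 components,
  learning rate α = 1/N, background designated as the smallest set of
  top-ranked components holding ≥ 0.9 of the weight, new components start
  at variance 225). This mirrors the behaviour of common video-surveillance
  background subtractors. The mixture remembers appearances far longer than
  N frames, so its masks can differ from window mode on gradually changing
  scenes or when an object returns to a previously occupied spot; the two
  modes agree on unambiguous input (high-contrast motion over a static
  background without revisits), which is tested.

The first N frames are warm-up: they are absorbed into the model and emit
masks with `valid=False` rather than being silently dropped, so downstream
bookkeeping is explicit. Excluded regions (burned-in timestamp overlays)
are zeroed before modelling; a constant region has zero variance and zero
deviation, so it can never be flagged after warm-up, and the particular
constant is irrelevant. Exclusion is applied after grayscale conversion;
the order is immaterial for the same reason.

**Steady-state response.** Two consequences of the sliding window are worth
stating because they shape every benchmark below. For a pixel whose window
contains an object of contrast c during k of the N = 28 frames:

* currently *occupied*: SMD = (28 − k)/k (for variance above the floor), so
  a freshly occupied pixel (k = 0: SMD = c²/σ²_floor) and one occupied once
  (k = 1: SMD = 27) are flagged, but k ≥ 2 falls below T = 20;
* currently *vacated*: SMD = k/(28 − k) ≤ 27/1 only as k → 27; for the
  common k = 1 case SMD = 1/27 ≈ 0.037 — never flagged, for any contrast.

Hence an object that relocates every frame produces a mask equal to its
*newly occupied* footprint only (no "ghost" at the vacated spot), and when
it stops, exactly one extra frame is flagged (the first static frame has
k = 1) before the model absorbs it. Both effects are exact and are asserted
in the tests.

**Mask clean-up.** One binary erosion with the 5×5 rasterised ellipse
(full middle three rows plus the centre cells of the top and bottom rows;
17 active cells). Cells falling outside the image are treated as
foreground, so the frame border does not erode an otherwise solid mask;
this border contract can differ from other libraries' defaults within a
2-pixel band. Exactly one pass is applied — no opening, closing or
dilation — which removes isolated noise responses while trimming only the
rim of genuine motion blobs.

## Activity indices

A = 100 · (white pixels) / (counted pixels), where counted = frame area
minus excluded pixels. Full precision is kept internally; 0.01 is the
reporting resolution. A0/A1 are per-bin fractions of frames with A > 0 and
A > 0.01 (strict inequalities); the A1 cut-off is on the percent scale
(0.01 percentage points ≈ 41 pixels at 704×576) and is configurable because
other scales are conceivable. Fractions use per-frame sample counts, which
coincide with wall-clock time at fixed frame rate. Bins are aligned to
multiples of the bin width from the series epoch; empty bins are emitted as
missing, not zero, and a trailing short bin is flagged partial. The manual
observer score M (0–3 ordinal: how many animals move, and whether they
translocate) aggregates identically with thresholds 0/1/2 → M0/M1/M2. The
centred simple moving average (default 11 samples, i.e. 11 s at 1 Hz)
shrinks its window symmetrically at the series ends.

## Agreement statistics

Neither A nor M is normally distributed (A is zero-inflated and
right-skewed, M is a four-level ordinal), so agreement is assessed by rank
methods: Spearman correlation (mid-ranks, t-approximation p; undefined on a
constant series and reported as missing), Kruskal–Wallis H with tie
correction and χ² p on k−1 df (all-identical data reported as H = 0,
p = 1), and Dunn's post-hoc z tests with the tie-corrected standard error

    SE = sqrt( [N(N+1)/12 − Σ(t³−t)/(12(N−1))] · (1/n_i + 1/n_j) ).

Dunn p-values are two-sided and unadjusted by default (per-pair reporting);
Bonferroni and Holm adjustments are available behind a flag. Normality is
screened with the Lilliefors-corrected Kolmogorov–Smirnov test because the
normal parameters are estimated from the data — the plain KS p-value would
be anti-conservative. Group summaries are mean ± SEM (sample sd/√n; SEM
set to 0 for n = 1). α = 0.05 throughout, configurable. The per-frame A
series is averaged within whole seconds before pairing with the 1 s manual
scores.

## Synthetic footage

The generator emulates the properties that make this problem hard: small
blobs (filled disks — the detector measures pixel change, so body-shape
realism adds nothing to ground truth), low contrast (default 20 intensity
units above a uniform background of 100), additive Gaussian sensor noise
(default sd 2), per-frame displacements larger than the blob's own
diameter, colour day frames versus grayscale night frames, and a diurnal
schedule (activity level = per-frame probability that a blob moves).
Defaults mirror a zoo-enclosure recording: 704×576 at 14 Hz, nine animals,
blob radius 10 px (≈ a 20 cm body at the ≈176 px/m scale of a
ceiling-mounted camera).

Two motion models:

* **teleport** — a moving blob jumps to a fresh position. Targets are kept
  disjoint from all locations any blob occupied during the preceding
  `avoid_frames` (default 28) frames, as soft constraints; disjointness
  from same-frame and just-vacated disks is always enforced (hard). This
  makes the pipeline's steady-state output exactly predictable: per the
  SMD analysis above, every valid frame's mask is precisely the union of
  the freshly occupied disks, so A = 100 · (eroded disk area) ·
  n_moving / counted. Without the avoidance, revisited pixels (k ≥ 2 in
  the window) drop below threshold and randomly trim the mask. In crowded
  frames the soft constraints are dropped rather than failing, degrading
  gracefully to consecutive-frame disjointness (which keeps the
  frame-difference ground truth, 2 × blob area per moving blob, exact).
* **walk** — uniform per-axis steps up to `max_step` (default 2.5×
  diameter), clipped at the border; no disjointness guarantees.

Ground truth records, per frame, the count of pixels differing between
consecutive noise-free grayscale frames, the number of blobs that moved,
and the scheduled activity level.

What a green synthetic test does *not* establish: robustness to
illumination change, shadows, compression artefacts, camera shake,
occlusion between animals, or deformable bodies — none of which the
generator models. The published headline agreement figures between this
kind of automatic index and human scoring on real footage cannot be
reproduced here because the original recordings are not publicly deposited;
the synthetic benchmarks validate the mechanics of the pipeline, not its
field performance. OpenCV is not a dependency; video-container decoding is
out of scope and input is a lossless image-sequence directory (PGM/PNG).

## Rhythm monitoring and anomaly screening

Daily summaries average A0/A1 over the daytime window (default 6:30–18:30)
per calendar day, reported as mean ± SEM. The abnormal-activity screen is
deliberately simple and training-free: on a fixed bin-of-day grid (default
10 min), the baseline across ≥2 reference days is the per-bin median and
MAD (median absolute deviation, unscaled); a test-day bin is flagged when

    |value − median_b| > k · max(MAD_b, mad_floor)

with defaults k = 5 and `mad_floor` = 0.005. Median/MAD rather than
mean/SD because night bins are zero-inflated: the median of an all-zero
night is exactly zero with zero MAD, and the floor then sets the detection
band (5 × 0.005 = 0.025) instead of collapsing it. The flag set shrinks
monotonically in k; k = ∞ flags nothing. This detector is an extension
beyond the published pipeline, which proposes abnormal-activity detection
(illness, births, caretaker events) without specifying a rule. A
`day_length` parameter supports compressed synthetic days for desk-scale
experiments.

## Numerical and design notes

* Grayscale: BT.601 integer luma (0.299, 0.587, 0.114), rounded to
  nearest; coefficients configurable. Already-grayscale input passes
  through, making conversion idempotent.
* Coordinates are 0-based, x rightward, y downward; exclusion rectangles
  are half-open `(x0, y0, x1, y1)`.
* The pipeline is streaming: memory is bounded by the N-frame history plus
  one mask, regardless of sequence length (multi-day recordings are tens of
  millions of frames).
* All randomness flows through one seeded NumPy generator per run; CLI
  runs write their resolved configuration next to their outputs.
* Degenerate inputs: constant series → Spearman missing, KW (0, 1);
  single-observation groups → SEM 0 with n recorded; empty bins → missing;
  counted-pixels 0, even smoothing widths, overlapping schedules, oversize
  blobs and out-of-bounds rectangles all raise `ValueError`.
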
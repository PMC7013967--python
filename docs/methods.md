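# Methods

## The measurement problem

Rigidity — resistance to passive movement — is a cardinal Parkinsonian
symptom, and its intra-operative improvement under trial stimulation is the
signal neurologists use to place DBS electrodes. The examiner flexes the
patient's wrist; a gyroscope worn on the palm records angular velocity.
With roughly constant imposed force, lower rigidity yields faster, smoother
flexion: higher peak angular velocity, higher average velocity, fewer
cogwheel interruptions. `wristrig` turns those kinematic regularities into
a calibrated improvement percentage.

## Signal chain

**Conversion.** ω = y/2¹⁵ · 2000 °/s maps signed 16-bit counts to angular
velocity. The divisor is 2¹⁵ (not 2¹⁵−1), so the accepted input domain is
[−32768, +32768]: the positive full-scale code maps to exactly 2000 °/s.
The map is linear and odd; both properties are tested exhaustively over
the 16-bit range.

**Filtering.** A width-4 trailing moving average. Edge handling is a
growing prefix mean, chosen so output length equals input length and window
bookkeeping stays exact. Filtering precedes the flexion mask: masking first
would splice non-adjacent samples and create artificial steps at arcade
boundaries.

**Flexion extraction.** Sensor orientation makes flexion negative along y;
strictly negative samples are retained (zero is not movement), rectified,
and kept with their source indices so sign-change boundaries delimit
arcades — one arcade per imposed flexion.

**Windowing.** Contiguous, non-overlapping, fixed length; ⌊n/size⌋ complete
windows, trailing residual reported but never classified. Device profiles:
v1 = 42 Hz / 300-sample windows, v2 = 50 Hz / 200-sample windows (4 s).

## Features

**Peaks.** The operational definition: a peak is the highest value between
two valleys, where both the rise from the preceding valley and the drop to
the following one must reach the margin (default 0.2 °/s). Implemented as a
symmetric hysteresis scan; sequence boundaries act as valleys, so ripples
below the margin can never split a peak. Peak detection runs on the
full-length rectified trace (zeros outside flexion), so the inter-arcade
baseline supplies the zero valleys. The test suite checks exact agreement
with an independently formulated oracle (alternating-extrema chain with
smallest-difference persistence merging) on hundreds of random signals.

**μω and μp.** Mean of the flexion-sample magnitudes, and mean of the peak
magnitudes; both 0 for an empty window (classification must always emit a
value; a window with no detected flexion is flagged unclassifiable rather
than poisoning descriptors with NaN). Note that μp ≥ μω is a property of
arcade-shaped signals, not a theorem: a pathological plateau with a tiny
confirmed secondary peak can invert it. It is asserted on the arcade family
the generator produces.

**Cogwheel count δ.** The original detection method is not published in
enough detail to reproduce; this package *defines* its own detector and
documents it: within each arcade, every interior oscillation whose rebound
clears the dip threshold (default 0.2 °/s, matching the peak margin) on
both sides counts as one artefact — equivalently, an arcade carrying k
confirmed peaks at that threshold contributes k−1. It is deterministic,
scale-consistent (invariant under joint scaling of signal and threshold),
and reproduces the qualitative behaviour expected of cogwheel counts
(integer 0–5 per window, decreasing with improvement).

**Axis combinations.** The multi-axis descriptors consume features of the
per-sample Euclidean norm √(Σωᵢ²) over the selected axes (the norm keeps
°/s units; the printed notation omits the root but a squared-units feature
would break the descriptor catalogue's dimensional consistency). Flexion
timing for a combined trace is taken from the y-axis sign.

## Descriptor catalogue

All descriptors reduce one window to a scalar φ. The base form is
φ_y = μω·μp, which separates fast-and-smooth from fast-but-interrupted
movement better than either factor alone. Variants: φ_I = φ_y and
φ_III (a log₂-weighted symmetric form) used by the baseline-gated pair;
φ_II = min(μω, μp); φ_IV = φ_y·exp(−ln²(μp/μω)/2σ²), a Gaussian penalty on
the peak-to-mean ratio (σ is dimensionless, default 1.0 — unspecified
upstream, the default penalises ratios ≳ e and is exposed in
configuration); multi-axis forms φ_norm2/φ_norm3 (features on the 2-/3-axis
norm) and φ_xy/φ_xyz/φ̄ (per-axis μω each paired with the y-axis μp,
exactly as the catalogue defines them); cogwheel corrections φ₁…φ₈
(φ_y² ± δ, φ_y ± δ², φ_y ± δ, μω·(μp ∓ δ)); and the production descriptor
φ_R = φ_y on 200-sample windows. Natural log is used inside φ_IV's Gaussian
(the σ² pairing implies it); log₂ only where the catalogue prints it
(φ_III). φ_IV is deliberately non-monotone in μp — it turns over at
μp = e·μω — and the tests pin that down.

Degenerate windows (μω = 0) short-circuit every descriptor to 0 with an
unclassifiable flag; log forms additionally guard non-positive inputs.

## Calibration model

Labels live on a discrete decile scale, 0–80 % improvement. The original
class set is {0, 10, …, 80}; later calibrations restrict to
{0, 40, 50, 60, 70, 80} because examiners could not reliably discriminate
improvements below 40 %. Valid windows are grouped by label; the class-mean
descriptor is computed; a quadratic `improvement = aφ² + bφ + c` is fitted
by least squares through the (mean, label) points (at least three distinct
abscissae required). Higher polynomial degrees are excluded by design —
they overfit a six-point calibration and respond erratically to
out-of-range signals. Classification is direct evaluation of the quadratic
clamped to [0, 80]; the output stays continuous, never snapped back to the
decile grid, because a discrete clinical scale is being modelled by a
continuous function.

**LOOCV.** One window is held out; class means are recomputed without it
(the holdout affects only its own class mean); the quadratic is refitted
and |prediction − label| recorded. Exhaustive mode (default) visits every
valid window once and is permutation-invariant; a seeded Monte-Carlo mode
draws a configurable number of random holdouts for compatibility with
iteration-count-style reporting. Holdouts that collapse a class below
three fit points are skipped and counted.

**Baseline gating.** Two calibrations, selected by the pre-stimulation
rigidity UPDRS: 1–2 → low-baseline model, 3 → high-baseline model, 4 →
explicit unsupported-regime error (no UPDRS-4 training data exists).

## Evaluation

A prediction is accurate iff |prediction − label| ≤ tolerance, boundary
inclusive, default 5 points. Displayed accuracy truncates (floors) to one
decimal — the convention under which 131/156 = 83.974 % prints as 83.9 %.
Discrimination analysis uses Welch's unequal-variance two-tailed t-test
(the pooled-variance assumption is not defensible for rigid vs non-rigid
groups of different sizes) with Jarque–Bera normality checks,
JB = n/6·(S² + (K−3)²/4) against χ²₂; zero-variance groups are flagged
degenerate rather than given a fabricated p-value.

## Synthetic session generator

The generator is the package's stand-in for unavailable surgical
recordings. What it emulates, per window of improvement label r:

- **Arcades**: negative half-sine pulses on y; `arcade_rate` defaults to
  0.75 flexions/s → 3 arcades per 4-s window (the window length was
  originally chosen to hold two-to-three flexions; the true rate is not
  published and is a free parameter). Each arcade occupies 60 % of its slot
  with jittered onset.
- **Amplitude law**: A(r) = base·(1 + gain·r/80); defaults base = 15 °/s,
  gain = 1.2, spanning ≈15 → ≈33 °/s across 0 → 80 % — consistent with the
  reported rigid (~13 °/s) vs non-rigid (~30 °/s) mean-peak scale.
- **Cogwheel artefacts**: per-window count ~ Poisson with mean linear in r
  through the observed anchors (2.6 at 40 %, 1.2 at 80 %; 4.0 extrapolated
  at 0 %, truncated at zero). Each artefact is a raised-cosine dip of
  0.4–0.5 of the local velocity, 0.08 s wide, placed in a free slot within
  the central 35–65 % of an arcade: catches concentrate mid-range, where
  resistance is highest — and a shallow dip on a steep rising flank would
  create no local minimum at all, i.e. an injected artefact that the
  definition of δ could never see. Central placement keeps injected and
  detected counts in agreement.
- **Noise and cross-axes**: white Gaussian noise of 0.05 °/s on every axis
  (the scale of a real gyroscope noise floor, below the 0.061 °/s
  quantisation step of the ±2000 °/s 16-bit register); x carries 25 % of
  the flexion waveform plus noise, z noise only — matching the observation
  that only y is pronounced during passive flexion, x co-varies weakly, z
  not at all.
- **Determinism**: one session seed; window k draws from substream
  (seed, k), so a window's content is independent of schedule order.

Defaults were calibrated once, at design time, so that the full chain
operating on default-condition cohorts sits in the ~80–85 %-within-±5
regime the method is known to occupy — the test suite then asserts that
regime as a property (≥80 % on ~500 held-out windows). The labelled-window
generator (`generate_labelled_windows`) inverts a known truth quadratic on
its monotone branch and adds Gaussian descriptor noise; it exists for
parameter-recovery tests (noiseless recovery to 1e-9; coefficient RMSE
shrinking ~1/√n) and warns when noise spills past the truth's vertex,
where the label–descriptor relation stops being invertible.

**What the generator does not model** — and hence what passing tests do
not show about real data: examiner force variability between trials and
surgeries (the dominant confounder in practice), active patient
participation, tremor superimposed on flexion, rotational contamination of
the y-axis, stimulation-voltage dynamics within a window, and inter-rater
label disagreement. Synthetic labels are exact by construction; clinical
labels are a two-expert agreement.

## Numerical choices and degenerate inputs

- Quadratic fits use `numpy.polyfit` (degree fixed at 2); tests cross-check
  against an explicit normal-equations solve.
- Fits with fewer than three distinct class-mean abscissae raise; they do
  not silently degrade degree.
- Peak margin and dip threshold are configuration, both defaulting to
  0.2 °/s.
- Empty windows/feature sets yield 0-valued features, and μω = 0 marks the
  window unclassifiable; streaming classification logs such windows but
  excludes them from the best-improvement display.
- Session CSVs round-trip at 6 decimals (≈0.06 % of the noise floor).
- All stochastic APIs take explicit seeds; nothing reads global RNG state.

## Known limitations

- The cogwheel detector is this package's own operational definition, not
  a reproduction of the original (unpublished) method; δ-based descriptor
  values are comparable within this package only.
- The multi-axis descriptors pair every axis's μω with the y-axis μp, as
  the catalogue prints them; a per-axis-peak variant would be a different
  (undocumented) descriptor and is deliberately not provided.
- Whether the original pipeline masked flexion before or after filtering
  is not recorded; this package fixes filter-then-mask and documents it.
- LOOCV holds out single windows, not whole patients; with real multi-
  patient data, per-patient holdout would estimate generalisation more
  honestly.
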
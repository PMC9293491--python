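# Methods

## Threshold selection

The segmentation core is Otsu's histogram thresholding. A grayscale image
with `K` levels (indexed `1..K`; an 8-bit intensity `v` maps to level
`i = v + 1`) yields per-level counts `a_i`, normalized to probabilities
`q_i = a_i / A`. A threshold `t` splits levels into a low class B0
(`1..t`) and high class B1 (`t+1..K`) with

    omega(t) = sum_{i<=t} q_i,     mu(t) = sum_{i<=t} i q_i,
    mu_E = mu(K),
    sigma_C^2(t) = omega0 (mu0 - mu_E)^2 + omega1 (mu1 - mu_E)^2
                 = (mu_E omega(t) - mu(t))^2 / (omega(t)(1 - omega(t))).

The within/between/total decomposition `sigma_V^2 + sigma_C^2 = sigma_E^2`
holds at every split, so maximizing `sigma_C^2` is equivalent to
maximizing the separability criterion `eta = sigma_C^2 / sigma_E^2` (and,
where `sigma_V^2 > 0`, to maximizing `lambda = sigma_C^2 / sigma_V^2`).
The selector evaluates the closed single-pass form over every admissible
split and averages exact ties, so the selected threshold is real-valued.

Numerical choices:

- Cumulative sums accumulate in extended precision (`np.longdouble`) in a
  single forward pass, and `omega` is renormalized at the endpoint so
  `omega(K) = 1` exactly; `K <= 65536` makes full O(K) passes cheap, so no
  incremental recurrences are used.
- Admissible thresholds are those leaving both classes non-empty, decided
  from exact count sums (not floating comparisons). Splits that empty a
  class are excluded rather than scored zero: the closed form is undefined
  there and their exclusion cannot change the argmax.
- Ties on the between-class variance are detected at relative tolerance
  1e-12 and averaged. When the averaged threshold is fractional, pixels
  compare against round-half-up of it — one documented rule keeping masks
  reproducible.
- A constant image raises a dedicated error carrying the occupied level;
  there is no silent default threshold.
- When `sigma_V^2 = 0` (two point masses), `lambda` and `kappa` are
  reported as `inf`; `eta` remains defined.

Polarity: ICG fluorescence renders perfused vessels bright, so the high
class is the foreground by default; `dark_foreground` (CLI
`--dark-foreground`) swaps the labeling for workflows that treat the low
class as the target. No preprocessing is applied by default — optional
Gaussian smoothing is explicit (`--smooth SIGMA`) because silent
smoothing would change thresholds.

## Evaluation metrics

`mse` is the mean squared intensity difference. `ssim` defaults to the
global (single-window) structural similarity with the conventional
stabilizers `C1 = (0.01 L)^2`, `C2 = (0.03 L)^2` and population
(ddof 0) moments; the global form is deterministic and parameter-free,
which matters when no window size is given with the metric. A
sliding-window mean (scikit-image) is available via `windowed=True`.

Shape error is a definitional choice of this package (the name alone does
not fix a formula): the symmetric-difference area normalized by the
ground-truth area, `SE = |pred XOR truth| / |truth|`. It is zero iff the
masks agree, 1 for an empty prediction, 2 for a disjoint equal-area one,
and deliberately asymmetric. Dice is carried as the standard auxiliary
overlap score.

## Synthetic phantom

The generator emulates the appearance of a usable ICGA frame, not its
optics or hemodynamics: a smooth random-walk centerline of fixed caliber
(default 3 mm at 10 px/mm on a 512×512 field) rasterized by distance
transform, plus one saccular disc bulge tangent to the centerline, drawn
uniformly within the clinical size class (small < 5 mm floored at 1.5,
medium 5–10, large 10–25, giant > 25 capped at 35 mm). The two-tone
image (background mean 40, vessel mean 180) is Gaussian-blurred
(sigma 1 px, a point-spread proxy) and corrupted with additive Gaussian
noise (sigma 10), then clipped to the bit depth. Additive Gaussian noise
was chosen over Poisson as the simplest model with controllable
histogram overlap.

Ground truth is the pre-blur geometry: blur models the instrument, noise
the sensor, and the metrics should score anatomy recovery. Every draw
flows from one seeded generator, so scenes are bit-reproducible.

What the phantom does **not** emulate — and what passing tests therefore
do not show about clinical frames: vessel trees and perforators, ICG
wash-in/wash-out kinetics, non-uniform illumination, motion blur,
specular instrument reflections, and overlapping anatomy. The phantom
establishes that the implementation recovers known geometry under
bimodal contrast; it says nothing about reader-level accuracy on real
angiography.

## Outcome statistics

The reproduced trial is a two-arm comparison (43 patients per arm) of
angiography-guided clipping with perioperative nursing versus clipping
with routine nursing. Enumeration data are expressed as percentages
rounded half-up to two decimals; 2×2 contrasts use the uncorrected
Pearson chi-square (df 1). The continuity-corrected statistic is
deliberately not used: at these arm sizes it is conservative enough to
flip the borderline good-outcome contrast (p 0.047 uncorrected vs 0.086
corrected), and the uncorrected form matches the reported conclusions.
Continuous measures summarized as mean ± SD are compared with the
pooled-variance Student t-test reconstructed from the summaries; with
equal arms and similar SDs the Welch/Student choice is immaterial, and
pooled is the convention the summaries imply.

The synthetic cohort draws categorical fields (severity grade, location,
size class, outcome, complication) from the published per-arm
frequencies and continuous fields from normal distributions truncated to
plausible ranges; quality-of-life dimension scores are truncated to the
instrument's 0–100 range. It exists for end-to-end tests and
calibration studies, not for inference about patients.

Calibration is measured empirically: type-I error of each test under a
seeded two-arm null (binomial p = 0.5 for the chi-square; normal
20.0 ± 3.5, echoing the stay scale, for the t-test), 2000 replicates,
rejection at alpha = 0.05. Replicates with a degenerate 2×2 marginal are
untestable and count as non-rejections.

## Problem sizes

The verification suite uses 1000 random histograms (K ≤ 32, counts ≤ 50)
plus an exhaustive K = 4 sweep for oracle parity, 20 phantom seeds at the
default noisy spec for the Dice floor, and 2000 replicates for test
calibration. These sizes give stable estimates (binomial SE ≈ 0.005 at
2000 replicates) while keeping the default suite fast.

## Known limitations

- Single global threshold only: no multi-level or locally adaptive
  variant, no entropy-based criteria.
- The global SSIM is a whole-image statistic; values are not comparable
  to windowed SSIM numbers from other software without selecting
  `windowed=True`.
- Shape error is this package's definition; other groups may normalize
  differently, so compare SE values only within this package.
- The published image-quality figures for the clinical frames cannot be
  recomputed here because those frames (and their comparison reference)
  are not available; phantom metrics stand in as verifiable surrogates.
- The source report's overall sex counts disagree between its cohort
  description and its per-arm tables; no reproduced statistic depends on
  sex, and the cohort generator does not carry it.
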
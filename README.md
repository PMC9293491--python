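# icga-otsu

Otsu-threshold segmentation for intraoperative indocyanine-green
angiography (ICGA), with a synthetic vascular phantom generator,
segmentation-quality metrics, and the two-arm clinical outcome
statistics of an aneurysm-clipping study.

During craniotomy clipping of an intracranial aneurysm, ICG fluorescence
angiography shows the parent artery, the aneurysm and nearby perforators
as bright structures on a dark field. Separating that bright foreground
from background is a two-class histogram thresholding problem, and
Otsu's method solves it without tuning: for a histogram with
probabilities `q_i` over gray levels `i = 1..K`, a threshold `t` splits
the levels into classes with probabilities `ω₀ = ω(t)`, `ω₁ = 1 − ω(t)`
and means `μ₀`, `μ₁`, and the selected threshold maximizes the
between-class variance

    σ_C²(t) = ω₀(μ₀ − μ_E)² + ω₁(μ₁ − μ_E)²
            = (μ_E ω(t) − μ(t))² / (ω(t)(1 − ω(t))),

equivalently the separability criterion `η = σ_C²/σ_E²`, with exact ties
averaged (so `t*` can be fractional). The package implements the full
chain — histogram normalization, cumulative moments, class statistics,
the within/between/total variance decomposition, and the selector — plus
everything needed to verify it end to end without clinical data.

Intended users: image-analysis engineers validating angiography
segmentation pipelines, and anyone needing a dependency-light, exactly
specified Otsu reference with ground-truth phantoms.

## Worked example

```python
from icga_otsu import PhantomSpec, generate_phantom, segment, evaluate_masks

scene = generate_phantom(PhantomSpec(aneurysm_class="medium", seed=7))
mask, result = segment(scene.image)
print(f"selected threshold level t* = {result.t_star:.1f} "
      f"(intensity {result.t_star - 1:.0f}), eta = {result.eta_at_star:.3f}")
report = evaluate_masks(mask, scene.truth)
print(f"dice = {report.dice:.4f}, shape error = {report.se:.4f}")
```

prints

```
selected threshold level t* = 109.0 (intensity 108), eta = 0.913
dice = 0.9990, shape error = 0.0019
```

The phantom places a 3 mm vessel and a medium (5–10 mm) saccular bulge
at means 40/180 with blur σ 1 and noise σ 10; the selected cut at
intensity 108 lies between the modes, the separability η = 0.91 reflects
the strongly bimodal histogram, and the mask recovers 99.9 % of the
ground-truth anatomy (Dice), mislabeling 0.2 % of the true area (shape
error = symmetric difference / truth area).

The clinical outcome statistics reproduce the study's printed numbers
from the bundled per-arm tables:

```python
from icga_otsu import analyze_tables
rep = analyze_tables()
g = rep["good_rate_percent"]
print(f"good rate: {g['experimental']}% vs {g['control']}%, "
      f"chi2 = {g['chi2']:.3f}, p = {g['p']:.4f}")
s = rep["continuous"]["hospital_stay_days"]
print(f"hospital stay: t = {s['t']:.3f}, df = {s['df']}, p = {s['p']:.2e}")
```

```
good rate: 90.7% vs 74.42%, chi2 = 3.957, p = 0.0467
hospital stay: t = -4.694, df = 84, p = 1.03e-05
```

i.e. the guided arm's good-outcome rate (90.70 % vs 74.42 %) is
significantly higher by an uncorrected Pearson chi-square, and its
hospital stay (19.9 ± 3.5 vs 23.2 ± 3.0 days, pooled t) significantly
shorter.

## Command line

```sh
icga-otsu segment frame.png --out mask.png --report report.json
icga-otsu threshold frame.png            # prints t*; exit code 2 if constant
icga-otsu evaluate pred.png truth.png --kind mask
icga-otsu simulate --seed 7 --class medium --out-img img.png --out-mask gt.png
icga-otsu study --out report.json        # rates, chi-square, t-tests
icga-otsu cohort --seed 1 --out cohort.csv
```

## Layout

- `src/icga_otsu/otsu.py` — histogram thresholding mathematics
- `src/icga_otsu/image.py` — raster I/O, histogram adapter, mask output
- `src/icga_otsu/metrics.py` — MSE, SSIM, shape error, Dice
- `src/icga_otsu/phantom.py` — seeded synthetic vessel + aneurysm scenes
- `src/icga_otsu/stats.py` — rates, chi-square, pooled t, synthetic cohort
- `src/icga_otsu/cli.py` — the `icga-otsu` command
- `docs/methods.md` — model details, numerical choices, limitations
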
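# leafsen

Quantifying the onset and progression of leaf senescence from RGB images
in high-throughput plant phenotyping pipelines.

Whole-plant imaging platforms trade per-leaf resolution for throughput:
fixed lenses and settings blur thin leaves, and because the R, G and B
bands are blurred unequally — and bleed into each other — green leaf
edges come out yellow. A color classifier applied to such images reports
substantial senescence on perfectly green plants and cannot time the real
onset. `leafsen` corrects the distortion with a learned linear operator,
then quantifies senescence per plant, per zone and per day, and relates
the estimates to manual visual scores.

## Method

The observed image **X** is modeled as **X** = **G·D** + **N**, with a
channel-coupled, band-specific blur **D** and noise **N**. Instead of
estimating and inverting **D**, the correction matrix **C** is estimated
directly from one calibration pair: arrange **X** into the S_i × M patch
matrix (each row a pixel's L × L × N_c neighborhood, M = L²·N_c), arrange
the undistorted reference **G** into S_i × N_c, and solve the
(ridge-regularized) least-squares problem

    C = argmin ‖G − X C‖² + λ‖C‖²      (λ = 0 → C = (XᵗX)⁻¹XᵗG)

Any image acquired under the same camera settings is then restored by a
single matrix product **R** = **X C**. The reference **G** comes either
from a standard color chart or is estimated from an image of a young,
uniformly green plant. Restored images are segmented by HSV color rules,
split into three equal-height zones (fallen leaves count as bottom), and
every plant pixel is classified as dark green, light green, light yellow
or brown; yellow + brown area is senescent. Daily percentages yield onset
(first persistent exceedance of a threshold), progression rate, and
treatment summaries; manual 1–10 scores are related to the image estimate
by an ordinary least-squares fit of score on ln(percentage).

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

A fully synthetic round trip — generate a scene with known truth, distort
it, calibrate, restore, analyze:

```python
import leafsen as ls

spec = ls.SyntheticSceneSpec(senescent_fraction=0.25, seed=11)
truth = ls.generate_scene(spec)

kern = ls.asymmetric_edge_preset(1.0, kernel_size=3, noise_sigma=0.005)
blurred = ls.simulate_degradation(truth.clean_image, kern, seed=1)

before = ls.analyze_image(blurred)
corr = ls.ColorDistortionCorrector(kernel_size=5).fit(blurred, truth.clean_image)
after = ls.analyze_image(corr.transform(blurred))

print(f"true senescent fraction : {100*truth.realized_senescent_fraction:.2f}%")
print(f"blurred image estimate  : {before.overall_senescent_pct:.2f}%")
print(f"restored image estimate : {after.overall_senescent_pct:.2f}%")
```

which prints

```
true senescent fraction : 25.00%
blurred image estimate  : 28.74%
restored image estimate : 24.45%
```

The blurred estimate overshoots by 3.7 points (yellow edge fringes); the
corrected estimate is within 0.6 points of truth. The fitted corrector
exposes `fit_residual_` (here 0.0076 RMS) and the zonal breakdown shows
senescence concentrated where it was planted
(`after.zone_senescent_pct` → top 0.0%, mid 21.6%, bottom 31.3%).

The packaged chickpea evaluation table (image percentage vs manual 1–10
score under four salt treatments) reproduces the logarithmic relation:

```python
table = ls.load_chickpea_scores()
fit = ls.fit_score_relationship(table[["senescent_pct", "score_2day"]].to_numpy())
# score = 2.33 + 1.65 ln(pct), R^2 = 0.7576
```

## Command line

```sh
leafsen simulate  --seed 3 --fraction 0.25 --out scene/      # scene + truth sidecars
leafsen calibrate --distorted day0.png --clean ref.png --out C.txt
leafsen restore   --image day7.png --matrix C.txt --out day7_restored.png
leafsen analyze   --batch images/ --matrix C.txt --out report.csv
leafsen series    --csv report_series.csv --out onsets.json
leafsen correlate --out score_fit.json
```

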
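# mitopolar

Quantification of planar cell polarity and oriented cell division in
epithelial mitotic domains, driven by a synthetic-image generator with
per-cell ground truth.

During *Drosophila* gastrulation, pockets of cells in the embryonic head —
mitotic domains — divide synchronously with their spindles oriented along
the anterior-posterior (AP) body axis, guided by cortical crescents of the
spindle-orientation protein Pins/LGN that are planar-polarized by
morphogenetic forces. Measuring this requires a specific chain of image
quantifications: cortical intensity profiles traced around each mitotic
cell, a peak-to-trough polarity statistic, division angles measured at
anaphase from the spindle pole axis, rotation chirality, interphase shape
anisotropy (the long-axis rule), and exact small-sample inference over
per-embryo means. `mitopolar` packages that chain as a tested, reusable
library for anyone quantifying planar polarity or division orientation in
en-face epithelial imaging — together with a generator that emulates the
data so every measurement can be validated against known truth.

## The measurements

**Cortical profile and polarity statistic.** The perimeter of each mitotic
cell is traced with a 2-pixel-wide segmented line (after 0.75-pixel
Gaussian smoothing), starting at the anterior-most point, clockwise for
cells on the left half of a mirrored domain pair and counterclockwise on
the right. Intensity *I(s)* is normalized to the mean cytoplasmic gray
value. The crescent is summarized by the angle of maximum intensity
φ_max and the peak-to-trough ratio

> P = I(φ_max) / mean(I(trough₁), I(trough₂)),

where the troughs are the nearest circular local minima flanking the peak.
P ≈ 1 for an unpolarized membrane control; P grows with crescent contrast.

**Division angles.** The spindle axis is the line through the two pole
centroids; its angle θ to the AP axis is signed in (−90°, 90°]
(counterclockwise positive, anterior up) and folded to [0°, 90°] for rose
histograms (0° = AP-aligned, 90° = DV-aligned). Rotation direction is the
sign of the net shorter-arc angular displacement from spindle assembly to
anaphase. Rose plots show the percentage of spindles per angular bin.

**Shape anisotropy.** Each interphase contour gets its moment-equivalent
ellipse (same area, centroid, and second central area moments, computed by
exact polygon formulas), giving aspect ratio AR = major/minor and long-axis
angle — the ingredients of the long-axis (Hertwig's) rule test against
division angles.

**Inference.** Group comparisons use the two-sample Mann-Whitney test with
the null distribution of U enumerated exactly for tie-free samples (the
regime of per-embryo means, n ≤ 20 per side); correlations use Spearman's ρ
with exact permutation p-values for n ≤ 9, plus Pearson r and R². Under
complete separation the exact two-sided p equals 2/C(n₁+n₂, n₁).

## Worked example

`examples/02_cortical_profiles_and_polarity.py` renders a 20-cell mirrored
domain with crescent contrast a = 1 and 5% Gaussian noise, measures every
cell in the polarity channel and a uniform membrane control, and prints:

```
peak-to-trough: polarity 1.96 +/- 0.04, membrane 1.04 +/- 0.01
Mann-Whitney (exact): p = 1.45e-11
crescent angle recovery: mean error 2.3 deg (truth known from the generator)
```

The polarized channel's ratio sits far above the control's (which stays at
~1.04 — residual rasterization/PSF ripple, not biology), the exact test
separates the channels at the minimal attainable p for 20 vs 20 cells, and
the recovered crescent angles agree with the generator's ground truth to a
couple of degrees. The other examples cover domain generation
(`01`), spindle rotation tracking and rose histograms (`03`), the
long-axis-rule test (`04`, flat against shape, R² ≈ 0.89 against the
crescent), and exact small-sample inference (`05`).

An end-to-end run — images → profiles → polarity → divisions → shapes →
statistics → plots, with every table and a seed-stamped run log — is one
call (or `mitopolar pipeline --outdir out --seed 0` from the shell):

```python
from mitopolar import pipeline
results = pipeline.run_pipeline(pipeline.demo_config("out", seed=0))
```

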
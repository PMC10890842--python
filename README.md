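# ucnpscore

Semi-quantification of HER2 membrane staining in immunohistochemistry images
labeled with upconverting nanoparticles (UCNPs), by sliding-window 2-D
Fourier band-pass scoring.

HER2 status in breast cancer is graded 0 / 1+ / 2+ / 3+ from the
*completeness and intensity of circumferential membrane staining* — a visual
call with poor inter-rater reliability at the low end. UCNP labels emit
against a dark (anti-Stokes) background, which makes the membrane texture
quantifiable. This package implements that quantification for image analysts
and assay developers:

* **Pixel / area scores** — for each pixel, a 201×201 px macro window is
  FFT-filtered with an annular pass-band (0.015–0.92 µm⁻¹ by default:
  removes DC background, keeps ~1 µm membrane texture), transformed back,
  weighted with a center-peaked Gaussian (σ = 34 px), and summed over
  absolute values. The mean over a region (*area score*) rises with HER2
  level because complete bright rings concentrate energy in the band:

  score(x₀) = Σᵣ w(r − x₀) · |F⁻¹[ M(f) · F[I·W_{x₀}] ](r)|,
  with M(f) = 1 for 0.015 ≤ |f| ≤ 0.92 µm⁻¹ and w a peak-normalized Gaussian.

* **Calibration & heat maps** — per-level area scores from control pellet
  arrays (CPAs) yield midpoint thresholds separating 0|1+|2+|3+; pixel-score
  images of unknown samples are thresholded into per-pixel HER2 level maps
  and per-level area fractions (the clinical "over 10 % of area at 3+" rule).

* **Contrast metrics** — emission signal-to-background (peak over
  negative-control mean), absorption signal-to-background (unlabeled over
  labeled mean, inverted because chromogens darken), and their ratio, the
  enhancement factor.

* **Phantom generator** — fully ground-truthed synthetic CPA/tissue fields
  (membrane-ring cells with configurable arc completeness and intensity,
  non-specific cluster artifacts, Poisson + Gaussian noise, DAPI channel,
  Beer–Lambert brightfield counterpart), so the whole pipeline is testable
  without microscope data.

## Worked example

```python
import ucnpscore as u

spec = u.PhantomSpec(shape=(512, 512), cell_count=150,
                     level=u.HER2Level.THREE_PLUS, seed=1)
out = u.generate_phantom(spec)

psi = u.score_image(out.ucnp, u.ScoringConfig(stride=8))
a = u.area_score(psi)
print(a.mean, a.std, a.n_pixels)
```

prints (see `examples/01_score_phantom.py`):

```
cells placed:        150
pixel-score grid:    (39, 39) (stride 8, origin (100, 100))
area score:          132226.3 +/- 12055.5 over 1521 scored pixels
```

An unstained (level 0) field under the same settings scores ≈ 17.5 k — the
score gap is what the calibrated thresholds cut into the four levels.
`examples/02_calibrate_and_classify.py` continues the story: it fits
thresholds on a four-level CPA series and classifies a mixed tissue phantom,
printing per-level heat-map area fractions (a 3+ fraction of 0.44 for a
field whose ground truth puts 30 % of cell area at 3+, well above the 10 %
positivity rule). `examples/03_contrast.py` and `examples/04_line_profile.py`
demonstrate the contrast metrics and the frequency-domain line profile.

A thin CLI wraps the same functions for shell use
(`ucnpscore phantom | score | calibrate | classify | contrast | profile`,
see `--help`; exit codes 0/2/3 = ok/usage/data error).

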
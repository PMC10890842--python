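# Methods

## The scoring model

`ucnpscore` semi-quantifies HER2 expression from single-channel luminescence
images of immunohistochemistry slides labeled with upconverting nanoparticles
(UCNPs). The clinical rubric grades HER2 on completeness and intensity of
*circumferential membrane staining* (0, 1+, 2+, 3+); the algorithm turns that
visual criterion into a texture statistic:

1. **Dark subtraction.** Camera dark counts (full frame or scalar mean) are
   subtracted and negative residuals clamped to zero — counts are physically
   non-negative and every later stage assumes it.
2. **Macro windows.** A square window (default 201×201 px, odd so a unique
   center pixel exists) is extracted around each pixel to be scored.
3. **Band-pass.** The window is 2-D Fourier transformed and multiplied by a
   hard annular mask expressed in physical frequency. Defaults: inner radius
   0.015 µm⁻¹ (removes DC / slow background), outer radius 0.92 µm⁻¹ (the
   highest frequency carried by strong membrane staining, ~1.1 µm features).
   Frequencies are cycles/µm on the standard DFT grid f = k/(N·Δx); Δx, the
   pixel pitch in µm/px, must come from the caller or TIFF metadata — there
   is deliberately no default, because a wrong pitch silently moves the band.
4. **Gaussian weighting.** Back in the spatial domain the filtered window is
   multiplied by an isotropic Gaussian (σ = 34 px, peak-normalized to 1 at
   the center) so the center pixel's neighbourhood dominates its score.
5. **Pixel score.** The weighted absolute filtered values are summed into one
   number per window; the grid of these is the *pixel score image*, and its
   mean (with population-SD spread) is the *area score* of a region.

Complete bright rings concentrate energy inside the annulus; patchy or absent
staining does not, so area scores increase with HER2 level. Calibration on
control pellet arrays (CPAs — reference slides of cell pellets at known
graded expression) converts scores into the four-level scale: the per-level
area-score means are computed and thresholds placed at midpoints of adjacent
means. Pixel-score images of unknown samples are then thresholded into
per-pixel level maps ("heat maps"), from which per-level area fractions are
reported (supporting the clinical "over 10 % of area at 3+" statement).

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| window_size | 201 | px | spans several cells; odd for a unique center |
| gaussian_sigma | 34 | px | weights ~1–2 cells around the center |
| band r_inner | 0.015 | µm⁻¹ | excludes DC and slow illumination gradients |
| band r_outer | 0.92 | µm⁻¹ | upper edge of membrane-staining texture |
| stride | 1 (lib), 8 for large images | px | pure decimation of scored centers |
| magnitude_mode | abs | — | see "Numerical choices" |
| edge_mode | valid | — | no padding artifacts; reflect offered for small images |

`optimize_bandpass` re-derives the radii from labeled patch collections by
maximizing a Fisher-style ratio (variance of per-level mean scores over mean
per-level variance); ties go to the widest band. It exists to document and
reproduce how such radii can be chosen, not to replace the defaults.

## Numerical choices

* **Absolute vs signed summation.** After DC removal the filtered window is
  zero-mean, so a signed weighted sum is sign-indefinite and close to zero
  regardless of staining. Summing absolute values yields a non-negative score
  that grows with in-band energy; the signed variant remains available as
  `magnitude_mode="signed"` for comparison.
* **FFT conventions.** Forward transform unnormalized, inverse 1/N²; the
  all-pass mask then reproduces the input to 1e−10 relative, which is the
  property the algorithm needs. The sliding-window path runs on the real
  half-spectrum (rfft2/irfft2); tests assert bit-level agreement with the
  full complex transform, which is guaranteed by the mask's f → −f symmetry.
* **Mask edges.** The annulus is hard-edged ({0,1}) and inclusive at both
  radii. Single-patch filtering asserts the imaginary residue is below 1e−8
  of the patch norm before discarding it.
* **Thresholds.** Midpoints of adjacent level means. An inversion of
  adjacent means larger than the two levels' combined spread is an error; an
  inversion or tie within it collapses the threshold to the midpoint and
  flags the model *degenerate* — expected for 1+/0, whose scores are known
  to be similar when non-specifically bound label clusters are present.
  Boundary scores classify to the higher level (deterministic tie-break).
* **Area-score spread** uses the population (n) divisor and is recorded in
  the calibration model.
* **Degenerate inputs.** Empty masks name the achievable frequency range;
  images smaller than the window are rejected in valid mode; double dark
  subtraction raises instead of silently re-subtracting.

## The phantom generator

Real slides for this assay are not redistributable, so the package generates
synthetic fields with exact ground truth. A field is a set of non-overlapping
circular cells (rejection-sampled positions; radius 7 ± 1 µm) drawn as:

* a membrane ring (1 µm thick) covering a single contiguous arc of angular
  extent 2π·completeness at the level's membrane intensity,
* a faint cytoplasmic fill (~5 % of membrane intensity),
* a nuclear disk in the DAPI channel.

Level presets: 3+ = completeness 1.0 / 100 counts, 2+ = 0.9 / 40,
1+ = 0.4 / 12, 0 = unstained — a graded rendering of the four-tier
membrane-staining rubric. Optional *cluster artifacts* (Gaussian spots,
σ = 1 µm, 500 counts, 80 mm⁻² when enabled) model non-specifically bound
label aggregates. Noise is Poisson shot noise on expected counts plus
Gaussian read noise (σ = 2 counts) over a 10-count background — the
conventional sCMOS model. Defaults were fixed once as a plausible
near-monolayer pellet at membrane-resolving magnification (0.5 µm/px);
intensity scales are arbitrary camera counts.

A tissue-like field uses a per-pixel region map (e.g. a disk of 3+ cells
among negative cells). A brightfield absorption counterpart is produced by
Beer–Lambert darkening of the same label geometry,
I = I₀·exp(−scale·density/max density), reproducing the saturation that
limits the dynamic range of absorption chromogens.

**What phantoms do not emulate:** realistic tissue morphology, optical
point-spread functions, illumination non-uniformity, label photophysics, 3-D
sectioning, or the true intensity statistics of scanner hardware. Passing
tests therefore demonstrate that the algorithm behaves as designed on images
satisfying its model assumptions — ordered, separable level scores; correct
geometry; correct contrast arithmetic — not that it achieves any particular
accuracy on clinical material.

## Problem sizes used in tests and the acceptance script

CPA phantoms are 512×512 px (0.5 µm/px, 150 cells) scored at stride 8 with
the full 201-px window; five replicates per level for calibration and five
held-out replicates for 2+/3+ recovery; the mixed tissue phantom is
768×768 px with 330 cells, 30 % of its area at 3+. These sizes were chosen
as the smallest fields that still hold tens of cells per window and give
stable area-score statistics. Oracle cross-checks run on 32–64 px patches
where the O(N⁴)-style direct DFT is affordable.

## Known limitations

* The absolute score scale depends on window size, σ, intensity calibration
  and pixel pitch; calibration and classification must use the same scoring
  configuration (the model stores it and the CLI writes it to sidecars).
* Midpoint thresholds assume roughly symmetric per-level score spreads; an
  equal-error-rate rule under per-level normal fits is deliberately out of
  scope.
* The 1+/0 boundary is not reliably resolvable in the presence of cluster
  artifacts; the model flags this degeneracy rather than hiding it.
* Per-window FFT scoring at stride 1 on large images is exact but O(H·W·N²
  log N); use stride, which is exact decimation, rather than any global
  approximation (none is offered, since a single global filter is not
  equivalent to per-window filtering followed by |·|).
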
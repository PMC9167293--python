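# Methods

## Pipeline model

A specimen is an H × W × B transmittance cube with band centers
(220, 255, 280, 300) nm. The analysis assumes (i) transmission imaging with
flat-field-corrected intensities, T = (raw − dark)/(bright − dark), clipped
to [0, 1.5] so shot noise above unity survives without letting hot pixels
dominate; (ii) chromatic misalignment between bands that is purely
translational, removed by phase correlation against a reference band; and
(iii) a *single* PC basis fitted to spectra pooled across representative
regions — per-patient refitting is deliberately not supported, since the
biomarker compares patients inside one fixed score space.

Pixels that fail flat-fielding or fall off the border after registration
are flagged in a validity mask that every later stage honours: they enter
no spectral pool, no histogram, and render black in stains.

## PCA domain and centering

The basis is fitted by eigendecomposition of the B × B covariance of the
pooled spectra. Two domains are supported and recorded on the basis:

- `transmittance` (default): PC shapes read directly as transmission-space
  features (the nucleic-acid absorption appears as an *inverted* peak at
  255 nm), and the noise model is closest to additive.
- `optical_density`: −log10(T) with T floored at 1e-4; in this domain
  Beer–Lambert mixtures are exactly linear, so 3-endmember data have exact
  spectral rank 3.

Projections are of centered spectra (standard PCA scores), so the radius of
a score vector measures deviation from the pooled mean spectrum — a
relative concentration. Uncentered projection is available
(`project_cube(..., center=False)`) for users who want absolute magnitudes.

### Sign convention

Eigenvector signs are arbitrary but every downstream angle depends on them,
so `fix_signs` enforces, deterministically and idempotently: PC1 loading
sum ≥ 0 (unipolar, scattering-like); PC2 and PC4 ≥ 0 at the 280 nm protein
band; PC3 ≤ 0 at the 255 nm nucleic-acid band (inverted absorption peak).
Band lookup is by nearest wavelength, so the convention survives slightly
different band sets.

## Spherical geometry and stains

With (x, y, z) the scores on an ordered PC triplet: radius = |(x, y, z)|,
azimuth = atan2(y, x) ∈ (−π, π], elevation = atan2(z, hypot(x, y)) ∈
[−π/2, π/2]. Azimuth is defined as 0 at the poles and at the origin, making
the conversion total; atan2's −π output (possible for y = −0.0) is folded
onto +π so histograms over (−π, π] conserve mass exactly.

Stains are HSV images: hue is a linear clamp of the chosen angle onto
[0, 1], saturation is 1 on valid pixels, value is the radius rescaled by a
[1st, 99th]-percentile clip (robust to outliers). The angle→hue range
defaults to the [1st, 99th] percentile of the rendered image's own angle
distribution — maximal contrast, but image-specific; a fixed
`hue_angle_range` must be supplied whenever stains of different images are
to be color-compared. Angle histograms default to 360 × 180 bins (1°).

## The biomarker

Per patient and gland class, pixels from *all* of the patient's regions are
pooled into one cumulative 2D histogram before any summary is taken (never
a mean of per-region CoMs), the histogram is integrated over elevation, and
the azimuth center of mass is computed **linearly over bin centers** — no
circular wrap. This matches distributions that sit well inside the azimuth
range; if more than 1 % of a marginal's mass lies within 5° of the ±π seam
a warning is raised, and `circular=True` switches to the circular mean.
The histogram weight defaults to `count`; `radius` weighting (emphasising
concentrated spectra) is a switch. Alongside the CoM, the azimuth of the
highest marginal bin is reported as a secondary summary (`peak_azimuth`),
since the two can differ for skewed distributions.

Shifts are Δθ(class) = CoM(class) − CoM(benign) per patient; the benign
shift is exactly 0 by construction, and the calibration is invariant to any
per-patient rotation of the whole azimuth distribution. The phenotype call
is a sign rule with a configurable margin t (default 0): aggressive if
every cancer-grade shift < −t, non-aggressive if every one > +t, otherwise
indeterminate. Stroma and inflammation labels never enter gland
histograms. The biomarker is defined on the PC (1, 2, 3) triplet — the
malignancy-stain space — and `per_class_com` rejects fields from any other
triplet.

## The phantom

`generate_phantom` lays non-overlapping circular glands (annular epithelium
of thickness 0.45 r around an empty lumen) in a stroma background on a
256 × 256 canvas (12 glands of radius 14–22 px by default), assigns each
gland a class cycled from the spec's class list, jitters its abundances by
5 % (per gland, seeded), renders T(λ) = exp(−d Σ c_k ε_k(λ)) and adds
additive Gaussian noise of σ = 0.005 (0.5 % of full-scale transmittance)
before clipping to [0, 1.5].

Endmember shapes are module constants chosen to honour the band
assignments: nucleic acid (0.60, 1.00, 0.55, 0.02) peaking at 255 nm,
protein (0.75, 0.40, 1.00, 0.03) peaking at 280 nm, both ≈0 at 300 nm, and
scattering (λ/220 nm)^−b with b = 2, within the usual tissue power-law
range. Baseline abundances (c_NA, c_prot, s): lumen (0.02, 0.02, 0.05),
stroma (0.15, 0.85, 0.45) — protein-rich — and benign epithelium
(0.65, 0.55, 0.45).

Two presets encode the phenotypes; benign is identical across them:

| class | non_aggressive scale | aggressive scale |
|-------|----------------------|------------------|
| G3    | absorbers ×1.30      | absorbers ×0.85, s ×1.80 |
| G4    | absorbers ×1.60      | absorbers ×0.80, s ×2.10 |
| G5    | —                    | absorbers ×0.75, s ×2.40 |

The non-aggressive preset accumulates nucleic acid and protein with grade
at fixed scattering; the aggressive preset shifts the *composition* toward
scattering in every grade — a higher scattering fraction of the total
attenuation, which is how a scattering-dominated phenotype manifests in a
transmission measurement. A pure additive increase of s at fixed absorbers
moves epithelium scores almost radially in the fitted (PC1, PC2) plane and
barely changes azimuth; the compositional shift has a clear tangential
component opposite to the absorber-up direction, which is why the two
presets rotate the azimuth CoM in opposite directions. Direction, not
magnitude, is the validated quantity: the phantom establishes sign and
grade-ordering of shifts, and no claim is made that its shift magnitudes
(≈5–25° under the defaults) correspond to any real tissue value.

What the phantom does *not* emulate: nuclear texture and subcellular
structure, diffraction/PSF blur, mosaic tiling and stitching seams,
intra-gland heterogeneity beyond a single abundance per gland, and
absorber spectra beyond the two-absorber + scattering model. Tests passing
on phantoms therefore demonstrate correctness of the computation and the
direction logic, not clinical performance on real tissue.

## Numerical choices

- Pooling subsamples to `max_pixels` (default 2e6) with a seeded
  generator; a 4 × 4 covariance does not benefit from more, but the
  subsample must be reproducible and its size is recorded on the basis.
- Registration estimates integer displacements from the peak of the
  normalised cross-power spectrum; optional subpixel refinement is a
  parabolic fit around that peak. A constant band, or a correlation peak
  below 0.1 (pure noise sits near the N^−1/2 floor), yields a zero shift
  with a warning rather than an arbitrary one.
- Rank-deficient covariances produce trailing zero eigenvalues (clipped at
  0), never NaN; a zero-variance pool returns a uniform variance ratio.
- Degenerate stains (empty validity, constant angle, zero radius spread)
  render black rather than dividing by zero.
- Problem sizes in the test suite — 256 × 512-pixel phantom canvases,
  20 phantoms per preset for sign recovery, 10^6-point geometry round
  trips — were chosen as the smallest sizes at which every property is
  exercised with comfortable statistical margin.

## Known limitations

- The linear CoM is meaningful only while azimuth distributions stay clear
  of the ±π seam; the seam warning and the circular-mean option are
  mitigations, not a general fix. A fixed reference rotation of the score
  plane would be needed for data that genuinely straddles the seam.
- The phenotype call is a pure sign rule over whatever cancer grades are
  present; a single noisy grade can flip a patient to indeterminate. The
  threshold parameter exists precisely because a data-derived margin was
  never published.
- One PC basis per cohort means results depend on which regions are pooled
  for the fit; the basis JSON records pixel count, mode and sign-rule
  version so fits are auditable.
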
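# uvpheno

Label-free phenotyping of tissue sections from multispectral deep-UV
transmission microscopy: geometric-PCA **optical stains** and a
benign-referenced **azimuth center-of-mass shift** that quantifies the
glandular phenotype of prostate cancer, including the scattering-dominated
signature of aggressive disease.

## The problem and the method

Thin, unstained tissue sections imaged in transmission at a few deep-UV
wavelengths (220, 255, 280, 300 nm by default) carry endogenous molecular
contrast: nucleic acids absorb around 255 nm, proteins around 280 nm, and
the 300 nm band is dominated by tissue scattering. `uvpheno` turns a stack
of such images — an H × W × B transmittance *cube* — into quantitative
phenotype maps:

1. **Pooled-spectra PCA.** Pixel spectra from representative regions are
   pooled and a single mean-centered principal-component basis of band
   space is fitted (eigendecomposition of the B × B covariance), with a
   deterministic sign convention: PC1 unipolar (scattering-like), PC2/PC4
   positive at the 280 nm protein peak, PC3 negative at the 255 nm
   nucleic-acid peak.
2. **Spherical geometry.** Each pixel's score vector on a PC triplet
   (Proj_i, Proj_j, Proj_k) is converted to spherical coordinates
   (θ, φ, R) = (azimuth, elevation, radius). The two angles encode
   spectral *shape* — molecular composition — while R is a relative
   concentration measure.
3. **Optical stains.** HSV renderings with hue from θ or φ, value from R,
   saturation fixed at 1. Three schemes are built in: `elevation_123`
   (nuclear contrast), `azimuth_234` (stroma contrast), and
   `malignancy_123` (azimuth over PCs 1–3, the malignancy map).
4. **The biomarker.** Per patient and gland class (benign, Gleason grade
   G3/G4/G5), annotated pixels are pooled into one cumulative θ × φ
   histogram, integrated over elevation, and summarised by the azimuth
   center of mass, CoM = Σ θ_j w_j / Σ w_j. The benign-referenced shift
   Δθ(class) = CoM(class) − CoM(benign) removes inter-patient variability;
   uniformly **negative** shifts of all cancer grades (toward
   scattering-dominated azimuths) call the *aggressive* phenotype,
   uniformly positive ones the *non-aggressive* phenotype.

Because real specimens are rarely at hand, the package ships a seeded
Beer–Lambert phantom generator (`uvpheno.phantom`): gland/lumen/stroma
geometry whose pixel spectra are T(λ) = exp(−d Σ c_k ε_k(λ)) mixtures of a
nucleic-acid-like absorber, a protein-like absorber and power-law
scattering, with `non_aggressive` and `aggressive` phenotype presets and
pixel-exact ground-truth annotations.

## Worked example

```python
from uvpheno import GlandPhenotypeModel

model = GlandPhenotypeModel.from_phantoms("aggressive", n_phantoms=2, seed=3)
results = model.fit()
print(results.summary())
```

```
Gland phenotype analysis (benign-referenced azimuth CoM shift)
================================================================
cubes: 2   pooled spectra: 131,072   PCA mode: transmittance
explained variance ratio: PC1 0.9496  PC2 0.0450  PC3 0.0050  PC4 0.0003
first three PCs: 99.97% of variance
----------------------------------------------------------------
patient_id gland_class  n_pixels com_azimuth_deg peak_azimuth_deg relative_shift_deg       phenotype_call
 phantom-3      benign      1862          164.27           166.50               0.00 aggressive_phenotype
 phantom-3          G3      2635          150.60           150.50             -13.67 aggressive_phenotype
 phantom-3          G4      2358          149.06           148.50             -15.21 aggressive_phenotype
 phantom-3          G5      2197          149.62           150.50             -14.65 aggressive_phenotype
 phantom-4      benign      2387          162.38           162.50               0.00 aggressive_phenotype
 phantom-4          G3      2138          151.09           151.50             -11.29 aggressive_phenotype
 phantom-4          G4      2405          149.98           149.50             -12.40 aggressive_phenotype
 phantom-4          G5      2553          149.56           149.50             -12.82 aggressive_phenotype
----------------------------------------------------------------
patient phantom-3: aggressive_phenotype
patient phantom-4: aggressive_phenotype
```

The first three PCs carry 99.97 % of the pooled spectral variance, so the
3-PC spherical representation loses almost nothing. Every cancer grade of
both simulated patients shifts its azimuth CoM by −11° to −15° relative to
that patient's benign glands — the ubiquitous negative shift that marks the
aggressive phenotype — so both patients are called `aggressive_phenotype`.
Benign rows are 0 by construction (self-reference).

The same pipeline is available from the shell:

```sh
uvpheno simulate --preset aggressive --seed 3 --out region0/
uvpheno fit-pca --cubes region0/cube.tif --out basis.json
uvpheno stain --cube region0/cube.tif --basis basis.json \
        --scheme malignancy_123 --out stain.png
uvpheno biomarker --region-dir region0 --basis basis.json --out biomarker.csv
uvpheno run --seed 3 --out out/        # end-to-end, writes manifest.json
```

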
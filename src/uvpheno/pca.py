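"""Pooled-spectra principal component analysis of UV band space.

With B acquisition bands every pixel is a point in a B-dimensional spectral
space.  One PC basis is fitted to spectra pooled across representative
regions (not per patient), then every cube is projected onto a chosen PC
triplet; the angular part of those score vectors is what carries the
molecular phenotype downstream.

Eigenvector sign is mathematically arbitrary but every downstream angle
depends on it, so a deterministic per-PC sign convention is applied after
each fit (:func:`fix_signs`): PC1 unipolar non-negative (scattering-like),
PC2 and PC4 positive at the 280 nm protein peak, PC3 negative at the 255 nm
nucleic-acid peak (inverted absorption peak).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import SpectralCube

__all__ = [
    "PCBasis",
    "ProjectionField",
    "pool_spectra",
    "fit_pca",
    "fix_signs",
    "project_cube",
    "to_optical_density",
]

SIGN_RULE_VERSION = 1

#: Floor applied to transmittance before taking -log10, keeping optical
#: density finite on opaque pixels.
OD_FLOOR = 1e-4


def to_optical_density(transmittance: np.ndarray) -> np.ndarray:
    """Optical density -log10(T), with T floored at :data:`OD_FLOOR`."""
    return -np.log10(np.clip(transmittance, OD_FLOOR, None))


@dataclass
class PCBasis:
    """A fitted, sign-fixed principal-component basis of band space.

    ``loadings`` is B x B with PC ``i`` in row ``i-1``; rows are orthonormal
    and ordered by decreasing explained variance.  ``mode`` records whether
    the fit (and hence any projection) operates on transmittance or on
    optical density.
    """

    loadings: np.ndarray
    mean_spectrum: np.ndarray
    explained_variance_ratio: np.ndarray
    wavelengths_nm: tuple[float, ...]
    fit_pixel_count: int
    mode: str = "transmittance"
    eigenvalues: np.ndarray | None = None
    sign_rule_version: int = SIGN_RULE_VERSION

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=np.float64)
        self.mean_spectrum = np.asarray(self.mean_spectrum, dtype=np.float64)
        self.explained_variance_ratio = np.asarray(
            self.explained_variance_ratio, dtype=np.float64
        )
        if self.mode not in ("transmittance", "optical_density"):
            raise ValueError(f"unknown PCA mode {self.mode!r}")

    @property
    def n_bands(self) -> int:
        return self.loadings.shape[0]

    def band_index(self, wavelength_nm: float) -> int:
        return int(np.argmin(np.abs(np.asarray(self.wavelengths_nm) - wavelength_nm)))

    def validate(self, atol: float = 1e-10) -> None:
        """Assert orthonormality and the variance-ratio invariants."""
        gram = self.loadings @ self.loadings.T
        if not np.allclose(gram, np.eye(self.n_bands), atol=atol):
            raise ValueError("loadings are not orthonormal")
        evr = self.explained_variance_ratio
        if (evr < -atol).any() or (np.diff(evr) > atol).any():
            raise ValueError("explained variance ratios must be non-negative, non-increasing")
        if abs(evr.sum() - 1.0) > atol:
            raise ValueError("explained variance ratios must sum to 1")

    # -- serialisation -----------------------------------------------------
    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "loadings": self.loadings.tolist(),
                    "mean_spectrum": self.mean_spectrum.tolist(),
                    "explained_variance_ratio": self.explained_variance_ratio.tolist(),
                    "eigenvalues": None if self.eigenvalues is None else self.eigenvalues.tolist(),
                    "wavelengths_nm": list(self.wavelengths_nm),
                    "fit_pixel_count": self.fit_pixel_count,
                    "mode": self.mode,
                    "sign_rule_version": self.sign_rule_version,
                },
                indent=1,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PCBasis":
        d = json.loads(Path(path).read_text())
        return cls(
            loadings=np.array(d["loadings"]),
            mean_spectrum=np.array(d["mean_spectrum"]),
            explained_variance_ratio=np.array(d["explained_variance_ratio"]),
            eigenvalues=None if d["eigenvalues"] is None else np.array(d["eigenvalues"]),
            wavelengths_nm=tuple(d["wavelengths_nm"]),
            fit_pixel_count=int(d["fit_pixel_count"]),
            mode=d["mode"],
            sign_rule_version=int(d["sign_rule_version"]),
        )


@dataclass
class ProjectionField:
    """Per-pixel scores of a cube on an ordered PC triplet.

    ``data`` is H x W x 3; invalid pixels carry NaN scores and are excluded
    from every downstream histogram.
    """

    data: np.ndarray
    triplet: tuple[int, int, int]
    validity: np.ndarray

    def __post_init__(self) -> None:
        self.triplet = tuple(int(i) for i in self.triplet)
        if len(set(self.triplet)) != 3:
            raise ValueError(f"triplet indices must be 3 distinct PCs, got {self.triplet}")


def pool_spectra(
    cubes: Sequence[SpectralCube],
    masks: Sequence[np.ndarray] | None = None,
    max_pixels: int = 2_000_000,
    seed: int = 0,
) -> np.ndarray:
    """Pool pixel spectra from valid (and optionally masked) pixels of many
    cubes into one N x B matrix.

    If more than ``max_pixels`` spectra are available a seeded uniform
    subsample of exactly ``max_pixels`` rows is returned, keeping fits on
    very large pools reproducible.
    """
    if not cubes:
        raise ValueError("no cubes to pool")
    wl = cubes[0].wavelengths_nm
    for c in cubes[1:]:
        if c.wavelengths_nm != wl:
            raise ValueError(f"wavelength mismatch across cubes: {wl} vs {c.wavelengths_nm}")
    if masks is not None and len(masks) != len(cubes):
        raise ValueError("need one mask per cube")
    chunks = []
    for i, cube in enumerate(cubes):
        mask = None if masks is None else masks[i]
        chunks.append(cube.valid_spectra(mask))
    spectra = np.concatenate(chunks, axis=0)
    if spectra.shape[0] == 0:
        raise ValueError("no valid pixels to pool")
    if spectra.shape[0] > max_pixels:
        rng = np.random.default_rng(seed)
        idx = rng.choice(spectra.shape[0], size=max_pixels, replace=False)
        spectra = spectra[np.sort(idx)]
    return spectra


def fit_pca(spectra: np.ndarray, mode: str = "transmittance",
            wavelengths_nm: Sequence[float] | None = None) -> PCBasis:
    """Fit a mean-centered PCA to pooled spectra by eigendecomposition of
    the B x B covariance matrix.

    ``mode="optical_density"`` converts T to -log10(T) before fitting; the
    choice is recorded on the basis so projections stay consistent.  Rank
    deficiency yields trailing (near-)zero eigenvalues, never NaN.
    """
    spectra = np.asarray(spectra, dtype=np.float64)
    if spectra.ndim != 2:
        raise ValueError("spectra must be an N x B matrix")
    n, b = spectra.shape
    if n <= b:
        raise ValueError(f"need more spectra ({n}) than bands ({b})")
    if not np.isfinite(spectra).all():
        raise ValueError("spectra contain non-finite values")
    if wavelengths_nm is None:
        from .io import DEFAULT_WAVELENGTHS_NM

        if b != len(DEFAULT_WAVELENGTHS_NM):
            raise ValueError("wavelengths_nm required for non-default band count")
        wavelengths_nm = DEFAULT_WAVELENGTHS_NM
    if mode == "optical_density":
        spectra = to_optical_density(spectra)
    mean = spectra.mean(axis=0)
    cov = np.cov(spectra, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    loadings = evecs[:, order].T
    total = evals.sum()
    evr = evals / total if total > 0 else np.full(b, 1.0 / b)
    basis = PCBasis(
        loadings=loadings,
        mean_spectrum=mean,
        explained_variance_ratio=evr,
        eigenvalues=evals,
        wavelengths_nm=tuple(wavelengths_nm),
        fit_pixel_count=n,
        mode=mode,
    )
    return fix_signs(basis)


def fix_signs(basis: PCBasis) -> PCBasis:
    """Apply the deterministic per-PC sign convention (idempotent).

    PC1: loading sum non-negative (unipolar, scattering-like).
    PC2: 280 nm loading non-negative (protein peak positive).
    PC3: 255 nm loading non-positive (nucleic-acid peak inverted).
    PC4: 280 nm loading non-negative.
    Band lookup is by nearest wavelength; PCs beyond 4 are left as fitted.
    """
    loadings = basis.loadings.copy()
    i255 = basis.band_index(255.0)
    i280 = basis.band_index(280.0)
    flips = {
        0: loadings[0].sum() < 0,
        1: loadings.shape[0] > 1 and loadings[1, i280] < 0,
        2: loadings.shape[0] > 2 and loadings[2, i255] > 0,
        3: loadings.shape[0] > 3 and loadings[3, i280] < 0,
    }
    for row, flip in flips.items():
        if flip:
            loadings[row] = -loadings[row]
    return replace(basis, loadings=loadings)


def project_cube(
    cube: SpectralCube,
    basis: PCBasis,
    triplet: tuple[int, int, int] = (1, 2, 3),
    center: bool = True,
) -> ProjectionField:
    """Project a cube onto an ordered PC triplet.

    Scores are of centered spectra by default (standard PCA scores), so the
    radius of a score vector measures deviation from the pooled mean
    spectrum; ``center=False`` projects raw spectra instead.
    """
    if cube.wavelengths_nm != basis.wavelengths_nm:
        raise ValueError(
            f"cube wavelengths {cube.wavelengths_nm} do not match basis {basis.wavelengths_nm}"
        )
    for i in triplet:
        if not 1 <= i <= basis.n_bands:
            raise ValueError(f"PC index {i} out of range 1..{basis.n_bands}")
    pixels = cube.data.reshape(-1, cube.n_bands)
    if basis.mode == "optical_density":
        pixels = to_optical_density(pixels)
    if center:
        pixels = pixels - basis.mean_spectrum
    rows = [i - 1 for i in triplet]
    scores = pixels @ basis.loadings[rows].T
    scores = scores.reshape(cube.data.shape[0], cube.data.shape[1], 3)
    scores[~cube.validity] = np.nan
    return ProjectionField(data=scores, triplet=tuple(triplet), validity=cube.validity.copy())
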
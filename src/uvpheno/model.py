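"""Model/Results interface over the full phenotyping pipeline.

`GlandPhenotypeModel` is constructed from annotated transmittance cubes (or
directly from a phantom preset) and `fit()` runs pooling -> PCA ->
projection -> spherical conversion -> per-class azimuth CoM -> benign-
referenced shifts -> phenotype calls, returning a `GlandPhenotypeResults`
that carries the fitted PC basis, the tidy biomarker table, per-patient
calls and a printable summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import biomarker as bm
from .geometry import SCHEMES, SphericalField, render_stain, to_spherical
from .io import RegionAnnotation, SpectralCube
from .pca import PCBasis, fit_pca, pool_spectra, project_cube

__all__ = ["GlandPhenotypeModel", "GlandPhenotypeResults"]


class GlandPhenotypeModel:
    """Benign-referenced azimuth-shift phenotyping of annotated UV cubes.

    Parameters
    ----------
    cubes, annotations
        One region annotation per transmittance cube; annotations of the
        same ``patient_id`` are pooled cumulatively.
    mode
        PCA domain, ``"transmittance"`` (default) or ``"optical_density"``.
    az_bins, el_bins
        Resolution of the joint angle histograms (default 1 degree).
    weight
        Histogram weighting, ``"count"`` or ``"radius"``.
    threshold
        Sign-rule margin (radians) for the phenotype call; 0 is the pure
        sign rule.
    max_pool_pixels, seed
        Cap and RNG seed for the pooled-spectra subsample used by the fit.
    """

    def __init__(
        self,
        cubes: Sequence[SpectralCube],
        annotations: Sequence[RegionAnnotation],
        mode: str = "transmittance",
        az_bins: int = 360,
        el_bins: int = 180,
        weight: str = "count",
        threshold: float = 0.0,
        circular_com: bool = False,
        max_pool_pixels: int = 2_000_000,
        seed: int = 0,
    ) -> None:
        cubes = list(cubes)
        annotations = list(annotations)
        if len(cubes) != len(annotations):
            raise ValueError("need one annotation per cube")
        for cube, ann in zip(cubes, annotations):
            ann.check_congruent(cube)
        self.cubes = cubes
        self.annotations = annotations
        self.mode = mode
        self.az_bins = az_bins
        self.el_bins = el_bins
        self.weight = weight
        self.threshold = threshold
        self.circular_com = circular_com
        self.max_pool_pixels = max_pool_pixels
        self.seed = seed

    @classmethod
    def from_phantoms(
        cls,
        preset: str = "non_aggressive",
        n_phantoms: int = 1,
        seed: int = 0,
        phantom_overrides: dict | None = None,
        **model_kwargs,
    ) -> "GlandPhenotypeModel":
        """Build a model on freshly simulated specimens of one preset.

        Each phantom acts as one patient; phantom ``i`` is seeded
        deterministically from ``seed``.
        """
        from .phantom import build_spec, generate_phantom

        cubes, anns = [], []
        for i in range(n_phantoms):
            spec = build_spec(preset, seed=seed + i, **(phantom_overrides or {}))
            cube, ann, _ = generate_phantom(spec)
            cubes.append(cube)
            anns.append(ann)
        return cls(cubes, anns, seed=seed, **model_kwargs)

    def fit(self) -> "GlandPhenotypeResults":
        """Run the full pipeline and return the results object."""
        spectra = pool_spectra(self.cubes, max_pixels=self.max_pool_pixels, seed=self.seed)
        basis = fit_pca(spectra, mode=self.mode, wavelengths_nm=self.cubes[0].wavelengths_nm)
        fields = [
            to_spherical(project_cube(cube, basis, (1, 2, 3))) for cube in self.cubes
        ]
        records = bm.per_class_com(
            fields,
            self.annotations,
            az_bins=self.az_bins,
            el_bins=self.el_bins,
            weight=self.weight,
            circular=self.circular_com,
        )
        shifts = bm.relative_shifts(records)
        calls: dict[str, str] = {}
        for pid in sorted({r.patient_id for r in shifts}):
            patient = [r for r in shifts if r.patient_id == pid]
            try:
                calls[pid] = bm.classify_phenotype(patient, threshold=self.threshold)
            except ValueError:
                calls[pid] = "no_cancer_classes"
        return GlandPhenotypeResults(
            model=self, basis=basis, fields=fields, records=shifts, phenotype_calls=calls
        )


@dataclass
class GlandPhenotypeResults:
    """Fitted basis, spherical fields, biomarker records and phenotype calls."""

    model: GlandPhenotypeModel
    basis: PCBasis
    fields: list[SphericalField]
    records: list[bm.BiomarkerRecord]
    phenotype_calls: dict[str, str]

    @property
    def table(self) -> pd.DataFrame:
        """Tidy per patient x class table (angles in degrees)."""
        return bm.records_to_dataframe(self.records, self.phenotype_calls)

    def shifts(self, patient_id: str) -> dict[str, float]:
        """Class -> relative azimuth shift (radians) for one patient."""
        return {
            r.gland_class: r.relative_shift
            for r in self.records
            if r.patient_id == patient_id
        }

    def render(self, scheme: str = "malignancy_123", cube_index: int = 0) -> np.ndarray:
        """RGB optical stain of one cube under a named scheme."""
        if scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
        sch = SCHEMES[scheme]
        field = self.fields[cube_index]
        if tuple(sch.triplet) != tuple(field.triplet):
            field = to_spherical(
                project_cube(self.model.cubes[cube_index], self.basis, sch.triplet)
            )
        return render_stain(field, sch)

    def summary(self) -> str:
        """Human-readable fit report."""
        evr = self.basis.explained_variance_ratio
        lines = [
            "Gland phenotype analysis (benign-referenced azimuth CoM shift)",
            "=" * 64,
            f"cubes: {len(self.model.cubes)}   pooled spectra: {self.basis.fit_pixel_count:,}"
            f"   PCA mode: {self.basis.mode}",
            "explained variance ratio: "
            + "  ".join(f"PC{i + 1} {v:.4f}" for i, v in enumerate(evr)),
            f"first three PCs: {evr[:3].sum():.2%} of variance",
            "-" * 64,
        ]
        df = self.table
        if not df.empty:
            lines.append(
                df.to_string(
                    index=False,
                    formatters={
                        "com_azimuth_deg": "{:8.2f}".format,
                        "peak_azimuth_deg": "{:8.2f}".format,
                        "relative_shift_deg": "{:8.2f}".format,
                    },
                )
            )
        lines.append("-" * 64)
        for pid, call in self.phenotype_calls.items():
            lines.append(f"patient {pid}: {call}")
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path
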
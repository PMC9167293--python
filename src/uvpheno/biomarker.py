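"""The benign-referenced azimuth center-of-mass malignancy biomarker.

Per patient and gland class (benign, Gleason grade 3/4/5), all annotated
pixels across the patient's regions are pooled into one cumulative
azimuth x elevation histogram in the PC 1-2-3 score space, the histogram is
integrated over elevation, and the center of mass (CoM) of the resulting
azimuth marginal is recorded.  Subtracting each patient's benign CoM
removes the large inter-patient offset; the *sign* of the residual shift of
the cancerous classes is the phenotype call: a uniformly negative shift
(toward the scattering-dominated azimuths) marks the aggressive phenotype,
a uniformly positive shift (toward higher nucleic-acid/protein content)
the non-aggressive one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import AngleHistogram2D, SphericalField, angle_histogram
from .io import CANCER_CLASSES, RegionAnnotation

__all__ = [
    "AzimuthMarginal",
    "ClassCoM",
    "BiomarkerRecord",
    "azimuth_marginal",
    "center_of_mass",
    "marginal_peak",
    "per_class_com",
    "relative_shifts",
    "classify_phenotype",
    "records_to_dataframe",
]

AGGRESSIVE = "aggressive_phenotype"
NON_AGGRESSIVE = "non_aggressive_phenotype"
INDETERMINATE = "indeterminate"

DEFAULT_CLASSES = ("benign",) + CANCER_CLASSES


@dataclass
class AzimuthMarginal:
    """Elevation-integrated azimuth distribution of one histogram."""

    centers: np.ndarray  # bin centers, radians
    mass: np.ndarray  # per-bin mass (counts or summed radius)
    weight_kind: str
    n_pixels: int


@dataclass
class ClassCoM:
    """Azimuth CoM of one patient x gland-class pool (absolute, radians).

    ``peak_azimuth`` is the azimuth of the highest marginal bin, reported as
    a secondary summary alongside the primary center of mass.
    """

    patient_id: str
    gland_class: str
    com_azimuth: float
    peak_azimuth: float
    n_pixels: int


@dataclass
class BiomarkerRecord:
    """Per patient x gland-class CoM and its benign-referenced shift."""

    patient_id: str
    gland_class: str
    com_azimuth: float
    relative_shift: float
    n_pixels: int
    peak_azimuth: float = float("nan")


def azimuth_marginal(hist: AngleHistogram2D) -> AzimuthMarginal:
    """Integrate a 2D angle histogram over elevation; mass is preserved."""
    return AzimuthMarginal(
        centers=hist.az_centers,
        mass=hist.counts.sum(axis=1),
        weight_kind=hist.weight_kind,
        n_pixels=hist.n_pixels,
    )


def center_of_mass(
    marginal: AzimuthMarginal,
    circular: bool = False,
    seam_mass_warn: float = 0.01,
    seam_margin: float = np.deg2rad(5.0),
) -> float:
    """Mass-weighted mean azimuth of a marginal, in radians.

    The default is a plain linear mean over bin centers (no circular wrap),
    appropriate when the distribution sits well inside (-pi, pi); if more
    than ``seam_mass_warn`` of the mass lies within ``seam_margin`` of the
    +-pi seam a warning is raised, and ``circular=True`` switches to the
    circular mean (angle of the mean resultant vector).
    """
    total = marginal.mass.sum()
    if total <= 0:
        raise ValueError("zero total mass: center of mass undefined")
    theta, w = marginal.centers, marginal.mass
    seam = np.abs(np.abs(theta) - np.pi) < seam_margin
    if not circular and w[seam].sum() > seam_mass_warn * total:
        warnings.warn(
            f"{w[seam].sum() / total:.1%} of azimuth mass lies within "
            f"{np.rad2deg(seam_margin):.0f} deg of the +-pi seam; the linear "
            "center of mass may be distorted (consider circular=True)"
        )
    if circular:
        return float(np.arctan2((w * np.sin(theta)).sum(), (w * np.cos(theta)).sum()))
    return float((theta * w).sum() / total)


def marginal_peak(marginal: AzimuthMarginal) -> float:
    """Azimuth of the highest marginal bin (ties -> lowest azimuth)."""
    return float(marginal.centers[int(np.argmax(marginal.mass))])


def _pool_histogram(
    fields: Sequence[SphericalField],
    masks: Sequence[np.ndarray],
    az_bins: int,
    el_bins: int,
    weight: str,
) -> AngleHistogram2D | None:
    pooled = None
    for field, mask in zip(fields, masks):
        if not (mask & field.validity).any():
            continue
        h = angle_histogram(field, mask=mask, az_bins=az_bins, el_bins=el_bins, weight=weight)
        pooled = h if pooled is None else pooled + h
    return pooled


def per_class_com(
    fields: SphericalField | Sequence[SphericalField],
    annotations: RegionAnnotation | Sequence[RegionAnnotation],
    classes: Sequence[str] = DEFAULT_CLASSES,
    az_bins: int = 360,
    el_bins: int = 180,
    weight: str = "count",
    circular: bool = False,
) -> list[ClassCoM]:
    """Cumulative per-patient, per-class azimuth CoM.

    All regions of a patient contribute to *one* histogram per class
    (cumulative pooling, not a mean of per-region CoMs).  Fields must come
    from the PC (1, 2, 3) triplet, the malignancy-stain score space.
    Classes with zero annotated pixels are omitted with a warning.
    """
    if isinstance(fields, SphericalField):
        fields = [fields]
        annotations = [annotations]
    fields = list(fields)
    annotations = list(annotations)
    if len(fields) != len(annotations):
        raise ValueError("need one annotation per field")
    for f in fields:
        if tuple(f.triplet) != (1, 2, 3):
            raise ValueError(
                f"biomarker fields must use PC triplet (1, 2, 3), got {f.triplet}"
            )
    for f, a in zip(fields, annotations):
        if a.labels.shape != f.azimuth.shape:
            raise ValueError("annotation incongruent with field")

    by_patient: dict[str, list[int]] = {}
    for i, ann in enumerate(annotations):
        by_patient.setdefault(ann.patient_id, []).append(i)

    records: list[ClassCoM] = []
    for patient_id, idxs in by_patient.items():
        for cls in classes:
            pooled = _pool_histogram(
                [fields[i] for i in idxs],
                [annotations[i].class_mask(cls) for i in idxs],
                az_bins, el_bins, weight,
            )
            if pooled is None:
                warnings.warn(f"patient {patient_id}: no pixels of class {cls!r}; omitted")
                continue
            marg = azimuth_marginal(pooled)
            records.append(
                ClassCoM(
                    patient_id=patient_id,
                    gland_class=cls,
                    com_azimuth=center_of_mass(marg, circular=circular),
                    peak_azimuth=marginal_peak(marg),
                    n_pixels=pooled.n_pixels,
                )
            )
    return records


def relative_shifts(records: Iterable[ClassCoM]) -> list[BiomarkerRecord]:
    """Benign-referenced shifts: com(class) - com(benign), per patient.

    The benign class's own shift is exactly 0; a patient without a benign
    record cannot be self-calibrated and raises an error.
    """
    records = list(records)
    benign = {r.patient_id: r.com_azimuth for r in records if r.gland_class == "benign"}
    out: list[BiomarkerRecord] = []
    for r in records:
        if r.patient_id not in benign:
            raise ValueError(f"patient {r.patient_id}: no benign reference record")
        shift = 0.0 if r.gland_class == "benign" else r.com_azimuth - benign[r.patient_id]
        out.append(
            BiomarkerRecord(
                patient_id=r.patient_id,
                gland_class=r.gland_class,
                com_azimuth=r.com_azimuth,
                relative_shift=shift,
                n_pixels=r.n_pixels,
                peak_azimuth=r.peak_azimuth,
            )
        )
    return out


def classify_phenotype(shifts: Iterable[BiomarkerRecord], threshold: float = 0.0) -> str:
    """Sign-based phenotype call for one patient.

    Aggressive if *every* cancerous-class shift is below ``-threshold``
    (shift toward scattering-dominated azimuths, across all grades present);
    non-aggressive if every one is above ``+threshold``; indeterminate
    otherwise.  The default threshold 0 is the pure sign rule.
    """
    shifts = list(shifts)
    patients = {r.patient_id for r in shifts}
    if len(patients) > 1:
        raise ValueError(f"classify_phenotype expects one patient, got {sorted(patients)}")
    cancer = [r.relative_shift for r in shifts if r.gland_class in CANCER_CLASSES]
    if not cancer:
        raise ValueError("no cancerous-class shifts: phenotype undefined")
    if all(s < -threshold for s in cancer):
        return AGGRESSIVE
    if all(s > threshold for s in cancer):
        return NON_AGGRESSIVE
    return INDETERMINATE


def records_to_dataframe(
    records: Iterable[BiomarkerRecord], phenotype_calls: dict[str, str] | None = None
) -> pd.DataFrame:
    """Tidy results table (angles reported in degrees at this I/O surface)."""
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "gland_class": r.gland_class,
                "n_pixels": r.n_pixels,
                "com_azimuth_deg": np.rad2deg(r.com_azimuth),
                "peak_azimuth_deg": np.rad2deg(r.peak_azimuth),
                "relative_shift_deg": np.rad2deg(r.relative_shift),
                "phenotype_call": (phenotype_calls or {}).get(r.patient_id, ""),
            }
        )
    order = {c: i for i, c in enumerate(DEFAULT_CLASSES)}
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["patient_id", "gland_class"], key=lambda s: s.map(order) if s.name == "gland_class" else s
        ).reset_index(drop=True)
    return df
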
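"""Seeded Beer-Lambert tissue phantoms for end-to-end pipeline testing.

A phantom is a field of non-overlapping circular glands (annular epithelium
around an empty lumen) embedded in stroma.  Every pixel carries three
abundances — a nucleic-acid-like absorber peaking at 255 nm, a protein-like
absorber peaking at 280 nm, and a power-law scattering attenuation that
decreases monotonically with wavelength — and its 4-band transmittance
follows the Beer-Lambert law, T(lambda) = exp(-d * sum_k c_k * eps_k(lambda)).

Two phenotype presets encode the biological hypotheses the biomarker is
designed to separate: ``non_aggressive`` cancer glands raise nucleic-acid
and protein content above benign levels (cell-overgrowth byproducts), while
``aggressive`` cancer glands instead raise the scattering fraction
(nanoscale tissue reorganisation).  Benign glands are identical across the
two presets.  The epithelium sits spectrally *between* the bright lumen and
the protein-rich stroma, so its PC-score azimuth responds to the
absorber/scatter balance with a stable sign (see docs/methods.md for the
direction argument).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    DEFAULT_WAVELENGTHS_NM,
    TRANSMITTANCE_CEIL,
    RegionAnnotation,
    SpectralCube,
    write_annotation,
    write_cube,
)

__all__ = [
    "EndmemberSet",
    "PhantomSpec",
    "beer_lambert_transmittance",
    "generate_phantom",
    "phenotype_presets",
    "build_spec",
    "write_phantom",
]


@dataclass
class EndmemberSet:
    """Relative attenuation spectra of the three phantom constituents.

    ``epsilon`` rows are dimensionless shapes over the acquisition bands:
    the nucleic-acid row peaks at 255 nm, the protein row at 280 nm, and
    both are near zero at 300 nm, where only scattering attenuates.
    Scattering follows (lambda/lambda0)^-b with lambda0 = 220 nm.
    """

    wavelengths_nm: tuple[float, ...] = DEFAULT_WAVELENGTHS_NM
    epsilon: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "nucleic_acid": (0.60, 1.00, 0.55, 0.02),
            "protein": (0.75, 0.40, 1.00, 0.03),
        }
    )
    scattering_exponent: float = 2.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm)
        na = np.asarray(self.epsilon["nucleic_acid"])
        prot = np.asarray(self.epsilon["protein"])
        if len(na) != len(wl) or len(prot) != len(wl):
            raise ValueError("endmember rows must have one coefficient per band")
        i255 = int(np.argmin(np.abs(wl - 255)))
        i280 = int(np.argmin(np.abs(wl - 280)))
        if np.argmax(na) != i255:
            raise ValueError("nucleic-acid endmember must peak at 255 nm")
        if np.argmax(prot) != i280:
            raise ValueError("protein endmember must peak at 280 nm")
        if self.scattering_exponent <= 0:
            raise ValueError("scattering exponent must be positive")

    @property
    def scattering(self) -> np.ndarray:
        """Per-band scattering attenuation shape, strictly decreasing in lambda."""
        wl = np.asarray(self.wavelengths_nm, dtype=np.float64)
        return (wl / wl[0]) ** (-self.scattering_exponent)

    def matrix(self) -> np.ndarray:
        """3 x B attenuation matrix, rows (nucleic_acid, protein, scattering)."""
        return np.vstack(
            [
                np.asarray(self.epsilon["nucleic_acid"], dtype=np.float64),
                np.asarray(self.epsilon["protein"], dtype=np.float64),
                self.scattering,
            ]
        )


#: Baseline (c_NA, c_protein, s_scatter) abundances per tissue class.
#: Stroma is protein-rich, epithelium nucleic-acid-rich, lumen nearly empty.
BASE_CONCENTRATIONS: dict[str, tuple[float, float, float]] = {
    "lumen": (0.02, 0.02, 0.05),
    "stroma": (0.15, 0.85, 0.45),
    "benign": (0.65, 0.55, 0.45),
}


@dataclass
class PhantomSpec:
    """Full, serialisable description of one synthetic specimen."""

    height: int = 256
    width: int = 256
    n_glands: int = 12
    gland_radius_range: tuple[float, float] = (14.0, 22.0)
    ring_fraction: float = 0.45  # epithelial ring thickness / gland radius
    min_gap: float = 4.0  # minimum stroma gap between gland rims, px
    margin: float = 4.0  # gland-free border, px
    gland_classes: tuple[str, ...] = ("benign",)
    class_concentrations: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(BASE_CONCENTRATIONS)
    )
    thickness: float = 1.0  # relative optical path length d
    noise_sigma: float = 0.005  # additive Gaussian noise, relative to T=1
    concentration_jitter: float = 0.05  # per-gland relative abundance jitter
    seed: int = 0
    patient_id: str | None = None
    endmembers: EndmemberSet = field(default_factory=EndmemberSet)

    def __post_init__(self) -> None:
        for cls, c in self.class_concentrations.items():
            if any(ci < 0 for ci in c):
                raise ValueError(f"negative concentration for class {cls!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        for cls in self.gland_classes:
            if cls not in self.class_concentrations:
                raise ValueError(f"gland class {cls!r} has no concentration entry")
        for required in ("stroma", "lumen"):
            if required not in self.class_concentrations:
                raise ValueError(f"class_concentrations must include {required!r}")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        path.write_text(json.dumps(d, indent=1, default=list))
        return path


def beer_lambert_transmittance(
    concentrations: np.ndarray,
    endmembers: EndmemberSet | None = None,
    thickness: float = 1.0,
) -> SpectralCube:
    """Forward model: abundances (..., 3) -> transmittance cube (..., B).

    T(lambda) = exp(-d * [c_NA*eps_NA + c_prot*eps_prot + s*(lambda/lambda0)^-b]);
    optical densities of independent constituents add, so transmittances
    multiply.
    """
    endmembers = endmembers or EndmemberSet()
    conc = np.asarray(concentrations, dtype=np.float64)
    if conc.shape[-1] != 3:
        raise ValueError("concentrations must have 3 components (c_NA, c_prot, s)")
    if (conc < 0).any():
        raise ValueError("concentrations must be non-negative")
    od = thickness * (conc @ endmembers.matrix())
    return SpectralCube(
        data=np.exp(-od),
        wavelengths_nm=endmembers.wavelengths_nm,
        provenance="beer-lambert forward model",
    )


def _place_glands(spec: PhantomSpec, rng: np.random.Generator) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping gland centers; error if infeasible."""
    placed: list[tuple[float, float, float]] = []
    r_lo, r_hi = spec.gland_radius_range
    max_tries = 200 * max(spec.n_glands, 1)
    tries = 0
    while len(placed) < spec.n_glands:
        if tries >= max_tries:
            raise ValueError(
                f"geometry infeasible: placed {len(placed)}/{spec.n_glands} glands "
                f"of radius {r_lo}-{r_hi} on a {spec.height}x{spec.width} canvas"
            )
        tries += 1
        r = rng.uniform(r_lo, r_hi)
        pad = r + spec.margin
        if 2 * pad >= min(spec.height, spec.width):
            continue
        cy = rng.uniform(pad, spec.height - pad)
        cx = rng.uniform(pad, spec.width - pad)
        if all(
            np.hypot(cy - py, cx - px) >= r + pr + spec.min_gap for py, px, pr in placed
        ):
            placed.append((cy, cx, r))
    return placed


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[SpectralCube, RegionAnnotation, pd.DataFrame]:
    """Render one phantom: transmittance cube, pixel-exact annotation, and
    the ground-truth per-gland abundance table.

    Label 1 is stroma (everything outside glands), labels 2.. are glands in
    placement order; lumina stay label 0 (unassigned).  Equal seeds give
    bit-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]

    conc = np.empty((h, w, 3), dtype=np.float64)
    conc[:] = spec.class_concentrations["stroma"]
    labels = np.ones((h, w), dtype=np.int32)  # stroma everywhere
    class_table: dict[int, str] = {1: "stroma"}
    truth_rows = [
        {"label": 1, "class": "stroma", "cy": np.nan, "cx": np.nan, "radius": np.nan}
        | dict(zip(("c_na", "c_prot", "s_scatter"), spec.class_concentrations["stroma"]))
    ]

    glands = _place_glands(spec, rng)
    for g, (cy, cx, r) in enumerate(glands):
        cls = spec.gland_classes[g % len(spec.gland_classes)]
        label = g + 2
        base = np.asarray(spec.class_concentrations[cls], dtype=np.float64)
        jitter = rng.normal(1.0, spec.concentration_jitter, size=3) if spec.concentration_jitter > 0 else np.ones(3)
        c_gland = np.clip(base * jitter, 0.0, None)
        dist = np.hypot(yy - cy, xx - cx)
        ring = (dist <= r) & (dist > r * (1.0 - spec.ring_fraction))
        lumen = dist <= r * (1.0 - spec.ring_fraction)
        conc[ring] = c_gland
        conc[lumen] = spec.class_concentrations["lumen"]
        labels[ring] = label
        labels[lumen] = 0
        class_table[label] = cls
        truth_rows.append(
            {"label": label, "class": cls, "cy": cy, "cx": cx, "radius": r}
            | dict(zip(("c_na", "c_prot", "s_scatter"), c_gland))
        )

    cube = beer_lambert_transmittance(conc, spec.endmembers, spec.thickness)
    data = cube.data
    if spec.noise_sigma > 0:
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
    data = np.clip(data, 0.0, TRANSMITTANCE_CEIL)
    patient = spec.patient_id or f"phantom-{spec.seed}"
    cube = SpectralCube(
        data=data,
        wavelengths_nm=spec.endmembers.wavelengths_nm,
        provenance=f"phantom seed={spec.seed} classes={spec.gland_classes}",
    )
    annotation = RegionAnnotation(labels=labels, class_table=class_table, patient_id=patient)
    return cube, annotation, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# phenotype presets

#: How each cancer grade scales the benign abundances (c_NA, c_prot, s):
#: the non-aggressive phenotype accumulates absorbers with grade at fixed
#: scattering; the aggressive phenotype shifts the *composition* toward
#: scattering in every grade (s up, absorbers down), i.e. a higher
#: scattering fraction of the total attenuation.
_PRESET_SCALES: dict[str, dict[str, tuple[float, float, float]]] = {
    "non_aggressive": {
        "G3": (1.30, 1.30, 1.00),
        "G4": (1.60, 1.60, 1.00),
    },
    "aggressive": {
        "G3": (0.85, 0.85, 1.80),
        "G4": (0.80, 0.80, 2.10),
        "G5": (0.75, 0.75, 2.40),
    },
}


def phenotype_presets() -> dict[str, dict]:
    """PhantomSpec keyword fragments for the two documented phenotypes.

    Benign, stroma and lumen abundances are identical across presets; only
    the cancer-grade classes differ, in the direction stated above.
    """
    presets: dict[str, dict] = {}
    for name, scales in _PRESET_SCALES.items():
        conc = dict(BASE_CONCENTRATIONS)
        benign = np.asarray(BASE_CONCENTRATIONS["benign"])
        for cls, scale in scales.items():
            conc[cls] = tuple(benign * np.asarray(scale))
        presets[name] = {
            "gland_classes": ("benign",) + tuple(scales),
            "class_concentrations": conc,
        }
    return presets


def build_spec(preset: str, seed: int = 0, **overrides) -> PhantomSpec:
    """A PhantomSpec for a named phenotype preset, with optional overrides."""
    presets = phenotype_presets()
    if preset not in presets:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(presets)}")
    kwargs = dict(presets[preset])
    kwargs.update(overrides)
    return PhantomSpec(seed=seed, **kwargs)


def write_phantom(spec: PhantomSpec, out_dir: str | Path) -> dict[str, Path]:
    """Materialise a phantom on disk: cube TIFF (+ sidecar), label TIFF,
    class CSV, ground-truth CSV and the spec itself as JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cube, annotation, truth = generate_phantom(spec)
    paths = {
        "cube": out_dir / "cube.tif",
        "labels": out_dir / "labels.tif",
        "classes": out_dir / "classes.csv",
        "truth": out_dir / "truth.csv",
        "spec": out_dir / "phantom_spec.json",
    }
    write_cube(cube, paths["cube"])
    write_annotation(annotation, paths["labels"], paths["classes"])
    truth.to_csv(paths["truth"], index=False)
    spec.to_json(paths["spec"])
    return paths
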
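"""Reading, writing and normalising multispectral deep-UV transmission cubes.

A *cube* is an H x W x B stack of transmittance images of one field of view,
acquired at a handful of deep-UV wavelengths (by default 220, 255, 280 and
300 nm, which bracket the nucleic-acid and protein absorption peaks and a
scattering-dominated band).  This module owns the cube container, flat-field
normalisation of raw intensities to transmittance, translation-only channel
registration by phase correlation, and the gland-annotation container that
links integer label masks to histological classes.

Cubes are interchanged as multipage TIFF (one page per wavelength, ascending)
with a JSON sidecar carrying wavelengths, pixel size and provenance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "DEFAULT_WAVELENGTHS_NM",
    "TRANSMITTANCE_CEIL",
    "VALID_CLASSES",
    "CANCER_CLASSES",
    "SpectralCube",
    "RegionAnnotation",
    "read_cube",
    "write_cube",
    "flat_field_correct",
    "register_channels",
    "read_annotation",
    "write_annotation",
]

#: Band centers of the default acquisition protocol, in nm.
DEFAULT_WAVELENGTHS_NM: tuple[float, ...] = (220.0, 255.0, 280.0, 300.0)

#: Ceiling applied to transmittance; admits shot noise above unity without
#: letting hot pixels dominate downstream statistics.
TRANSMITTANCE_CEIL: float = 1.5

#: Histological classes an annotation may carry.
VALID_CLASSES = frozenset(
    {"benign", "G3", "G4", "G5", "stroma", "inflammation", "exclude"}
)

#: Gleason-graded (cancerous) gland classes, in grade order.
CANCER_CLASSES: tuple[str, ...] = ("G3", "G4", "G5")


@dataclass
class SpectralCube:
    """A multispectral transmission image cube.

    Parameters
    ----------
    data
        H x W x B array of transmittance values (dimensionless).
    wavelengths_nm
        The B band centers in nm, strictly increasing.
    validity
        H x W boolean mask; False marks pixels excluded from all pooling
        and histogramming (failed flat-field, registration border, ...).
        Defaults to all-valid.
    pixel_size_um
        Physical pixel pitch in micrometres, if known.
    provenance
        Free-text origin note carried through I/O round trips.
    """

    data: np.ndarray
    wavelengths_nm: tuple[float, ...] = DEFAULT_WAVELENGTHS_NM
    validity: np.ndarray | None = None
    pixel_size_um: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be H x W x B, got shape {self.data.shape}")
        self.wavelengths_nm = tuple(float(w) for w in self.wavelengths_nm)
        if len(self.wavelengths_nm) != self.data.shape[2]:
            raise ValueError(
                f"{self.data.shape[2]} bands but {len(self.wavelengths_nm)} wavelengths"
            )
        if len(self.wavelengths_nm) < 3:
            raise ValueError("a cube needs at least 3 bands")
        if any(b <= a for a, b in zip(self.wavelengths_nm, self.wavelengths_nm[1:])):
            raise ValueError(f"wavelengths must be strictly increasing: {self.wavelengths_nm}")
        if self.validity is None:
            self.validity = np.ones(self.data.shape[:2], dtype=bool)
        else:
            self.validity = np.asarray(self.validity, dtype=bool)
            if self.validity.shape != self.data.shape[:2]:
                raise ValueError("validity mask incongruent with cube")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band whose center is nearest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(np.asarray(self.wavelengths_nm) - wavelength_nm)))

    def valid_spectra(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Return the N x B matrix of spectra at valid (and masked) pixels."""
        keep = self.validity if mask is None else (self.validity & np.asarray(mask, bool))
        return self.data[keep]


@dataclass
class RegionAnnotation:
    """Integer gland/region label mask with its class table.

    ``labels`` uses 0 for unassigned background; every nonzero label that
    occurs in the mask must map to a class in :data:`VALID_CLASSES` through
    ``class_table``.
    """

    labels: np.ndarray
    class_table: Mapping[int, str]
    patient_id: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label mask must be integer-valued")
        self.class_table = {int(k): str(v) for k, v in dict(self.class_table).items()}
        bad = set(self.class_table.values()) - VALID_CLASSES
        if bad:
            raise ValueError(f"unknown annotation class(es): {sorted(bad)}")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.class_table)
        if missing:
            raise ValueError(f"labels present in mask but absent from class table: {sorted(missing)}")

    def class_mask(self, cls: str) -> np.ndarray:
        """Boolean mask of all pixels whose label maps to class ``cls``."""
        members = [lab for lab, c in self.class_table.items() if c == cls]
        return np.isin(self.labels, members)

    def check_congruent(self, cube: SpectralCube) -> None:
        if self.labels.shape != cube.data.shape[:2]:
            raise ValueError(
                f"annotation {self.labels.shape} incongruent with cube {cube.data.shape[:2]}"
            )


# ---------------------------------------------------------------------------
# cube I/O

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_cube(path: str | Path, wavelengths_nm: Sequence[float] | None = None) -> SpectralCube:
    """Read a multipage TIFF cube; channels must already be in ascending
    wavelength order (this function refuses to reorder silently).

    If ``wavelengths_nm`` is omitted, a JSON sidecar written by
    :func:`write_cube` is consulted.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a multipage 2D TIFF, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{path}: non-numeric TIFF data ({arr.dtype})")

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if wavelengths_nm is None:
        wavelengths_nm = meta.get("wavelengths_nm")
        if wavelengths_nm is None:
            raise ValueError(f"{path}: no wavelengths given and no sidecar {sidecar.name}")
    if arr.shape[0] != len(wavelengths_nm):
        raise ValueError(
            f"{path}: {arr.shape[0]} TIFF pages but {len(wavelengths_nm)} wavelengths requested"
        )
    validity = None
    if meta.get("validity_path"):
        validity = tifffile.imread(path.parent / meta["validity_path"]).astype(bool)
    return SpectralCube(
        data=np.moveaxis(arr.astype(np.float64), 0, -1),
        wavelengths_nm=tuple(wavelengths_nm),
        validity=validity,
        pixel_size_um=meta.get("pixel_size_um"),
        provenance=meta.get("provenance", f"read from {path.name}"),
    )


def write_cube(cube: SpectralCube, path: str | Path) -> Path:
    """Write a cube as float32 multipage TIFF plus a JSON metadata sidecar.

    A companion ``*.validity.tif`` is written only when some pixels are
    invalid.  Returns the TIFF path.
    """
    path = Path(path)
    tifffile.imwrite(
        path, np.moveaxis(cube.data, -1, 0).astype(np.float32), photometric="minisblack"
    )
    meta = {
        "wavelengths_nm": list(cube.wavelengths_nm),
        "pixel_size_um": cube.pixel_size_um,
        "provenance": cube.provenance,
        "validity_path": None,
    }
    if not cube.validity.all():
        vpath = path.with_suffix(".validity.tif")
        tifffile.imwrite(vpath, cube.validity.astype(np.uint8))
        meta["validity_path"] = vpath.name
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


# ---------------------------------------------------------------------------
# flat-field normalisation

def flat_field_correct(
    raw: np.ndarray | SpectralCube,
    bright: np.ndarray | SpectralCube,
    dark: np.ndarray | SpectralCube,
    wavelengths_nm: Sequence[float] = DEFAULT_WAVELENGTHS_NM,
    max_invalid_fraction: float = 0.05,
) -> SpectralCube:
    """Convert raw intensities to transmittance, T = (raw-dark)/(bright-dark).

    Pixels where ``bright <= dark`` in any band carry no usable reference and
    are flagged invalid; if their fraction exceeds ``max_invalid_fraction``
    the reference pair is considered unusable and an error is raised.
    Transmittance is clipped to [0, 1.5].
    """
    def as_arr(x):
        return x.data if isinstance(x, SpectralCube) else np.asarray(x, dtype=np.float64)

    if isinstance(raw, SpectralCube):
        wavelengths_nm = raw.wavelengths_nm
    raw_a, bright_a, dark_a = as_arr(raw), as_arr(bright), as_arr(dark)
    if not (raw_a.shape == bright_a.shape == dark_a.shape):
        raise ValueError(
            f"shape mismatch: raw {raw_a.shape}, bright {bright_a.shape}, dark {dark_a.shape}"
        )
    denom = bright_a - dark_a
    bad = (denom <= 0).any(axis=-1)
    frac = bad.mean()
    if frac > max_invalid_fraction:
        raise ValueError(
            f"bright <= dark over {frac:.1%} of pixels "
            f"(limit {max_invalid_fraction:.1%}); reference frames unusable"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (raw_a - dark_a) / denom
    t = np.clip(t, 0.0, TRANSMITTANCE_CEIL)
    t[bad] = 0.0
    return SpectralCube(
        data=t,
        wavelengths_nm=tuple(wavelengths_nm),
        validity=~bad,
        provenance="flat-field corrected",
    )


# ---------------------------------------------------------------------------
# channel registration

def _phase_correlate(ref: np.ndarray, mov: np.ndarray) -> tuple[np.ndarray, float]:
    """Integer displacement of ``mov`` relative to ``ref`` by phase correlation.

    Returns ``(disp, peak)`` where ``mov ~ np.roll(ref, disp, axis=(0, 1))``
    and ``peak`` is the height of the normalised cross-power correlation
    surface (1 for a pure translation of identical content, ~N^-1/2 noise
    floor for unrelated images).
    """
    f_ref = np.fft.fft2(ref)
    f_mov = np.fft.fft2(mov)
    cross = f_ref * np.conj(f_mov)
    mag = np.abs(cross)
    mag[mag == 0] = 1.0
    corr = np.fft.ifft2(cross / mag).real
    peak_idx = np.unravel_index(int(np.argmax(corr)), corr.shape)
    shift = np.array(peak_idx, dtype=np.float64)
    # wrap to signed shifts
    for ax, n in enumerate(corr.shape):
        if shift[ax] > n // 2:
            shift[ax] -= n
    return -shift, float(corr[peak_idx])


def register_channels(
    cube: SpectralCube,
    reference_band: int = 0,
    subpixel: bool = False,
    min_peak: float = 0.1,
) -> tuple[SpectralCube, np.ndarray]:
    """Align every band to ``reference_band`` by translation-only phase
    correlation; chromatic shifts in a fixed transmission optical train are
    predominantly translational.

    Returns the registered cube and the B x 2 array of applied shifts
    (row, col), zero for the reference band.  Bands whose correlation is
    degenerate (constant band, or correlation peak below ``min_peak`` as for
    pure noise) are left untouched with a warning.  Pixels wrapped or
    interpolated across the border are invalidated.
    """
    if cube.n_bands < 2:
        raise ValueError("registration needs at least 2 bands")
    ref = cube.data[:, :, reference_band]
    out = cube.data.copy()
    validity = cube.validity.copy()
    shifts = np.zeros((cube.n_bands, 2))
    for b in range(cube.n_bands):
        if b == reference_band:
            continue
        mov = cube.data[:, :, b]
        if np.ptp(ref) == 0 or np.ptp(mov) == 0:
            warnings.warn(f"band {b}: constant image, registration undefined; zero shift")
            continue
        disp, peak = _phase_correlate(ref, mov)
        if peak < min_peak:
            warnings.warn(
                f"band {b}: correlation peak {peak:.3f} below {min_peak}; "
                "no reliable translation, zero shift"
            )
            continue
        if subpixel:
            disp = disp + _subpixel_refine(ref, mov, disp)
            correction = -disp
            out[:, :, b] = ndimage.shift(mov, correction, order=1, mode="nearest")
        else:
            correction = -np.round(disp)
            out[:, :, b] = np.roll(mov, correction.astype(int), axis=(0, 1))
        shifts[b] = correction
        validity &= _border_valid(cube.data.shape[:2], correction)
    reg = SpectralCube(
        data=out,
        wavelengths_nm=cube.wavelengths_nm,
        validity=validity,
        pixel_size_um=cube.pixel_size_um,
        provenance=(cube.provenance + "; registered").strip("; "),
    )
    return reg, shifts


def _subpixel_refine(ref: np.ndarray, mov: np.ndarray, int_shift: np.ndarray) -> np.ndarray:
    """Parabolic sub-bin refinement of a phase-correlation peak."""
    f_ref = np.fft.fft2(ref)
    f_mov = np.fft.fft2(mov)
    cross = f_ref * np.conj(f_mov)
    mag = np.abs(cross)
    mag[mag == 0] = 1.0
    corr = np.fft.ifft2(cross / mag).real
    frac = np.zeros(2)
    peak = (-int_shift).astype(int)
    for ax in range(2):
        n = corr.shape[ax]
        idx = [peak[0] % corr.shape[0], peak[1] % corr.shape[1]]
        lo, hi = idx.copy(), idx.copy()
        lo[ax] = (idx[ax] - 1) % n
        hi[ax] = (idx[ax] + 1) % n
        c0, c1, c2 = corr[tuple(lo)], corr[tuple(idx)], corr[tuple(hi)]
        denom = c0 - 2 * c1 + c2
        if denom != 0:
            frac[ax] = -0.5 * (c2 - c0) / denom
    return -frac


def _border_valid(shape: tuple[int, int], shift: np.ndarray) -> np.ndarray:
    """Validity mask excluding pixels wrapped/extrapolated by a translation."""
    valid = np.ones(shape, dtype=bool)
    for ax, s in enumerate(shift):
        n = int(np.ceil(abs(s)))
        if n == 0:
            continue
        sl = [slice(None), slice(None)]
        sl[ax] = slice(0, n) if s > 0 else slice(shape[ax] - n, shape[ax])
        valid[tuple(sl)] = False
    return valid


# ---------------------------------------------------------------------------
# annotations

def read_annotation(label_path: str | Path, class_table_path: str | Path) -> RegionAnnotation:
    """Read an integer label mask (TIFF/PNG) and its CSV class table.

    The table needs columns ``label,class,patient_id`` and must describe a
    single patient; unknown class names and unmapped labels are rejected by
    :class:`RegionAnnotation`.
    """
    label_path = Path(label_path)
    if label_path.suffix.lower() in {".tif", ".tiff"}:
        labels = tifffile.imread(label_path)
    else:
        labels = iio.imread(label_path)
    if labels.ndim != 2:
        raise ValueError(f"{label_path}: label mask must be 2D, got shape {labels.shape}")
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError(f"{label_path}: label mask must be integer, got {labels.dtype}")
    table = pd.read_csv(class_table_path)
    required = {"label", "class", "patient_id"}
    if not required.issubset(table.columns):
        raise ValueError(f"class table needs columns {sorted(required)}, got {list(table.columns)}")
    patients = table["patient_id"].unique()
    if len(patients) != 1:
        raise ValueError(f"class table must describe one patient, got {list(patients)}")
    class_table = dict(zip(table["label"].astype(int), table["class"].astype(str)))
    return RegionAnnotation(labels=labels, class_table=class_table, patient_id=str(patients[0]))


def write_annotation(ann: RegionAnnotation, label_path: str | Path, class_table_path: str | Path) -> None:
    """Write the label mask as uint16 TIFF and the class table as CSV."""
    tifffile.imwrite(Path(label_path), ann.labels.astype(np.uint16))
    pd.DataFrame(
        {
            "label": list(ann.class_table.keys()),
            "class": list(ann.class_table.values()),
            "patient_id": ann.patient_id,
        }
    ).to_csv(class_table_path, index=False)
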
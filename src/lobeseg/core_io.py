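"""Core image containers, label conventions, and volume/label-map I/O.

Conventions used throughout the package
---------------------------------------
* Arrays are indexed ``(z, y, x)`` with 0-based indices.
* ``z`` increases toward the feet (index 0 is the most cranial slice),
  ``y`` increases toward the anterior chest wall, ``x`` increases toward
  the patient's left side.
* ``spacing`` and ``origin`` are per-axis physical values in mm, in the
  same ``(z, y, x)`` order; physical position = origin + index * spacing.
* CT intensities are Hounsfield units (HU), stored as integers and
  clamped to [-1024, 3071] on read.

Lobe label codes
----------------
0 background, 1 RUL (right upper), 2 RML (right middle), 3 RLL (right
lower), 4 LUL (left upper), 5 LLi (lingula), 6 LLL (left lower).  In
``five_lobe`` mode the lingula is merged into the LUL and code 5 never
occurs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import DimensionalityError, FormatError, GridMismatchError, ValidationError

log = logging.getLogger(__name__)

HU_MIN = -1024
HU_MAX = 3071

LOBE_NAMES = {1: "RUL", 2: "RML", 3: "RLL", 4: "LUL", 5: "LLi", 6: "LLL"}
RIGHT_CODES = (1, 2, 3)
LEFT_CODES = (4, 5, 6)
ALL_CODES = RIGHT_CODES + LEFT_CODES

_SUFFIXES = (".nii.gz", ".nii", ".mha", ".mhd")


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValidationError(f"spacing must be 3 positive values, got {spacing}")
    return spacing


@dataclass
class CTVolume:
    """A 3-D CT scalar volume in Hounsfield units with physical metadata."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    phase: str = "insp"
    kernel: str = "soft"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise DimensionalityError(f"CTVolume requires a 3-D array, got ndim={self.voxels.ndim}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValidationError("CTVolume voxels must be an integer (HU) array")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.phase not in ("insp", "exp"):
            raise ValidationError(f"phase must be 'insp' or 'exp', got {self.phase!r}")
        if self.kernel not in ("soft", "sharp"):
            raise ValidationError(f"kernel must be 'soft' or 'sharp', got {self.kernel!r}")
        lo, hi = int(self.voxels.min(initial=0)), int(self.voxels.max(initial=0))
        if lo < HU_MIN or hi > HU_MAX:
            raise ValidationError(f"HU values outside [{HU_MIN}, {HU_MAX}]: range [{lo}, {hi}]")

    @classmethod
    def from_hu(cls, hu: np.ndarray, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                phase: str = "insp", kernel: str = "soft") -> "CTVolume":
        """Build from a float HU array, rounding and clamping to the valid range."""
        arr = np.rint(np.asarray(hu, dtype=np.float64))
        n_out = int(np.count_nonzero((arr < HU_MIN) | (arr > HU_MAX)))
        if n_out:
            log.info("clamping %d HU values to [%d, %d]", n_out, HU_MIN, HU_MAX)
        arr = np.clip(arr, HU_MIN, HU_MAX).astype(np.int16)
        return cls(arr, spacing, origin, phase, kernel)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class BinaryMask:
    """A boolean mask on a CT grid."""

    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise DimensionalityError(f"BinaryMask requires a 3-D array, got ndim={self.mask.ndim}")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def count(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class LobeMap:
    """An integer lobe label volume on a CT grid."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mode: str = "six_lobe"

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DimensionalityError(f"LobeMap requires a 3-D array, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.uint8)
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.validate()

    def validate(self) -> None:
        present = np.unique(self.labels)
        bad = [int(v) for v in present if v not in (0,) + ALL_CODES]
        if bad:
            raise ValidationError(f"LobeMap contains invalid label codes {bad}")
        if self.mode not in ("six_lobe", "five_lobe"):
            raise ValidationError(f"mode must be 'six_lobe' or 'five_lobe', got {self.mode!r}")
        if self.mode == "five_lobe" and 5 in present:
            raise ValidationError("five_lobe map must not contain lingula code 5")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def present_codes(self) -> tuple[int, ...]:
        return tuple(int(c) for c in np.unique(self.labels) if c != 0)

    def lobe_mask(self, code: int) -> BinaryMask:
        return BinaryMask(self.labels == code, self.spacing, self.origin)


def assert_same_grid(a, b, rtol: float = 1e-6) -> None:
    """Raise :class:`GridMismatchError` unless ``a`` and ``b`` share a voxel grid.

    Both arguments must expose ``shape`` and ``spacing``.  Spacings agree
    when within ``rtol`` relative tolerance (default 1e-6).
    """
    if tuple(a.shape) != tuple(b.shape):
        raise GridMismatchError(f"shape mismatch: {tuple(a.shape)} vs {tuple(b.shape)}")
    sa, sb = np.asarray(a.spacing, float), np.asarray(b.spacing, float)
    if not np.allclose(sa, sb, rtol=rtol, atol=0.0):
        raise GridMismatchError(f"spacing mismatch: {tuple(sa)} vs {tuple(sb)}")


# ---------------------------------------------------------------------------
# File I/O.  Volumes and label maps travel as NIfTI-1 or MetaImage; the
# phase/kernel (or lobe-count mode) tags, which neither format reserves a
# field for, ride in a JSON sidecar with the same basename + ".meta.json".
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in _SUFFIXES:
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".meta.json")
    return path.with_name(name + ".meta.json")


def _check_suffix(path: Path) -> None:
    if not any(path.name.endswith(s) for s in _SUFFIXES):
        raise FormatError(f"unsupported image format for {path} (use {_SUFFIXES})")


def _read_image(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    _check_suffix(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # noqa: BLE001 - SimpleITK raises RuntimeError
        raise FormatError(f"unreadable image {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise DimensionalityError(f"{path} is {img.GetDimension()}-D, expected a 3-D volume")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return arr, spacing, origin


def _write_image(arr: np.ndarray, spacing, origin, path: Path) -> None:
    path = Path(path)
    _check_suffix(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    img.SetSpacing(tuple(reversed([float(s) for s in spacing])))
    img.SetOrigin(tuple(reversed([float(o) for o in origin])))
    sitk.WriteImage(img, str(path))


def read_volume(path) -> CTVolume:
    """Read a CT volume (NIfTI-1 or MetaImage) with phase/kernel sidecar tags.

    Out-of-range HU values are clamped to [-1024, 3071] with a logged count.
    Missing sidecar tags default to inspiratory phase / soft kernel.
    """
    path = Path(path)
    arr, spacing, origin = _read_image(path)
    phase, kernel = "insp", "soft"
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        phase = meta.get("phase", phase)
        kernel = meta.get("kernel", kernel)
    else:
        log.warning("no sidecar %s; defaulting phase=insp kernel=soft", sidecar.name)
    return CTVolume.from_hu(arr, spacing, origin, phase, kernel)


def write_volume(vol: CTVolume, path) -> None:
    path = Path(path)
    _write_image(vol.voxels.astype(np.int16), vol.spacing, vol.origin, path)
    _sidecar_path(path).write_text(
        json.dumps({"phase": vol.phase, "kernel": vol.kernel}, indent=0) + "\n"
    )


def read_labelmap(path) -> LobeMap:
    """Read a lobe label map; mode comes from the sidecar (default six_lobe)."""
    path = Path(path)
    arr, spacing, origin = _read_image(path)
    mode = "six_lobe"
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        mode = json.loads(sidecar.read_text()).get("mode", mode)
    return LobeMap(arr.astype(np.uint8), spacing, origin, mode)


def write_labelmap(lobemap: LobeMap, path) -> None:
    lobemap.validate()
    path = Path(path)
    _write_image(lobemap.labels.astype(np.uint8), lobemap.spacing, lobemap.origin, path)
    _sidecar_path(path).write_text(json.dumps({"mode": lobemap.mode}, indent=0) + "\n")
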
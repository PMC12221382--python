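"""Image and label-map containers with physical pixel size, plus I/O.

Histology tiles arrive as 8- or 16-bit TIFF/PNG, grayscale or RGB, exported
at a known resolution (0.249 μm/px for the BAT sections this package was
written for).  Everything downstream works on an *inverted grayscale*
representation in which lipid droplets — bright, unstained vacuoles in the
raw H&E image — become the dark phase.  Label maps are integer images where
0 is background and each positive id is one droplet instance; their I/O is
bit-exact.

Coordinate convention: row-major arrays, origin at the top-left corner,
pixel-center sampling.  Areas in px² convert to μm² via ``pixel_size_um**2``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image as _PILImage

from .errors import ImageIOError, LabelDTypeError, MissingPixelSizeError, ValidationError

#: Default extraction resolution of the BAT histology tiles, μm per pixel.
DEFAULT_PIXEL_SIZE_UM = 0.249

#: ITU-R BT.709 luminance weights used to collapse RGB to gray.
LUMINANCE_WEIGHTS = (0.2125, 0.7154, 0.0721)

_MIN_SIDE = 16


def _bit_depth_of(dtype: np.dtype) -> int:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    raise ValidationError(f"unsupported intensity dtype {dtype!r}; expected uint8 or uint16")


@dataclasses.dataclass(frozen=True)
class IntensityImage:
    """A 2D intensity image (optionally RGB) with physical pixel size.

    Parameters
    ----------
    pixels
        ``(H, W)`` grayscale or ``(H, W, 3)`` RGB array of uint8/uint16.
    pixel_size_um
        Physical side length of one pixel in μm (> 0).
    """

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValidationError(f"expected (H, W) or (H, W, 3) pixels, got shape {px.shape}")
        if px.shape[0] < _MIN_SIDE or px.shape[1] < _MIN_SIDE:
            raise ValidationError(f"image must be at least {_MIN_SIDE}×{_MIN_SIDE}, got {px.shape[:2]}")
        if not self.pixel_size_um > 0:
            raise ValidationError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        _bit_depth_of(px.dtype)
        object.__setattr__(self, "pixels", px)

    @property
    def bit_depth(self) -> int:
        return _bit_depth_of(self.pixels.dtype)

    @property
    def max_intensity(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def needs_preprocessing(self) -> bool:
        """RGB images must pass through :func:`to_inverted_gray` first."""
        return self.is_rgb

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclasses.dataclass(frozen=True)
class LabelMap:
    """An instance label map: 0 = background, positive ids = droplets."""

    labels: np.ndarray
    pixel_size_um: float
    scale_tag: str | None = None

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValidationError(f"label map must be 2D, got shape {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            raise LabelDTypeError(f"label map must be integer-valued, got dtype {lab.dtype}")
        if lab.size and lab.min() < 0:
            raise ValidationError("label map contains negative ids")
        if not self.pixel_size_um > 0:
            raise ValidationError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        object.__setattr__(self, "labels", lab)

    @property
    def ids(self) -> np.ndarray:
        """Sorted array of distinct positive label ids."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_labels(self) -> int:
        return int(self.ids.size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _pixel_size_from_tiff(path: Path) -> float | None:
    """Recover μm/px from the description JSON (exact) or resolution tags."""
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            if page.description:
                try:
                    meta = json.loads(page.description)
                    if "pixel_size_um" in meta:
                        return float(meta["pixel_size_um"])
                except (ValueError, TypeError):
                    pass
            xres = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if xres is None:
                return None
            num, den = xres.value
            if num == 0:
                return None
            px_per_unit = num / den
            # RESUNIT.CENTIMETER → px/cm; convert to μm/px
            if unit is not None and getattr(unit.value, "value", unit.value) == 3:
                return 1e4 / px_per_unit
            return None
    except Exception:
        return None


def read_image(path: str | Path, pixel_size_um: float | None = None) -> IntensityImage:
    """Read a TIFF/PNG intensity image.

    ``pixel_size_um`` overrides any embedded resolution; if neither is
    available a :class:`MissingPixelSizeError` is raised.  RGB inputs are
    passed through unchanged (``needs_preprocessing`` is set).
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such file: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
            embedded = _pixel_size_from_tiff(path)
        else:
            arr = np.asarray(_PILImage.open(path))
            embedded = None
    except ImageIOError:
        raise
    except Exception as exc:  # pragma: no cover - format corruption path
        raise ImageIOError(f"could not read {path}: {exc}") from exc
    if pixel_size_um is None:
        pixel_size_um = embedded
    if pixel_size_um is None:
        raise MissingPixelSizeError(
            f"{path}: no pixel size supplied and none embedded; pass pixel_size_um explicitly"
        )
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha from RGBA PNGs
        arr = arr[:, :, :3]
    return IntensityImage(pixels=arr, pixel_size_um=float(pixel_size_um))


def write_image(image: IntensityImage, path: str | Path) -> None:
    """Write an intensity image; TIFF output embeds the pixel size."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        px_per_cm = 1e4 / image.pixel_size_um
        tifffile.imwrite(
            path,
            image.pixels,
            resolution=(px_per_cm, px_per_cm),
            resolutionunit="CENTIMETER",
            description=json.dumps({"pixel_size_um": image.pixel_size_um}),
        )
    else:
        _PILImage.fromarray(image.pixels).save(path)


def read_label_map(
    path: str | Path,
    pixel_size_um: float | None = None,
    scale_tag: str | None = None,
) -> LabelMap:
    """Read an integer label map (16-bit single-channel TIFF preferred)."""
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such file: {path}")
    try:
        arr = tifffile.imread(path) if path.suffix.lower() in (".tif", ".tiff") else np.asarray(_PILImage.open(path))
    except Exception as exc:
        raise ImageIOError(f"could not read {path}: {exc}") from exc
    if not np.issubdtype(arr.dtype, np.integer):
        raise LabelDTypeError(f"{path}: label maps must hold integers, found dtype {arr.dtype}")
    if pixel_size_um is None and path.suffix.lower() in (".tif", ".tiff"):
        pixel_size_um = _pixel_size_from_tiff(path)
    if pixel_size_um is None:
        raise MissingPixelSizeError(f"{path}: no pixel size supplied and none embedded")
    return LabelMap(labels=arr, pixel_size_um=float(pixel_size_um), scale_tag=scale_tag)


def write_label_map(label_map: LabelMap, path: str | Path) -> None:
    """Write a label map as 16-bit TIFF (32-bit if ids overflow), bit-exact."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lab = label_map.labels
    dtype = np.uint16 if (lab.size == 0 or lab.max() < 2 ** 16) else np.uint32
    px_per_cm = 1e4 / label_map.pixel_size_um
    tifffile.imwrite(
        path,
        lab.astype(dtype),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        description=json.dumps({"pixel_size_um": label_map.pixel_size_um}),
    )


# ---------------------------------------------------------------------------
# Working representation
# ---------------------------------------------------------------------------

def to_inverted_gray(
    image: IntensityImage,
    weights: tuple[float, float, float] = LUMINANCE_WEIGHTS,
) -> IntensityImage:
    """Convert to the inverted-grayscale working representation.

    RGB is collapsed by luminance weighting (BT.709 by default), then the
    image is inverted: ``out = max_intensity − gray``.  In raw H&E tiles the
    lipid droplets are the bright, unstained phase; after inversion they are
    the dark phase, which is the polarity the reference detector assumes.

    Note this transform is an involution on grayscale input (two applications
    restore the original), so it must be applied exactly once in a pipeline.
    """
    px = image.pixels
    if px.ndim == 3:
        w = np.asarray(weights, dtype=np.float64)
        gray = px.astype(np.float64) @ w
        gray = np.rint(gray).astype(px.dtype)
    else:
        gray = px
    inverted = (image.max_intensity - gray.astype(np.int64)).astype(px.dtype if px.ndim == 2 else gray.dtype)
    return IntensityImage(pixels=inverted, pixel_size_um=image.pixel_size_um)
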
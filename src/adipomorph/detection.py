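"""Per-scale droplet detection: detector contract, reference detector and
the per-scale size-bandwidth filter.

The production analysis runs one trained segmentation model per inference
scale (a small scale around 2 μm / 8 px and a large one around 13.68 μm /
54.9 px) and then filters each scale's label map with a diameter bandwidth
adapted to that scale.  Trained models are plugged in through
:func:`detect_with`; :func:`reference_detect` is a self-contained classical
stand-in (smoothing → Otsu → distance-transform watershed) so the pipeline
runs end to end without model weights — it is not a reproduction of the
trained models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .errors import ValidationError
from .imaging_io import IntensityImage, LabelMap


@dataclass(frozen=True)
class ScaleSpec:
    """One inference scale and its diameter bandwidth.

    ``bandwidth_um`` is the closed interval of equivalent diameters (μm) a
    detection at this scale may have; endpoints are kept.  Consistency of
    the nominal diameter in μm and px is checked to 5% against the image
    pixel size at detection time.
    """

    name: str
    nominal_diameter_um: float
    nominal_diameter_px: float
    bandwidth_um: tuple[float, float]

    def __post_init__(self) -> None:
        d_min, d_max = self.bandwidth_um
        if not (0 < d_min < d_max):
            raise ValidationError(f"bandwidth needs 0 < d_min < d_max, got {self.bandwidth_um}")
        if self.nominal_diameter_um <= 0 or self.nominal_diameter_px <= 0:
            raise ValidationError("nominal diameters must be > 0")

    def validate_pixel_size(self, pixel_size_um: float) -> None:
        implied = self.nominal_diameter_px * pixel_size_um
        if abs(implied - self.nominal_diameter_um) > 0.05 * self.nominal_diameter_um:
            raise ValidationError(
                f"scale {self.name!r}: nominal {self.nominal_diameter_px} px at "
                f"{pixel_size_um} μm/px is {implied:.3g} μm, more than 5% from "
                f"the declared {self.nominal_diameter_um} μm"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "ScaleSpec":
        d = dict(d)
        d["bandwidth_um"] = tuple(d["bandwidth_um"])
        return cls(**d)


#: Default two-scale configuration.  Bandwidths are free choices (the study
#: states only that each scale is filtered with an adapted bandwidth); they
#: overlap on purpose in the 6–8 μm band so that fusion arbitrates it.
SMALL_SCALE = ScaleSpec("small", 2.0, 8.0, (1.0, 8.0))
LARGE_SCALE = ScaleSpec("large", 13.68, 54.9, (6.0, 120.0))

Detector = Callable[[IntensityImage, ScaleSpec], LabelMap]


def detect_with(detector: Detector, image: IntensityImage, scale: ScaleSpec) -> LabelMap:
    """Run any detector satisfying the contract and validate its output.

    The output must be a :class:`LabelMap` of the input shape with
    non-negative integer ids (instances are disjoint by construction in a
    single-channel map) and the input's pixel size.
    """
    out = detector(image, scale)
    if not isinstance(out, LabelMap):
        raise ValidationError(f"detector returned {type(out).__name__}, expected LabelMap")
    if out.shape != image.shape:
        raise ValidationError(f"detector output shape {out.shape} != image shape {image.shape}")
    if out.pixel_size_um != image.pixel_size_um:
        raise ValidationError("detector changed the pixel size")
    return out


def reference_detect(
    image: IntensityImage,
    scale: ScaleSpec,
    polarity: str = "dark",
    exclude_border_labels: bool = False,
) -> LabelMap:
    """Classical droplet detector tuned by the scale's nominal diameter.

    Pipeline: Gaussian smoothing (sigma = nominal_diameter_px / 8) → global
    Otsu threshold, keeping the droplet-polarity side (``"dark"`` for the
    inverted-grayscale working representation) → hole filling →
    distance-transform peak seeding (min separation = nominal_diameter_px/2)
    → watershed split → connected labels.  The threshold is relative, so
    the output is invariant to uniform intensity offsets.  An empty
    foreground yields an empty map, not an error.
    """
    if image.is_rgb:
        raise ValidationError("reference_detect expects the inverted-gray working image")
    if polarity not in ("dark", "bright"):
        raise ValidationError(f"polarity must be 'dark' or 'bright', got {polarity!r}")
    scale.validate_pixel_size(image.pixel_size_um)

    sigma = scale.nominal_diameter_px / 8.0
    smoothed = ndi.gaussian_filter(image.pixels.astype(np.float64), sigma=sigma)
    if np.ptp(smoothed) == 0:
        return LabelMap(np.zeros(image.shape, dtype=np.int32), image.pixel_size_um, scale.name)
    t = threshold_otsu(smoothed)
    mask = smoothed < t if polarity == "dark" else smoothed > t
    mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        return LabelMap(np.zeros(image.shape, dtype=np.int32), image.pixel_size_um, scale.name)

    distance = ndi.distance_transform_edt(mask)
    min_sep = max(1, int(round(scale.nominal_diameter_px / 2.0)))
    peaks = peak_local_max(distance, min_distance=min_sep, labels=mask, exclude_border=False)
    markers = np.zeros(image.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels = cc_label(mask, connectivity=1).astype(np.int32)
    else:
        labels = watershed(-distance, markers, mask=mask).astype(np.int32)

    if exclude_border_labels:
        border_ids = np.unique(
            np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
        )
        labels[np.isin(labels, border_ids[border_ids > 0])] = 0

    # renumber to consecutive ids for a stable contract
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    return LabelMap(lut[labels], image.pixel_size_um, scale.name)


def label_equivalent_diameters_um(label_map: LabelMap) -> dict[int, float]:
    """Equivalent diameter (μm) of every positive label, by pixel counting."""
    lab = label_map.labels
    counts = np.bincount(lab.ravel())
    out = {}
    for i in range(1, counts.size):
        if counts[i] > 0:
            area_um2 = counts[i] * label_map.pixel_size_um ** 2
            out[i] = 2.0 * math.sqrt(area_um2 / math.pi)
    return out


def bandwidth_filter(label_map: LabelMap, scale: ScaleSpec) -> LabelMap:
    """Keep labels whose equivalent diameter lies in the scale's closed bandwidth.

    Survivors keep their ids; removed labels' pixels become background.
    Idempotent, and never increases the label count.
    """
    d_min, d_max = scale.bandwidth_um
    diam = label_equivalent_diameters_um(label_map)
    keep = {i for i, d in diam.items() if d_min <= d <= d_max}
    out = label_map.labels.copy()
    drop_mask = ~np.isin(out, list(keep)) & (out != 0) if keep else out != 0
    out[drop_mask] = 0
    return LabelMap(out, label_map.pixel_size_um, label_map.scale_tag or scale.name)
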
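"""End-to-end convenience: image → per-scale detection → bandwidth filter →
multi-scale fusion → droplet table."""

from __future__ import annotations

import pandas as pd

from .detection import LARGE_SCALE, SMALL_SCALE, Detector, ScaleSpec, bandwidth_filter, detect_with, reference_detect
from .fusion import DEFAULT_OCCUPANCY_THRESHOLD, FusedLabelMap, fuse
from .imaging_io import IntensityImage, LabelMap, to_inverted_gray
from .morphometry import measure


def segment_droplets(
    image: IntensityImage,
    scales: tuple[ScaleSpec, ...] = (SMALL_SCALE, LARGE_SCALE),
    detector: Detector = reference_detect,
    threshold: float = DEFAULT_OCCUPANCY_THRESHOLD,
    invert: bool = True,
) -> FusedLabelMap:
    """Detect droplets at every scale and fuse the filtered maps.

    ``invert=True`` applies the inverted-grayscale preprocessing first (set
    it to False if the image is already in the working representation).
    """
    working = to_inverted_gray(image) if invert else image
    filtered = []
    for scale in scales:
        labels = detect_with(detector, working, scale)
        filtered.append((bandwidth_filter(labels, scale), scale))
    return fuse(filtered, threshold=threshold)


def fuse_label_maps(
    maps: list[tuple[LabelMap, ScaleSpec]],
    threshold: float = DEFAULT_OCCUPANCY_THRESHOLD,
    apply_bandwidth: bool = True,
) -> FusedLabelMap:
    """Fuse externally produced per-scale maps, optionally bandwidth-filtered."""
    if apply_bandwidth:
        maps = [(bandwidth_filter(lm, spec), spec) for lm, spec in maps]
    return fuse(maps, threshold=threshold)


def measure_image(
    image: IntensityImage,
    image_id: str = "",
    group: str = "",
    **segment_kwargs,
) -> tuple[FusedLabelMap, pd.DataFrame]:
    """Segment one section and return (fused map, droplet table)."""
    fused = segment_droplets(image, **segment_kwargs)
    return fused, measure(fused, image_id=image_id, group=group)
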
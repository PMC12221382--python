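"""Multi-scale label fusion with the overlap-occupancy acceptance rule.

Per-scale droplet maps are merged by adding scales successively in order of
increasing nominal scale.  A candidate label is accepted only if strictly
less than a threshold fraction (default 10%) of its area is already occupied
by labels accepted before it; an accepted label claims only the pixels that
are still free, so smaller-scale geometry is never altered by later scales.
Acceptance decisions and original vs accepted areas are recorded in a
provenance table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import ScaleSpec
from .errors import ValidationError
from .imaging_io import LabelMap

logger = logging.getLogger(__name__)

DEFAULT_OCCUPANCY_THRESHOLD = 0.10

PROVENANCE_COLUMNS = [
    "global_id", "scale", "source_label", "original_area_px", "accepted_area_px", "accepted",
]


@dataclass(frozen=True)
class FusedLabelMap:
    """Fusion result: global label map + per-label provenance.

    ``provenance`` has one row per candidate label (accepted or rejected):
    global_id (pd.NA when rejected), scale, source_label, original_area_px,
    accepted_area_px (0 when rejected), accepted.
    """

    labels: LabelMap
    provenance: pd.DataFrame
    occupancy_threshold: float

    def __post_init__(self) -> None:
        accepted = self.provenance[self.provenance["accepted"]]
        gids = accepted["global_id"].to_numpy()
        if gids.size and not np.array_equal(np.sort(gids), np.arange(1, gids.size + 1)):
            raise ValidationError("global ids must be consecutive from 1")

    @property
    def n_labels(self) -> int:
        return self.labels.n_labels


def occupancy(label_mask: np.ndarray, fused_labels: np.ndarray) -> float:
    """Fraction of a candidate label's pixels already occupied in the fused map.

    ``label_mask`` is the candidate's boolean footprint; ``fused_labels`` the
    integer fused map so far.  Raises on an empty candidate.
    """
    label_mask = np.asarray(label_mask, dtype=bool)
    n = int(label_mask.sum())
    if n == 0:
        raise ValidationError("occupancy of an empty label is undefined")
    occupied = int((np.asarray(fused_labels)[label_mask] != 0).sum())
    return occupied / n


def fuse(
    maps: list[tuple[LabelMap, ScaleSpec]],
    threshold: float = DEFAULT_OCCUPANCY_THRESHOLD,
) -> FusedLabelMap:
    """Merge per-scale label maps, ascending scale, under the occupancy rule.

    Scales are processed in ascending ``nominal_diameter_um`` (the list is
    sorted, with a log message, if not already ordered); within a scale,
    labels are visited by ascending source id.  A label is accepted iff its
    occupancy against the fused map as it stands is strictly below
    ``threshold``; accepted labels claim only currently-free pixels and get
    the next global id.
    """
    if not maps:
        raise ValidationError("fuse needs at least one (LabelMap, ScaleSpec) pair")
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError(f"threshold must lie in [0, 1], got {threshold}")
    shape = maps[0][0].shape
    pixel_size = maps[0][0].pixel_size_um
    for lm, _ in maps:
        if lm.shape != shape:
            raise ValidationError(f"shape mismatch: {lm.shape} vs {shape}")
        if lm.pixel_size_um != pixel_size:
            raise ValidationError(
                f"pixel-size mismatch: {lm.pixel_size_um} vs {pixel_size} μm/px"
            )

    order = [spec.nominal_diameter_um for _, spec in maps]
    if order != sorted(order):
        logger.info("fuse: input scales were not in ascending order; sorting by nominal diameter")
        maps = sorted(maps, key=lambda pair: pair[1].nominal_diameter_um)

    fused = np.zeros(shape, dtype=np.int32)
    rows = []
    next_gid = 0
    for lm, spec in maps:
        for src_id in lm.ids:
            mask = lm.labels == src_id
            original_area = int(mask.sum())
            occ = occupancy(mask, fused)
            if occ < threshold:
                next_gid += 1
                claim = mask & (fused == 0)
                accepted_area = int(claim.sum())
                # occupancy < threshold ≤ 1 implies at least one free pixel
                assert accepted_area > 0
                fused[claim] = next_gid
                rows.append((next_gid, spec.name, int(src_id), original_area, accepted_area, True))
            else:
                rows.append((pd.NA, spec.name, int(src_id), original_area, 0, False))

    provenance = pd.DataFrame(rows, columns=PROVENANCE_COLUMNS).astype(
        {
            "global_id": "Int64",
            "scale": "string",
            "source_label": np.int64,
            "original_area_px": np.int64,
            "accepted_area_px": np.int64,
            "accepted": bool,
        }
    )
    fused_map = LabelMap(fused, pixel_size, scale_tag="fused")
    return FusedLabelMap(labels=fused_map, provenance=provenance, occupancy_threshold=threshold)
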
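"""Droplet morphometry: areas, equivalent diameters and size summaries.

Fused label areas are measured by pixel counting, converted to μm² via the
pixel size and to the equivalent diameter d = 2·√(A/π) — the diameter of the
circle with the measured area.  Summaries report, per image, the droplet
count and the arithmetic mean diameter over droplets, and the fraction of
droplets falling in each configurable diameter class; group-level values are
unweighted means over images (each section/mouse contributes one point).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import ValidationError
from .fusion import FusedLabelMap

#: Default diameter class edges in μm; bins are (0,2], (2,5], ..., (50,∞).
#: The study does not enumerate its class edges; these are documented free
#: choices spanning multilocular (~2–5 μm) to unilocular (>20 μm) droplets.
DEFAULT_BIN_EDGES_UM = (2.0, 5.0, 10.0, 20.0, 50.0)

DROPLET_COLUMNS = [
    "image_id", "group", "global_id", "source_scale",
    "area_px", "area_um2", "equiv_diameter_um", "centroid_row", "centroid_col",
]


def equivalent_diameter(area_um2: float) -> float:
    """Diameter (μm) of the circle whose area equals ``area_um2``."""
    if not area_um2 > 0:
        raise ValidationError(f"area must be > 0, got {area_um2}")
    return 2.0 * math.sqrt(area_um2 / math.pi)


def measure(fused: FusedLabelMap, image_id: str = "", group: str = "") -> pd.DataFrame:
    """One row per fused droplet: areas, equivalent diameter, centroid.

    ``image_id`` and ``group`` annotate the rows so tables from several
    sections can be concatenated before :func:`summarize`.
    """
    lab = fused.labels.labels
    px = fused.labels.pixel_size_um
    ids = fused.labels.ids
    if ids.size == 0:
        return pd.DataFrame(columns=DROPLET_COLUMNS)
    counts = np.bincount(lab.ravel(), minlength=int(ids.max()) + 1)
    centroids = ndi.center_of_mass(np.ones_like(lab), lab, ids)
    scale_of = fused.provenance.loc[fused.provenance["accepted"]].set_index("global_id")["scale"]
    rows = []
    for gid, (cy, cx) in zip(ids, centroids):
        area_px = int(counts[gid])
        area_um2 = area_px * px ** 2
        rows.append(
            (
                image_id, group, int(gid), scale_of.get(int(gid), fused.labels.scale_tag),
                area_px, area_um2, equivalent_diameter(area_um2), float(cy), float(cx),
            )
        )
    return pd.DataFrame(rows, columns=DROPLET_COLUMNS)


def _bins(bin_edges_um) -> tuple[np.ndarray, list[str]]:
    edges = np.asarray(bin_edges_um, dtype=float)
    if edges.ndim != 1 or edges.size == 0:
        raise ValidationError("bin edges must be a non-empty 1D sequence")
    if np.any(np.diff(edges) <= 0) or edges[0] <= 0:
        raise ValidationError("bin edges must be positive and strictly increasing")
    full = np.concatenate([[0.0], edges, [np.inf]])
    names = []
    for lo, hi in zip(full[:-1], full[1:]):
        names.append(f"({lo:g}, {hi:g}]" if np.isfinite(hi) else f"({lo:g}, inf)")
    return full, names


@dataclass(frozen=True)
class MorphometrySummary:
    """Per-image and per-group size summaries.

    ``per_image``: image_id, group, droplet_count, mean_diameter_um and one
    ``frac (lo, hi]`` column per class (fractions of the image's droplet
    count; they sum to 1; NaN mean and zero fractions for empty images).
    ``per_group``: unweighted means of the image rows plus n_images.
    """

    per_image: pd.DataFrame
    per_group: pd.DataFrame
    bin_edges_um: tuple[float, ...]


def summarize(droplets: pd.DataFrame, bin_edges_um=DEFAULT_BIN_EDGES_UM) -> MorphometrySummary:
    """Summarize a droplet table into per-image and per-group statistics.

    The mean diameter is the arithmetic mean over the droplets of an image
    (not area-weighted); class fractions are per-image counts over the
    image's total.  Group aggregation is image-first: the group value is the
    unweighted mean of its images' values, so each section (mouse) carries
    equal weight regardless of droplet count.
    """
    full_edges, bin_names = _bins(bin_edges_um)
    frac_cols = [f"frac {name}" for name in bin_names]
    image_rows = []
    for (image_id, group), sub in droplets.groupby(["image_id", "group"], sort=True, dropna=False):
        d = sub["equiv_diameter_um"].to_numpy()
        row: dict = {"image_id": image_id, "group": group, "droplet_count": int(d.size)}
        if d.size == 0:
            row["mean_diameter_um"] = np.nan
            for col in frac_cols:
                row[col] = 0.0
        else:
            row["mean_diameter_um"] = float(d.mean())
            counts, _ = np.histogram(d, bins=full_edges)
            for col, c in zip(frac_cols, counts):
                row[col] = c / d.size
        image_rows.append(row)
    per_image = pd.DataFrame(image_rows)

    if per_image.empty:
        per_group = pd.DataFrame(columns=["group", "n_images", "droplet_count", "mean_diameter_um", *frac_cols])
    else:
        agg = per_image.groupby("group", sort=True).agg(
            n_images=("image_id", "size"),
            droplet_count=("droplet_count", "mean"),
            mean_diameter_um=("mean_diameter_um", "mean"),
            **{col: (col, "mean") for col in frac_cols},
        )
        per_group = agg.reset_index()
    return MorphometrySummary(per_image=per_image, per_group=per_group, bin_edges_um=tuple(bin_edges_um))


def plot_diameter_distribution(summary: MorphometrySummary, ax=None):
    """Bar plot of per-group mean class fractions (one bar cluster per class)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    frac_cols = [c for c in summary.per_group.columns if c.startswith("frac ")]
    x = np.arange(len(frac_cols))
    groups = summary.per_group["group"].tolist()
    width = 0.8 / max(1, len(groups))
    for gi, (_, row) in enumerate(summary.per_group.iterrows()):
        ax.bar(x + gi * width, [row[c] for c in frac_cols], width, label=str(row["group"]))
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels([c.removeprefix("frac ") for c in frac_cols], rotation=45, ha="right")
    ax.set_ylabel("fraction of droplets")
    ax.set_xlabel("equivalent diameter class (μm)")
    ax.legend(title="group")
    return ax
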
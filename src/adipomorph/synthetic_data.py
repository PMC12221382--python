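"""Synthetic study data: BAT-like droplet images, per-scale detections,
fatty-acid composition tables, qPCR Ct tables and glucose-tolerance series.

The generators emulate the data of a 2×2 mouse study (genotype Ctrl/KO ×
treatment NaCl/CL316,243) so that every downstream stage — detection, label
fusion, morphometry, lipid indices, ΔCt quantification and group statistics —
can be exercised and validated against known ground truth.  Every generator
is a pure function of its parameter object and seed; seeds are explicit
fields, never global state.

The image model is deliberately minimal: non-overlapping bright discs
(unstained lipid vacuoles in H&E) with a darker 1-px rim on a uniform
background plus Gaussian noise.  Tissue texture, staining variability and
whole-slide geometry are out of scope; see the methods note for what this
does and does not validate.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import PlacementError, ValidationError
from .imaging_io import DEFAULT_PIXEL_SIZE_UM, IntensityImage, LabelMap

GroupKey = tuple[str, str]  # (genotype, treatment)


def group_key(value) -> GroupKey:
    """Normalize ``("KO", "CL")`` / ``"KO:CL"`` to a (genotype, treatment) tuple."""
    if isinstance(value, str):
        parts = value.split(":")
        if len(parts) != 2:
            raise ValidationError(f"group key {value!r} must look like 'genotype:treatment'")
        return (parts[0], parts[1])
    key = tuple(value)
    if len(key) != 2:
        raise ValidationError(f"group key {value!r} must have exactly two levels")
    return key  # type: ignore[return-value]


def group_label(key: GroupKey) -> str:
    return f"{key[0]}:{key[1]}"


# ---------------------------------------------------------------------------
# Droplet images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiameterDist:
    """Log-normal droplet-diameter distribution truncated to [d_lo, d_hi] μm.

    ``median_um`` is the median (geometric mean) of the untruncated
    distribution; ``sigma`` is the log-scale shape parameter.
    """

    median_um: float
    sigma: float
    d_lo: float
    d_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.d_lo < self.d_hi):
            raise ValidationError("need 0 < d_lo < d_hi")
        if self.median_um <= 0 or self.sigma < 0:
            raise ValidationError("median_um must be > 0 and sigma ≥ 0")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Rejection-sample ``size`` diameters inside the truncation window."""
        out = np.empty(size)
        filled = 0
        for _ in range(1000):
            if filled >= size:
                break
            draw = np.exp(rng.normal(math.log(self.median_um), self.sigma, size=size))
            ok = draw[(draw >= self.d_lo) & (draw <= self.d_hi)]
            take = min(ok.size, size - filled)
            out[filled : filled + take] = ok[:take]
            filled += take
        if filled < size:
            raise ValidationError("truncation window rejects virtually all diameter draws")
        return out


@dataclass(frozen=True)
class ImageSpec:
    """Parameters of one synthetic BAT section.

    Defaults describe a mixed multilocular/unilocular field: many small
    droplets around 3 μm and a few large ones around 25 μm, rendered at the
    0.249 μm/px extraction resolution of the histology tiles.  Intensity
    levels are 8-bit; droplets are brighter than background with a darker
    1-px rim (the downstream pipeline inverts the image, making droplets the
    dark phase).
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_small: int = 24
    n_large: int = 6
    small_diam_dist: DiameterDist = field(default_factory=lambda: DiameterDist(3.0, 0.25, 1.5, 6.0))
    large_diam_dist: DiameterDist = field(default_factory=lambda: DiameterDist(25.0, 0.15, 12.0, 40.0))
    min_gap_px: int = 3
    background_level: int = 150
    droplet_level: int = 230
    rim_level: int = 80
    rim_width_px: int = 1
    noise_sd: float = 6.0
    seed: int = 0
    max_retries: int = 10_000

    def __post_init__(self) -> None:
        if self.width_px < 16 or self.height_px < 16:
            raise ValidationError("image must be at least 16×16")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        if self.n_small < 0 or self.n_large < 0:
            raise ValidationError("droplet counts must be ≥ 0")
        if self.min_gap_px < 0:
            raise ValidationError("min_gap_px must be ≥ 0")
        if self.droplet_level == self.background_level:
            raise ValidationError("droplet_level must differ from background_level")
        for lvl in (self.background_level, self.droplet_level, self.rim_level):
            if not (0 <= lvl <= 255):
                raise ValidationError("intensity levels must fit 8 bits")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be ≥ 0")

    @classmethod
    def from_dict(cls, d: dict) -> "ImageSpec":
        d = dict(d)
        for key in ("small_diam_dist", "large_diam_dist"):
            if key in d and isinstance(d[key], dict):
                d[key] = DiameterDist(**d[key])
        return cls(**d)


def _rasterize_disc(cy: float, cx: float, radius_px: float, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers lie within ``radius_px`` of (cy, cx)."""
    h, w = shape
    r_int = int(math.ceil(radius_px)) + 1
    y0, y1 = max(0, int(cy) - r_int), min(h, int(cy) + r_int + 1)
    x0, x1 = max(0, int(cx) - r_int), min(w, int(cx) + r_int + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    sub = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px ** 2
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = sub
    return mask


def generate_bat_image(spec: ImageSpec) -> tuple[IntensityImage, LabelMap, pd.DataFrame]:
    """Render one synthetic section with ground truth.

    Returns the 8-bit intensity image, the truth label map (one id per
    droplet, 1..n, large droplets placed first) and a truth table with one
    row per droplet: label, size_class, sampled diameter (μm), rasterized
    area (px) and equivalent diameter (μm), and centroid.

    Raises :class:`PlacementError` when the requested droplets cannot be
    placed without overlap (rejection sampling, bounded retries).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    small_d = spec.small_diam_dist.sample(rng, spec.n_small) if spec.n_small else np.empty(0)
    large_d = spec.large_diam_dist.sample(rng, spec.n_large) if spec.n_large else np.empty(0)
    # place large droplets first: packing is far more constrained for them
    order = [("large", d) for d in large_d] + [("small", d) for d in small_d]

    margin = spec.rim_width_px
    placed: list[tuple[float, float, float]] = []  # (cy, cx, radius_px)
    records = []
    labels = np.zeros((h, w), dtype=np.int32)
    image = np.full((h, w), float(spec.background_level))

    for size_class, diam_um in order:
        r = diam_um / (2.0 * spec.pixel_size_um)
        lo_y, hi_y = r + margin, h - 1 - r - margin
        lo_x, hi_x = r + margin, w - 1 - r - margin
        if lo_y >= hi_y or lo_x >= hi_x:
            raise PlacementError(
                f"cannot place droplets: a {diam_um:.1f} μm droplet does not fit a "
                f"{w}×{h} px image at {spec.pixel_size_um} μm/px"
            )
        for attempt in range(spec.max_retries):
            cy = rng.uniform(lo_y, hi_y)
            cx = rng.uniform(lo_x, hi_x)
            if all(
                math.hypot(cy - py, cx - px) >= r + pr + spec.min_gap_px
                for py, px, pr in placed
            ):
                break
        else:
            raise PlacementError(
                f"cannot place droplets: no room for droplet {len(placed) + 1} "
                f"after {spec.max_retries} retries"
            )
        placed.append((cy, cx, r))
        label = len(placed)
        disc = _rasterize_disc(cy, cx, r, (h, w))
        rim = _rasterize_disc(cy, cx, r + spec.rim_width_px, (h, w)) & ~disc
        image[rim] = spec.rim_level
        image[disc] = spec.droplet_level
        labels[disc] = label
        area_px = int(disc.sum())
        records.append(
            {
                "label": label,
                "size_class": size_class,
                "diameter_um": float(diam_um),
                "area_px": area_px,
                "equiv_diameter_um": 2.0 * math.sqrt(area_px / math.pi) * spec.pixel_size_um,
                "center_row": cy,
                "center_col": cx,
            }
        )

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    pixels = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    truth_table = pd.DataFrame.from_records(
        records,
        columns=[
            "label", "size_class", "diameter_um", "area_px",
            "equiv_diameter_um", "center_row", "center_col",
        ],
    )
    return (
        IntensityImage(pixels=pixels, pixel_size_um=spec.pixel_size_um),
        LabelMap(labels=labels, pixel_size_um=spec.pixel_size_um, scale_tag="truth"),
        truth_table,
    )


# ---------------------------------------------------------------------------
# Error-modelled per-scale detections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionErrorModel:
    """Detector imperfections applied to truth droplets per inference scale.

    The defaults encode the clean two-scale contract: each scale sees only
    its own size class (the "wrong" class is always missed), and detections
    reproduce the truth footprints exactly.
    """

    miss_rate_small_at_small_scale: float = 0.0
    miss_rate_large_at_small_scale: float = 1.0
    miss_rate_small_at_large_scale: float = 1.0
    miss_rate_large_at_large_scale: float = 0.0
    merge_rate: float = 0.0
    fragment_rate: float = 0.0
    fragment_k: int = 3
    boundary_jitter_px: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "miss_rate_small_at_small_scale", "miss_rate_large_at_small_scale",
            "miss_rate_small_at_large_scale", "miss_rate_large_at_large_scale",
            "merge_rate", "fragment_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be a probability, got {v}")
        if self.fragment_k < 2:
            raise ValidationError("fragment_k must be ≥ 2")
        if self.boundary_jitter_px < 0:
            raise ValidationError("boundary_jitter_px must be ≥ 0")

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionErrorModel":
        return cls(**d)


def _jitter_mask(mask: np.ndarray, amount: int, occupied: np.ndarray) -> np.ndarray:
    """Dilate (amount>0) or erode (amount<0); dilation claims free pixels only."""
    if amount == 0:
        return mask
    struct = ndi.generate_binary_structure(2, 1)
    if amount > 0:
        grown = ndi.binary_dilation(mask, structure=struct, iterations=amount)
        return mask | (grown & ~occupied)
    shrunk = ndi.binary_erosion(mask, structure=struct, iterations=-amount)
    return shrunk if shrunk.any() else mask


def _fragment_mask(mask: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Split a footprint into k fragments strictly inside it (1-px erosion,
    then nearest-seed partition)."""
    inner = ndi.binary_erosion(mask, ndi.generate_binary_structure(2, 1))
    if not inner.any():
        inner = mask
    coords = np.argwhere(inner)
    k = min(k, len(coords))
    seeds = coords[rng.choice(len(coords), size=k, replace=False)]
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    frags = []
    for j in range(k):
        pts = coords[assign == j]
        if len(pts) == 0:
            continue
        fm = np.zeros_like(mask)
        fm[pts[:, 0], pts[:, 1]] = True
        frags.append(fm)
    return frags


def simulate_scale_detections(
    truth: LabelMap,
    truth_table: pd.DataFrame,
    error: DetectionErrorModel,
) -> tuple[LabelMap, LabelMap]:
    """Emit (small-scale, large-scale) label maps from truth + an error model.

    Per scale, each truth droplet is kept or missed according to its size
    class; kept droplets may be pairwise merged (nearest neighbour, one
    label covering both footprints), and at the small scale a large droplet
    may instead appear as ``fragment_k`` fragments strictly inside its
    footprint.  Boundary jitter grows/shrinks each emitted label by up to
    ``boundary_jitter_px``.  Deterministic given ``error.seed``.
    """
    rng = np.random.default_rng(error.seed)
    by_label = truth_table.set_index("label")
    maps = []
    for scale in ("small", "large"):
        miss = {
            "small": getattr(error, f"miss_rate_small_at_{scale}_scale"),
            "large": getattr(error, f"miss_rate_large_at_{scale}_scale"),
        }
        kept: list[np.ndarray] = []
        kept_centers: list[tuple[float, float]] = []
        for label, row in by_label.iterrows():
            mask = truth.labels == label
            if rng.uniform() >= miss[row["size_class"]]:
                kept.append(mask)
                kept_centers.append((row["center_row"], row["center_col"]))
            if scale == "small" and row["size_class"] == "large" and rng.uniform() < error.fragment_rate:
                for frag in _fragment_mask(mask, error.fragment_k, rng):
                    kept.append(frag)
                    com = np.argwhere(frag).mean(axis=0)
                    kept_centers.append((float(com[0]), float(com[1])))

        # nearest-neighbour merging of emitted labels
        merged_into = list(range(len(kept)))
        for i in range(len(kept)):
            if merged_into[i] != i or len(kept) < 2:
                continue
            if rng.uniform() < error.merge_rate:
                dists = [
                    (math.hypot(kept_centers[i][0] - kept_centers[j][0],
                                kept_centers[i][1] - kept_centers[j][1]), j)
                    for j in range(len(kept))
                    if j != i and merged_into[j] == j
                ]
                if dists:
                    _, j = min(dists)
                    merged_into[j] = i

        out = np.zeros(truth.shape, dtype=np.int32)
        next_id = 0
        for i in range(len(kept)):
            if merged_into[i] != i:
                continue
            mask = kept[i].copy()
            for j in range(len(kept)):
                if j != i and merged_into[j] == i:
                    mask |= kept[j]
            if error.boundary_jitter_px:
                amount = int(rng.integers(-error.boundary_jitter_px, error.boundary_jitter_px + 1))
                mask = _jitter_mask(mask, amount, out != 0)
            mask = mask & (out == 0)
            if not mask.any():
                continue
            next_id += 1
            out[mask] = next_id
        maps.append(LabelMap(labels=out, pixel_size_um=truth.pixel_size_um, scale_tag=scale))
    return maps[0], maps[1]


# ---------------------------------------------------------------------------
# Fatty-acid composition tables
# ---------------------------------------------------------------------------

#: Default species panel and mean mol% for adipose triglycerides of
#: lard-HFD-fed mice (free choice; the study reports effects, not baselines).
DEFAULT_MEAN_MOL_PERCENT = {
    "C16:0": 24.0,
    "C16:1n-7": 3.0,
    "C18:0": 6.0,
    "C18:1n-9": 38.0,
    "C18:1n-7": 2.5,
    "C18:2n-6": 20.0,
    "C20:4n-6": 0.5,
    "other": 6.0,
}

DEFAULT_GROUPS: list[tuple[str, str, int]] = [
    ("Ctrl", "NaCl", 4), ("Ctrl", "CL", 4), ("KO", "NaCl", 4), ("KO", "CL", 4),
]

#: Default genotype×treatment effects: the knockout under β3-agonist shows
#: raised de novo lipogenesis and desaturation (palmitate and palmitoleate up,
#: stearate and arachidonate down) and stores more fat per sample.
DEFAULT_EFFECT_MULTIPLIERS = {
    ("KO", "CL"): {"C16:0": 1.3, "C16:1n-7": 2.0, "C18:0": 0.7, "C20:4n-6": 0.7},
}

INTERNAL_STANDARD = "C19:0"


def _norm_group_dict(d: dict | None) -> dict[GroupKey, dict]:
    if not d:
        return {}
    return {group_key(k): v for k, v in d.items()}


@dataclass(frozen=True)
class FAGroupParams:
    """Parameters of the synthetic fatty-acid composition tables.

    ``concentration`` is the Dirichlet concentration of the compositional
    noise on the mol% simplex (higher = tighter around the group mean);
    ``None`` switches noise off, making every sample exactly the renormalized
    group mean.  Quantities are expressed in arbitrary molar-comparable units
    relative to the C19:0 internal standard.
    """

    groups: list[tuple[str, str, int]] = field(default_factory=lambda: list(DEFAULT_GROUPS))
    mean_mol_percent: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MEAN_MOL_PERCENT))
    effect_multipliers: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_MULTIPLIERS))
    concentration: float | None = 2000.0
    c19_quantity: float = 4.0
    total_fa_scale: dict = field(default_factory=lambda: {("KO", "CL"): 1.5})
    fraction_scale: dict = field(default_factory=lambda: {"TG": 40.0, "PL": 20.0})
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.mean_mol_percent.values())
        if abs(total - 100.0) > 1e-6:
            raise ValidationError(f"mean mol% must sum to 100, got {total}")
        if any(v < 0 for v in self.mean_mol_percent.values()):
            raise ValidationError("mean mol% entries must be ≥ 0")
        for g in self.groups:
            if len(g) != 3 or g[2] < 2:
                raise ValidationError("each group needs (genotype, treatment, n) with n ≥ 2")
        if self.concentration is not None and self.concentration <= 0:
            raise ValidationError("concentration must be > 0 or None")
        if self.c19_quantity <= 0:
            raise ValidationError("c19_quantity must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "FAGroupParams":
        d = dict(d)
        if "groups" in d:
            d["groups"] = [tuple(g) for g in d["groups"]]
        for key in ("effect_multipliers", "total_fa_scale"):
            if key in d:
                d[key] = _norm_group_dict(d[key])
        return cls(**d)

    def expected_mol_percent(self, group: GroupKey) -> dict[str, float]:
        """Renormalized group-mean mol% after applying effect multipliers."""
        mults = _norm_group_dict(self.effect_multipliers).get(group_key(group), {})
        raw = {sp: v * mults.get(sp, 1.0) for sp, v in self.mean_mol_percent.items()}
        total = sum(raw.values())
        return {sp: 100.0 * v / total for sp, v in raw.items()}


def generate_fa_tables(params: FAGroupParams) -> pd.DataFrame:
    """Generate a long-format composition table over TG and PL fractions.

    Columns: sample, genotype, treatment, group, fraction, species, quantity.
    Each sample×fraction includes one C19:0 internal-standard row.  Expected
    sample mol% equals ``params.expected_mol_percent(group)``.
    """
    rng = np.random.default_rng(params.seed)
    scales = _norm_group_dict(params.total_fa_scale)
    rows = []
    for genotype, treatment, n in params.groups:
        key = (genotype, treatment)
        mean = params.expected_mol_percent(key)
        species = list(mean)
        p = np.array([mean[sp] for sp in species]) / 100.0
        for i in range(n):
            sample = f"{genotype}-{treatment}-{i + 1}"
            for fraction, frac_scale in params.fraction_scale.items():
                if params.concentration is None:
                    fracs = p
                else:
                    fracs = rng.dirichlet(params.concentration * p)
                total = frac_scale * scales.get(key, 1.0)
                for sp, f in zip(species, fracs):
                    rows.append((sample, genotype, treatment, group_label(key), fraction, sp, total * f))
                rows.append((sample, genotype, treatment, group_label(key), fraction,
                             INTERNAL_STANDARD, params.c19_quantity))
    return pd.DataFrame(
        rows, columns=["sample", "genotype", "treatment", "group", "fraction", "species", "quantity"]
    )


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CtGroupParams:
    """Parameters of synthetic qPCR Ct tables.

    ``group_shifts`` maps a group to per-gene ΔCt shifts added to the base
    Ct (positive shift = less template = lower expression).  Replicate Ct
    values are base + shift + N(0, replicate_sd).
    """

    genes: dict[str, float] = field(default_factory=lambda: {"Scd1": 24.0, "36B4": 18.0})
    housekeeping_gene: str = "36B4"
    group_shifts: dict = field(default_factory=dict)
    replicate_sd: float = 0.15
    n_replicates: int = 3
    groups: list[tuple[str, str, int]] = field(default_factory=lambda: list(DEFAULT_GROUPS))
    seed: int = 0

    def __post_init__(self) -> None:
        for gene, ct in self.genes.items():
            if not (10.0 <= ct <= 38.0):
                raise ValidationError(f"base Ct for {gene} must lie in [10, 38], got {ct}")
        if self.housekeeping_gene not in self.genes:
            raise ValidationError(f"housekeeping gene {self.housekeeping_gene!r} missing from genes")
        if self.replicate_sd < 0:
            raise ValidationError("replicate_sd must be ≥ 0")
        if self.n_replicates < 1:
            raise ValidationError("need ≥ 1 replicate")

    @classmethod
    def from_dict(cls, d: dict) -> "CtGroupParams":
        d = dict(d)
        if "groups" in d:
            d["groups"] = [tuple(g) for g in d["groups"]]
        if "group_shifts" in d:
            d["group_shifts"] = _norm_group_dict(d["group_shifts"])
        return cls(**d)


def generate_ct_table(params: CtGroupParams) -> pd.DataFrame:
    """Generate a long-format Ct table.

    Columns: sample, genotype, treatment, group, gene, replicate, ct.
    """
    rng = np.random.default_rng(params.seed)
    shifts = _norm_group_dict(params.group_shifts)
    rows = []
    for genotype, treatment, n in params.groups:
        key = (genotype, treatment)
        for i in range(n):
            sample = f"{genotype}-{treatment}-{i + 1}"
            for gene, base in params.genes.items():
                shift = shifts.get(key, {}).get(gene, 0.0)
                for rep in range(1, params.n_replicates + 1):
                    ct = base + shift + (rng.normal(0.0, params.replicate_sd) if params.replicate_sd else 0.0)
                    rows.append((sample, genotype, treatment, group_label(key), gene, rep, ct))
    return pd.DataFrame(
        rows, columns=["sample", "genotype", "treatment", "group", "gene", "replicate", "ct"]
    )


# ---------------------------------------------------------------------------
# Glucose tolerance tests
# ---------------------------------------------------------------------------

#: Sampling scheme of the i.p. GTT: minutes after the glucose bolus.
GTT_TIMEPOINTS = (0, 15, 30, 60, 90, 120)

#: Default mean excursion (mg/dL) of an obese mouse at the scheme above.
DEFAULT_GTT_CURVE = (160.0, 330.0, 300.0, 240.0, 200.0, 180.0)


@dataclass(frozen=True)
class GTTGroupSpec:
    """One group's glucose-excursion model: mean curve (mg/dL) + noise sd."""

    name: str
    n: int
    mean_glucose: tuple[float, ...] = DEFAULT_GTT_CURVE
    sd: float = 15.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("group n must be ≥ 1")
        if any(g <= 0 for g in self.mean_glucose):
            raise ValidationError("mean glucose must be positive")
        if self.sd < 0:
            raise ValidationError("sd must be ≥ 0")

    @classmethod
    def from_dict(cls, d: dict) -> "GTTGroupSpec":
        d = dict(d)
        if "mean_glucose" in d:
            d["mean_glucose"] = tuple(d["mean_glucose"])
        return cls(**d)


def generate_gtt(
    groups: list[GTTGroupSpec],
    timepoints: tuple[int, ...] = GTT_TIMEPOINTS,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a long-format GTT table (sample, group, time_min, glucose_mg_dl).

    Glucose values are clipped below at 30 mg/dL to stay physiological and
    positive.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for spec in groups:
        if len(spec.mean_glucose) != len(timepoints):
            raise ValidationError(
                f"group {spec.name!r}: mean curve has {len(spec.mean_glucose)} values "
                f"for {len(timepoints)} timepoints"
            )
        for i in range(1, spec.n + 1):
            sample = f"{spec.name}-{i}"
            noise = rng.normal(0.0, spec.sd, size=len(timepoints)) if spec.sd else np.zeros(len(timepoints))
            for t, mu, e in zip(timepoints, spec.mean_glucose, noise):
                rows.append((sample, spec.name, t, max(30.0, mu + e)))
    return pd.DataFrame(rows, columns=["sample", "group", "time_min", "glucose_mg_dl"])
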
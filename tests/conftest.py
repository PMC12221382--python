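import numpy as np
import pandas as pd
import pytest

import adipomorph as am


@pytest.fixture(scope="session")
def single_disc():
    """One noiseless 20 μm disc at the native pixel size."""
    spec = am.ImageSpec(
        n_small=0,
        n_large=1,
        large_diam_dist=am.DiameterDist(20.0, 0.0, 19.9, 20.1),
        noise_sd=0.0,
        seed=7,
    )
    image, truth, table = am.generate_bat_image(spec)
    return spec, image, truth, table


@pytest.fixture(scope="session")
def clean_field():
    """5 small + 2 large droplets with clean two-scale detections."""
    spec = am.ImageSpec(n_small=5, n_large=2, seed=3)
    image, truth, table = am.generate_bat_image(spec)
    small, large = am.simulate_scale_detections(truth, table, am.DetectionErrorModel(seed=0))
    return image, truth, table, small, large


@pytest.fixture()
def toy_fa_sample():
    """The five-species worked example (quantities in common molar units)."""
    rows = [
        ("s1", "TG", "C16:0", 20.0),
        ("s1", "TG", "C16:1n-7", 5.0),
        ("s1", "TG", "C18:0", 10.0),
        ("s1", "TG", "C18:2n-6", 25.0),
        ("s1", "TG", "C19:0", 4.0),
    ]
    return pd.DataFrame(rows, columns=["sample", "fraction", "species", "quantity"])


def random_label_map(rng: np.random.Generator, shape=(32, 32), max_labels=6) -> np.ndarray:
    """Random disjoint rectangles; later ids may overwrite earlier ones, so
    some ids can be partially occluded or absent — still a valid label map."""
    labels = np.zeros(shape, dtype=np.int32)
    for i in range(1, int(rng.integers(0, max_labels + 1)) + 1):
        h = int(rng.integers(2, 12))
        w = int(rng.integers(2, 12))
        r = int(rng.integers(0, shape[0] - h))
        c = int(rng.integers(0, shape[1] - w))
        labels[r : r + h, c : c + w] = i
    return labels


def fuse_bruteforce(maps, threshold=0.10):
    """Literal reference for the fusion rule, on python pixel sets.

    Scales ascending by nominal diameter, labels ascending by id; accept a
    label iff strictly less than ``threshold`` of its pixels are already
    claimed; accepted labels claim only free pixels.
    """
    ordered = sorted(maps, key=lambda pair: pair[1].nominal_diameter_um)
    shape = ordered[0][0].labels.shape
    claimed: dict[tuple[int, int], int] = {}
    gid = 0
    for lm, _spec in ordered:
        for src in sorted(int(i) for i in np.unique(lm.labels) if i > 0):
            pixels = {tuple(p) for p in np.argwhere(lm.labels == src)}
            occupied = sum(1 for p in pixels if p in claimed)
            if occupied / len(pixels) < threshold:
                gid += 1
                for p in pixels:
                    if p not in claimed:
                        claimed[p] = gid
    out = np.zeros(shape, dtype=np.int32)
    for (r, c), g in claimed.items():
        out[r, c] = g
    return out


@pytest.fixture(scope="session")
def design_factory():
    """Build 2×2 genotype×treatment response tables with an optional
    interaction shift (in units of the within-cell SD) on the KO:CL cell."""

    def make(seed: int, delta_sd: float = 0.0, n: int = 6, mu: float = 0.125, sigma: float = 0.01):
        rng = np.random.default_rng(seed)
        rows = []
        for g in ("Ctrl", "KO"):
            for t in ("NaCl", "CL"):
                shift = delta_sd * sigma if (g, t) == ("KO", "CL") else 0.0
                for i in range(n):
                    rows.append((f"{g}-{t}-{i}", g, t, rng.normal(mu + shift, sigma)))
        return pd.DataFrame(rows, columns=["sample", "genotype", "treatment", "response"])

    return make
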
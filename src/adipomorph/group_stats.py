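"""Group-comparison statistics for the 2×2 genotype × treatment design.

The routing mirrors common practice for small-n mouse studies: per-group
Shapiro–Wilk normality at α; if every group is compatible with normality and
the full 2×2 design is present, a two-way ANOVA (type-II sums of squares by
default) with Šídák-corrected planned pairwise comparisons; if exactly two
groups are present and normal, an unpaired two-tailed t-test; if any group
fails normality (or is too small to test), Mann–Whitney tests per planned
pair.  The planned family is the set of simple-effect contrasts actually
reported in such studies: genotype within each treatment and treatment
within each genotype (m = 4).

Numeric kernels are delegated to scipy/statsmodels; this module owns the
routing, the contrast family and the report assembly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ValidationError

DEFAULT_ALPHA = 0.05

PAIRWISE_COLUMNS = ["comparison", "group_a", "group_b", "test", "statistic", "p_raw", "p_adjusted", "significant"]


def sidak_adjust(p: float, m: int) -> float:
    """Šídák multiple-comparison adjustment: 1 − (1 − p)^m, clipped to [0, 1]."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p must lie in [0, 1], got {p}")
    if m < 1:
        raise ValidationError(f"m must be ≥ 1, got {m}")
    # max(p, ·) guards the adjusted ≥ raw invariant against float rounding
    return float(min(1.0, max(p, 1.0 - (1.0 - p) ** m)))


@dataclass(frozen=True)
class Design:
    """Per-sample responses across the genotype × treatment factors."""

    data: pd.DataFrame
    response: str = "response"
    genotype: str = "genotype"
    treatment: str = "treatment"
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        for col in (self.response, self.genotype, self.treatment):
            if col not in self.data.columns:
                raise ValidationError(f"design table lacks column {col!r}")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.data[self.response].isna().any():
            raise ValidationError("response contains missing values")

    def cells(self) -> dict[tuple[str, str], np.ndarray]:
        out = {}
        for (g, t), sub in self.data.groupby([self.genotype, self.treatment], sort=True):
            out[(str(g), str(t))] = sub[self.response].to_numpy(dtype=float)
        return out


@dataclass(frozen=True)
class StatsReport:
    """Assembled result of :func:`route_and_test`.

    ``routing`` names the chosen branch; ``normality`` has one Shapiro–Wilk
    row per group; ``anova`` is the two-way table (None outside the ANOVA
    branch); ``pairwise`` lists the planned comparisons with raw and
    Šídák-adjusted p-values and significance flags at ``alpha``.
    """

    routing: str
    normality: pd.DataFrame
    anova: pd.DataFrame | None
    pairwise: pd.DataFrame
    alpha: float
    warnings_: list[str] = field(default_factory=list)

    @property
    def significant_comparisons(self) -> list[str]:
        return self.pairwise.loc[self.pairwise["significant"], "comparison"].tolist()

    def effect_p(self, effect: str) -> float | None:
        """p-value of an ANOVA effect row (e.g. 'genotype:treatment'), if present."""
        if self.anova is None or effect not in self.anova.index:
            return None
        return float(self.anova.loc[effect, "PR(>F)"])

    def summary(self) -> str:
        lines = [f"Routing: {self.routing} (alpha = {self.alpha})", "", "Normality (Shapiro-Wilk):"]
        lines.append(self.normality.to_string(index=False))
        if self.anova is not None:
            lines += ["", "Two-way ANOVA:", self.anova.to_string()]
        lines += ["", "Planned comparisons:", self.pairwise.to_string(index=False)]
        if self.warnings_:
            lines += ["", "Warnings:"] + [f"  - {w}" for w in self.warnings_]
        return "\n".join(lines)


def _planned_pairs(cells: dict[tuple[str, str], np.ndarray]) -> list[tuple[tuple[str, str], tuple[str, str], str]]:
    """Simple-effect family: genotype within treatment, treatment within genotype."""
    genotypes = sorted({g for g, _ in cells})
    treatments = sorted({t for _, t in cells})
    pairs = []
    for t in treatments:
        for ga, gb in itertools.combinations(genotypes, 2):
            if (ga, t) in cells and (gb, t) in cells:
                pairs.append(((ga, t), (gb, t), f"{ga} vs {gb} | {t}"))
    for g in genotypes:
        for ta, tb in itertools.combinations(treatments, 2):
            if (g, ta) in cells and (g, tb) in cells:
                pairs.append(((g, ta), (g, tb), f"{ta} vs {tb} | {g}"))
    return pairs


def _normality_table(cells, alpha) -> tuple[pd.DataFrame, bool, bool]:
    rows, testable, all_normal = [], True, True
    for key, values in cells.items():
        if len(values) < 3:
            rows.append({"group": ":".join(key), "n": len(values), "shapiro_p": np.nan, "normal": None})
            testable = False
            continue
        if np.ptp(values) == 0:
            # constant sample: Shapiro is undefined; treat as non-normal
            rows.append({"group": ":".join(key), "n": len(values), "shapiro_p": 0.0, "normal": False})
            all_normal = False
            continue
        p = float(sps.shapiro(values).pvalue)
        normal = p >= alpha
        all_normal &= normal
        rows.append({"group": ":".join(key), "n": len(values), "shapiro_p": p, "normal": normal})
    return pd.DataFrame(rows), testable, all_normal


def _mannwhitney_pairwise(cells, pairs, alpha) -> pd.DataFrame:
    m = len(pairs)
    rows = []
    for a, b, name in pairs:
        res = sps.mannwhitneyu(cells[a], cells[b], alternative="two-sided")
        p_adj = sidak_adjust(float(res.pvalue), m)
        rows.append((name, ":".join(a), ":".join(b), "Mann-Whitney", float(res.statistic),
                     float(res.pvalue), p_adj, p_adj < alpha))
    return pd.DataFrame(rows, columns=PAIRWISE_COLUMNS)


def _pooled_t_pairwise(cells, pairs, mse, df_resid, alpha, adjust: bool) -> pd.DataFrame:
    m = len(pairs) if adjust else 1
    rows = []
    for a, b, name in pairs:
        xa, xb = cells[a], cells[b]
        se = np.sqrt(mse * (1.0 / len(xa) + 1.0 / len(xb)))
        tval = (xa.mean() - xb.mean()) / se
        p = 2.0 * float(sps.t.sf(abs(tval), df_resid))
        p_adj = sidak_adjust(p, m)
        test = "t (pooled MSE), Sidak" if adjust else "t (pooled MSE), LSD"
        rows.append((name, ":".join(a), ":".join(b), test, float(tval), p, p_adj, p_adj < alpha))
    return pd.DataFrame(rows, columns=PAIRWISE_COLUMNS)


def route_and_test(
    design: Design,
    post_hoc: str = "sidak",
    anova_type: int = 2,
) -> StatsReport:
    """Apply the study's statistical routing to one response.

    ``post_hoc`` is "sidak" (default) or "lsd" (Fisher's LSD: unadjusted
    pooled-variance pairwise tests).  ``anova_type`` selects the ANOVA
    sums-of-squares type (2 by default, suited to near-balanced designs).
    """
    if post_hoc not in ("sidak", "lsd"):
        raise ValidationError(f"post_hoc must be 'sidak' or 'lsd', got {post_hoc!r}")
    cells = design.cells()
    if len(cells) < 2:
        raise ValidationError("need at least two groups to compare")
    alpha = design.alpha
    pairs = _planned_pairs(cells)
    notes: list[str] = []

    normality, testable, all_normal = _normality_table(cells, alpha)
    if not testable:
        notes.append("a group has n < 3: normality untestable, routed to Mann-Whitney")
        warnings.warn(notes[-1], stacklevel=2)
        return StatsReport("mann-whitney (normality untestable)", normality, None,
                           _mannwhitney_pairwise(cells, pairs, alpha), alpha, notes)
    if not all_normal:
        return StatsReport("mann-whitney (non-normal group)", normality, None,
                           _mannwhitney_pairwise(cells, pairs, alpha), alpha, notes)

    genotypes = {g for g, _ in cells}
    treatments = {t for _, t in cells}
    full_2x2 = len(genotypes) >= 2 and len(treatments) >= 2 and len(cells) == len(genotypes) * len(treatments)

    if full_2x2:
        df = design.data.rename(
            columns={design.response: "response", design.genotype: "genotype", design.treatment: "treatment"}
        )
        model = smf.ols("response ~ C(genotype) * C(treatment)", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=anova_type)
        anova = anova.rename(index=lambda s: (
            s.replace("C(genotype)", "genotype").replace("C(treatment)", "treatment")
        ))
        mse = float(model.mse_resid)
        pairwise = _pooled_t_pairwise(cells, pairs, mse, model.df_resid, alpha, adjust=post_hoc == "sidak")
        label = "two-way ANOVA + " + ("Sidak" if post_hoc == "sidak" else "Fisher LSD")
        return StatsReport(label, normality, anova, pairwise, alpha, notes)

    if len(cells) == 2:
        (a, xa), (b, xb) = sorted(cells.items())
        res = sps.ttest_ind(xa, xb)
        p = float(res.pvalue)
        row = pd.DataFrame(
            [(f"{':'.join(a)} vs {':'.join(b)}", ":".join(a), ":".join(b), "t (unpaired)",
              float(res.statistic), p, p, p < alpha)],
            columns=PAIRWISE_COLUMNS,
        )
        return StatsReport("unpaired t-test", normality, None, row, alpha, notes)

    notes.append("incomplete factorial design: fell back to Mann-Whitney planned pairs")
    warnings.warn(notes[-1], stacklevel=2)
    return StatsReport("mann-whitney (incomplete design)", normality, None,
                       _mannwhitney_pairwise(cells, pairs, alpha), alpha, notes)
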
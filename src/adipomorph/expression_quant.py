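"""Comparative-ΔCt expression, mitochondrial-DNA content and GTT AUC.

Relative mRNA expression follows the comparative-ΔCt convention: replicate
Ct values are averaged on the Ct scale, ΔCt = Ct_target − Ct_housekeeping
(36B4 for mRNA) and RQ = 2^−ΔCt; an optional calibrator group rescales RQ to
fold change over that group's mean.  Relative mitochondrial DNA content uses
the Cox1 (mitochondrial) / Ppia (nuclear) primer pair with the sign chosen
so that more mitochondrial template gives a larger value:
2^(Ct_nuclear − Ct_mitochondrial).  Glucose-tolerance AUC is the trapezoidal
area over the full sampling range (total AUC, no baseline subtraction;
incremental AUC above the t=0 value is available via a flag).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError

HOUSEKEEPING_MRNA = "36B4"
MITO_GENE = "Cox1"
NUCLEAR_GENE = "Ppia"

CT_COLUMNS = ("sample", "gene", "ct")


def _mean_ct(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValidationError(f"Ct table lacks columns {missing}")
    if ((ct["ct"] <= 0) | (ct["ct"] >= 45)).any():
        raise ValidationError("Ct values must lie in (0, 45)")
    carry = [c for c in ("group", "genotype", "treatment") if c in ct.columns]
    agg = {"ct": ("ct", "mean")}
    agg.update({c: (c, "first") for c in carry})
    return ct.groupby(["sample", "gene"], as_index=False).agg(**agg)


def relative_expression(
    ct: pd.DataFrame,
    target: str,
    housekeeping: str = HOUSEKEEPING_MRNA,
    calibrator_group: str | None = None,
) -> pd.DataFrame:
    """Per-sample relative quantity of ``target`` by the comparative-ΔCt method.

    Returns sample, (group columns if present), delta_ct and rq = 2^−ΔCt.
    With ``calibrator_group``, rq is divided by that group's mean rq (the
    calibrator's mean fold change is then exactly 1).  Samples missing either
    gene are skipped with a warning.
    """
    mean = _mean_ct(ct)
    wide = mean.pivot(index="sample", columns="gene", values="ct")
    for gene in (target, housekeeping):
        if gene not in wide.columns:
            raise ValidationError(f"gene {gene!r} absent from Ct table")
    skipped = wide.index[wide[[target, housekeeping]].isna().any(axis=1)]
    if len(skipped):
        warnings.warn(f"samples missing {target} or {housekeeping} Ct, skipped: {list(skipped)}", stacklevel=2)
    wide = wide.drop(index=skipped)
    out = pd.DataFrame(index=wide.index)
    out["delta_ct"] = wide[target] - wide[housekeeping]
    out["rq"] = np.exp2(-out["delta_ct"])
    carry = [c for c in ("group", "genotype", "treatment") if c in mean.columns]
    if carry:
        meta = mean.drop_duplicates("sample").set_index("sample")[carry]
        out = out.join(meta)
    out = out.reset_index()
    if calibrator_group is not None:
        if "group" not in out.columns:
            raise ValidationError("calibrator normalization needs a 'group' column")
        cal = out.loc[out["group"] == calibrator_group, "rq"]
        if cal.empty:
            raise ValidationError(f"calibrator group {calibrator_group!r} has no samples")
        out["fold_change"] = out["rq"] / cal.mean()
    return out


def mtdna_content(
    ct: pd.DataFrame,
    mito_gene: str = MITO_GENE,
    nuclear_gene: str = NUCLEAR_GENE,
) -> pd.DataFrame:
    """Per-sample relative mitochondrial DNA content, 2^(Ct_nuclear − Ct_mito).

    Larger values mean more mitochondrial DNA per nuclear genome; a +1 Ct
    shift on the mitochondrial gene (half the template) halves the value.
    """
    mean = _mean_ct(ct)
    wide = mean.pivot(index="sample", columns="gene", values="ct")
    for gene in (mito_gene, nuclear_gene):
        if gene not in wide.columns:
            raise ValidationError(f"gene {gene!r} absent from Ct table")
    skipped = wide.index[wide[[mito_gene, nuclear_gene]].isna().any(axis=1)]
    if len(skipped):
        warnings.warn(f"samples missing {mito_gene} or {nuclear_gene} Ct, skipped: {list(skipped)}", stacklevel=2)
    wide = wide.drop(index=skipped)
    out = pd.DataFrame(index=wide.index)
    out["mtdna_relative"] = np.exp2(wide[nuclear_gene] - wide[mito_gene])
    carry = [c for c in ("group", "genotype", "treatment") if c in mean.columns]
    if carry:
        out = out.join(mean.drop_duplicates("sample").set_index("sample")[carry])
    return out.reset_index()


def gtt_auc(
    time_min: np.ndarray | list[float],
    glucose_mg_dl: np.ndarray | list[float],
    incremental: bool = False,
) -> float:
    """Trapezoidal AUC (mg·min/dL) of one glucose-tolerance series.

    ``incremental=True`` subtracts the t=0 baseline before integrating
    (negative increments allowed, as is conventional for iAUC).
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(glucose_mg_dl, dtype=float)
    if t.size != y.size or t.size < 2:
        raise ValidationError("need ≥ 2 matching timepoints")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("timepoints must be strictly increasing")
    if incremental:
        y = y - y[0]
    return float(np.trapezoid(y, t))


def gtt_auc_table(gtt: pd.DataFrame, incremental: bool = False) -> pd.DataFrame:
    """AUC per sample from a long GTT table (sample, group, time_min, glucose_mg_dl)."""
    for col in ("sample", "time_min", "glucose_mg_dl"):
        if col not in gtt.columns:
            raise ValidationError(f"GTT table lacks column {col!r}")
    rows = []
    for sample, sub in gtt.groupby("sample", sort=True):
        sub = sub.sort_values("time_min")
        row = {"sample": sample, "auc": gtt_auc(sub["time_min"], sub["glucose_mg_dl"], incremental)}
        if "group" in sub.columns:
            row["group"] = sub["group"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)
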
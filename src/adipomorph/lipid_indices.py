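"""Fatty-acid composition indices for TG and PL fractions.

From a long-format species-quantity table (quantified against a C19:0
internal standard, glyceryl trinonadecanoate) this module computes molar
percentages and the study's activity indices:

- lipogenic index      = C16:0 / C18:2n-6   (de novo vs dietary fat)
- palmitoleate/linoleate = C16:1n-7 / C18:2n-6
- SCD1 ratio           = C16:1n-7 / C16:0   (Δ9-desaturation)
- ELOVL6 ratio         = C18:0 / C16:0      (palmitate elongation)
- total FA vs C19      = Σ(non-standard quantities) / C19:0 quantity
- TG/PL ratio          = total FA in TG / total FA in PL (per sample)

Ratios are computed on quantities; mol% gives identical values because the
per-sample normalization cancels.  The ELOVL6 ratio is taken as the enzyme's
canonical product/substrate pair C18:0/C16:0; the vaccenate-based alternative
C18:1n-7/C16:1n-7 is available via ``elovl6_definition``.  Missing species or
zero denominators yield NaN with a warning, never fabricated values.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError

INTERNAL_STANDARD = "C19:0"

#: Normalization of common code variants ("18:2 n-6", "C18:2 n6", …) to the
#: canonical "C<carbons>:<double bonds>n-<position>" form.
_CODE_RE = re.compile(
    r"^\s*C?\s*(?P<c>\d{1,2})\s*:\s*(?P<db>\d{1,2})\s*(?:n\s*-?\s*(?P<n>\d{1,2}))?\s*$",
    re.IGNORECASE,
)


#: Aggregate/bookkeeping codes that are legitimate non-FA species labels.
_AGGREGATE_CODES = {"other", "others", "unknown"}


def normalize_species(code: str) -> str:
    """Canonicalize a fatty-acid species code; unknown codes pass through
    unchanged with a warning."""
    if str(code).strip().lower() in _AGGREGATE_CODES:
        return str(code)
    m = _CODE_RE.match(str(code))
    if not m:
        warnings.warn(f"unrecognized species code {code!r}; passing through", stacklevel=2)
        return str(code)
    c, db, n = m.group("c"), m.group("db"), m.group("n")
    return f"C{int(c)}:{int(db)}" + (f"n-{int(n)}" if n else "")


REQUIRED_COLUMNS = ("sample", "fraction", "species", "quantity")


def _validated(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"composition table lacks columns {missing}")
    t = table.copy()
    t["species"] = t["species"].map(normalize_species)
    if (t["quantity"] < 0).any():
        raise ValidationError("quantities must be ≥ 0")
    dup = t.duplicated(["sample", "fraction", "species"])
    if dup.any():
        raise ValidationError("one row per sample×fraction×species required; found duplicates")
    return t


def mol_percent(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample×fraction mol% of each species, standard excluded.

    mol%(s) = 100 · q(s) / Σ_{s' ≠ C19:0} q(s').  The C19:0 internal-standard
    rows are dropped from both numerator and denominator.  A sample×fraction
    whose non-standard quantities are all zero raises.
    """
    t = _validated(table)
    t = t[t["species"] != INTERNAL_STANDARD].copy()
    totals = t.groupby(["sample", "fraction"])["quantity"].transform("sum")
    if (totals <= 0).any():
        bad = t.loc[totals <= 0, ["sample", "fraction"]].drop_duplicates()
        raise ValidationError(f"all-zero composition for {bad.to_dict('records')}")
    t["mol_percent"] = 100.0 * t["quantity"] / totals
    return t.drop(columns="quantity")


def _ratio(num: float | None, den: float | None, what: str, where: str) -> float:
    if num is None or den is None:
        warnings.warn(f"{where}: species missing for {what}; index set to NaN", stacklevel=3)
        return np.nan
    if den == 0:
        warnings.warn(f"{where}: zero denominator for {what}; index set to NaN", stacklevel=3)
        return np.nan
    return num / den


def compute_indices(table: pd.DataFrame, elovl6_definition: str = "C18:0/C16:0") -> pd.DataFrame:
    """Per-sample×fraction index table.

    Columns: sample, (group/genotype/treatment if present), fraction,
    lipogenic_index, palmitoleate_linoleate, scd1_ratio, elovl6_ratio,
    total_fa_vs_c19.  ``elovl6_definition`` is "C18:0/C16:0" (default) or
    "C18:1n-7/C16:1n-7".
    """
    if elovl6_definition not in ("C18:0/C16:0", "C18:1n-7/C16:1n-7"):
        raise ValidationError(f"unknown elovl6_definition {elovl6_definition!r}")
    e_num, e_den = elovl6_definition.split("/")
    t = _validated(table)
    carry = [c for c in ("group", "genotype", "treatment") if c in t.columns]
    rows = []
    for (sample, fraction), sub in t.groupby(["sample", "fraction"], sort=True):
        q = sub.set_index("species")["quantity"]

        def get(sp: str) -> float | None:
            return float(q[sp]) if sp in q.index else None

        where = f"{sample}/{fraction}"
        non_std = q.drop(INTERNAL_STANDARD, errors="ignore")
        row = {"sample": sample, "fraction": fraction}
        for c in carry:
            row[c] = sub[c].iloc[0]
        row["lipogenic_index"] = _ratio(get("C16:0"), get("C18:2n-6"), "lipogenic index", where)
        row["palmitoleate_linoleate"] = _ratio(
            get("C16:1n-7"), get("C18:2n-6"), "palmitoleate/linoleate", where
        )
        row["scd1_ratio"] = _ratio(get("C16:1n-7"), get("C16:0"), "SCD1 ratio", where)
        row["elovl6_ratio"] = _ratio(get(e_num), get(e_den), "ELOVL6 ratio", where)
        row["total_fa_vs_c19"] = _ratio(
            float(non_std.sum()), get(INTERNAL_STANDARD), "total FA vs C19", where
        )
        rows.append(row)
    return pd.DataFrame(rows)


def tg_pl_ratio(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample total-FA ratio of the TG fraction to the PL fraction.

    Totals exclude the C19:0 standard.  Samples lacking either fraction get
    NaN with a warning.
    """
    t = _validated(table)
    t = t[t["species"] != INTERNAL_STANDARD]
    carry = [c for c in ("group", "genotype", "treatment") if c in t.columns]
    totals = t.groupby(["sample", "fraction"])["quantity"].sum().unstack("fraction")
    rows = []
    for sample, row in totals.iterrows():
        tg, pl = row.get("TG", np.nan), row.get("PL", np.nan)
        if pd.isna(tg) or pd.isna(pl):
            warnings.warn(f"{sample}: missing TG or PL fraction; TG/PL ratio set to NaN", stacklevel=2)
            value = np.nan
        elif pl == 0:
            warnings.warn(f"{sample}: zero PL total; TG/PL ratio set to NaN", stacklevel=2)
            value = np.nan
        else:
            value = tg / pl
        out = {"sample": sample, "tg_pl_ratio": value}
        sub = t[t["sample"] == sample]
        for c in carry:
            out[c] = sub[c].iloc[0]
        rows.append(out)
    return pd.DataFrame(rows)
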
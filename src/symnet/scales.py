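"""Eligibility filtering, CESD-10 / GAD-7 scoring and descriptives.

The CESD-10 (10 items, 0-3 each, total 0-30) screens for depression with a
cutoff of 10; the GAD-7 (7 items, 0-3 each, total 0-21) screens for anxiety
with severity bands at 5 (mild), 10 (moderate) and 15 (severe).  Anxiety
"presence" for prevalence and comorbidity is GAD-7 >= 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import CESD_ITEMS, GAD_ITEMS, NODE_NAMES

CESD_CUTOFF = 10
GAD_BANDS = (5, 10, 15)  # mild / moderate / severe lower bounds

VALID_RESPONSES = frozenset({0, 1, 2, 3})


@dataclass
class FilterResult:
    """Complete-case eligible table plus per-criterion exclusion counts.

    Criteria are applied sequentially (age, then diagnosis, then item
    completeness), so the counts sum to ``n_input - len(table)``.
    """

    table: pd.DataFrame
    n_input: int
    excluded_age: int
    excluded_dm: int
    excluded_missing: int

    @property
    def n_retained(self) -> int:
        return len(self.table)


def _as_valid_item(values: pd.Series) -> pd.Series:
    """Numeric item column with NaN wherever the response is not in 0-3."""
    num = pd.to_numeric(values, errors="coerce")
    num[~num.isin(list(VALID_RESPONSES))] = np.nan
    return num


def filter_eligible(raw: pd.DataFrame, min_age: float = 65,
                    require_dm: bool = True,
                    item_names=NODE_NAMES) -> FilterResult:
    """Apply the study eligibility filter to a raw survey table.

    Keeps rows with age >= ``min_age``, the diabetes-diagnosis flag set, and
    all items answered with a valid 0-3 response (survey codes such as
    "don't know" count as missing).  Row order is preserved and item
    columns are returned as plain integers.
    """
    required = ["age"] + (["dm_diagnosed"] if require_dm else []) + list(item_names)
    absent = [c for c in required if c not in raw.columns]
    if absent:
        raise KeyError(f"required columns absent: {absent}")

    age_ok = pd.to_numeric(raw["age"], errors="coerce") >= min_age
    if require_dm:
        dm_ok = pd.to_numeric(raw["dm_diagnosed"], errors="coerce").fillna(0) != 0
    else:
        dm_ok = pd.Series(True, index=raw.index)
    items = pd.DataFrame({c: _as_valid_item(raw[c]) for c in item_names})
    complete = items.notna().all(axis=1)

    keep = age_ok & dm_ok & complete
    excluded_age = int((~age_ok).sum())
    excluded_dm = int((age_ok & ~dm_ok).sum())
    excluded_missing = int((age_ok & dm_ok & ~complete).sum())

    out = items.loc[keep].astype(int)
    if "participant_id" in raw.columns:
        out.insert(0, "participant_id", raw.loc[keep, "participant_id"].values)
    out = out.reset_index(drop=True)
    return FilterResult(out, len(raw), excluded_age, excluded_dm,
                        excluded_missing)


def item_matrix(table: pd.DataFrame, item_names=NODE_NAMES) -> pd.DataFrame:
    """The 17 item columns of a complete-case table, validated."""
    absent = [c for c in item_names if c not in table.columns]
    if absent:
        raise KeyError(f"item columns absent: {absent}")
    items = table[list(item_names)]
    vals = items.to_numpy()
    if not np.isin(vals, list(VALID_RESPONSES)).all():
        raise ValueError("item responses must all be integers in {0,1,2,3}")
    return items.astype(int)


def score(table: pd.DataFrame) -> pd.DataFrame:
    """Score each participant: totals, depression flag, anxiety band."""
    items = item_matrix(table)
    cesd = items[list(CESD_ITEMS)].sum(axis=1)
    gad = items[list(GAD_ITEMS)].sum(axis=1)
    mild, moderate, severe = GAD_BANDS
    band = pd.cut(gad, bins=[-1, mild - 1, moderate - 1, severe - 1, 21],
                  labels=["none", "mild", "moderate", "severe"])
    out = pd.DataFrame({
        "cesd_total": cesd.astype(int),
        "gad_total": gad.astype(int),
        "depressed": (cesd >= CESD_CUTOFF).astype(bool),
        "anxiety_band": band.astype(str),
    })
    if "participant_id" in table.columns:
        out.insert(0, "participant_id", table["participant_id"].values)
    return out


def prevalence(records: pd.DataFrame) -> dict[str, float]:
    """Fractions screening positive for depression, anxiety, and both.

    Depression is CESD-10 total >= 10; anxiety is GAD-7 total >= 5 (the
    mild band or worse); comorbidity is the joint fraction.
    """
    if len(records) == 0:
        raise ValueError("prevalence undefined for an empty record list")
    dep = records["cesd_total"] >= CESD_CUTOFF
    anx = records["gad_total"] >= GAD_BANDS[0]
    return {
        "depression": float(dep.mean()),
        "anxiety": float(anx.mean()),
        "comorbid": float((dep & anx).mean()),
    }


def cronbach_alpha(items: pd.DataFrame) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the total),
    with the n-1 variance divisor throughout.
    """
    X = np.asarray(items, dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("cronbach_alpha needs at least 2 items")
    if n < 2:
        raise ValueError("cronbach_alpha needs at least 2 rows")
    item_var = X.var(axis=0, ddof=1).sum()
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1 - item_var / total_var))


def describe_items(table: pd.DataFrame, item_names=NODE_NAMES) -> pd.DataFrame:
    """Per-item mean and sample SD (n-1 divisor), one row per item."""
    items = item_matrix(table, item_names)
    return pd.DataFrame({
        "item": list(item_names),
        "mean": items.mean(axis=0).to_numpy(),
        "sd": items.std(axis=0, ddof=1).to_numpy(),
    })
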
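"""Scoring of the three item batteries and derived analysis variables.

The resource-constraint battery (AFSSM) is the first 10 adult items of
the USDA Household Food Security Survey Module, each dichotomized
affirmative/negative.  The physical food security battery (PFS) asks
about difficulty with six food-related tasks (standing, lifting,
shopping, reaching overhead, preparing meals, using utensils); any
response other than "no difficulty" counts as affirmative.  The PHQ-9
depression screener has nine items scored 0-3 with a total of >= 10
flagging depression.

Raw-score category cut points:

==========  ======  ==========  =====  =========
scale       High    Marginal    Low    Very low
==========  ======  ==========  =====  =========
AFSSM (10)  0       1-2         3-5    6-10
PFS (6)     0       1-2         3-4    5-6
==========  ======  ==========  =====  =========

All functions accept scalars or numpy/pandas vectors; missing inputs
(NaN) propagate to missing outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .categories import Category

AFSSM_ITEMS = [f"afssm{i}" for i in range(1, 11)]
PFS_ITEMS = [f"pfs{i}" for i in range(1, 7)]
PHQ9_ITEMS = [f"phq{i}" for i in range(1, 10)]

#: PFS 4-level response codes: 0 = no difficulty, 1 = some difficulty,
#: 2 = much difficulty, 3 = unable to do the activity.
PFS_AFFIRMATIVE_LEVELS = (1, 2, 3)

PHQ9_DEPRESSION_CUTOFF = 10
WEIGHT_LOSS_FRACTION = 0.10
PIR_LOW_CUTOFF = 1.85


def categorize_afssm(raw):
    """Map an AFSSM raw affirmative count (0-10) to a severity category.

    0 -> High, 1-2 -> Marginal, 3-5 -> Low, 6-10 -> VeryLow.
    """
    return _categorize(raw, bins=(0, 2, 5, 10), scale_max=10)


def categorize_pfs(raw):
    """Map a PFS raw affirmative count (0-6) to a severity category.

    0 -> High, 1-2 -> Marginal, 3-4 -> Low, 5-6 -> VeryLow.
    """
    return _categorize(raw, bins=(0, 2, 4, 6), scale_max=6)


def _categorize(raw, bins, scale_max):
    arr = np.asarray(raw, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    valid = ~np.isnan(arr)
    if np.any((arr[valid] < 0) | (arr[valid] > scale_max)):
        raise ValueError(f"raw score outside [0, {scale_max}]")
    if np.any(arr[valid] != np.round(arr[valid])):
        raise ValueError("raw score must be an integer count")
    out = np.full(arr.shape, np.nan)
    hi_edges = np.array(bins, dtype=float)
    out[valid] = np.searchsorted(hi_edges, arr[valid], side="left")
    if scalar:
        return Category(int(out[0])) if valid[0] else None
    return out


#: Sentinel for AFSSM items skipped by the household screener (the module
#: stops asking once a respondent screens out as clearly food secure).
SCREENED_OUT = -1


def afssm_raw_score(table: pd.DataFrame, screened_as: str = "negative") -> pd.Series:
    """Raw AFSSM score: count of affirmative items; NaN if any item missing.

    Items carrying the ``SCREENED_OUT`` sentinel (-1) were never asked
    because the respondent screened out of the module; by default they
    count as negative responses.  ``screened_as="missing"`` instead
    treats them as missing, which excludes the record downstream.
    """
    if screened_as not in ("negative", "missing"):
        raise ValueError("screened_as must be 'negative' or 'missing'")
    items = table[AFSSM_ITEMS].copy()
    screened = items == SCREENED_OUT
    items = items.mask(screened, 0.0 if screened_as == "negative" else np.nan)
    raw = items.sum(axis=1)
    raw[items.isna().any(axis=1)] = np.nan
    return raw


def pfs_affirmative(table: pd.DataFrame) -> pd.DataFrame:
    """Dichotomize 4-level PFS responses: any difficulty counts affirmative."""
    items = table[PFS_ITEMS]
    aff = items.isin(PFS_AFFIRMATIVE_LEVELS).astype(float)
    aff[items.isna()] = np.nan
    return aff


def pfs_raw_score(table: pd.DataFrame) -> pd.Series:
    """Raw PFS score: count of items with any reported difficulty."""
    aff = pfs_affirmative(table)
    raw = aff.sum(axis=1)
    raw[aff.isna().any(axis=1)] = np.nan
    return raw


def score_phq9(table: pd.DataFrame) -> pd.DataFrame:
    """PHQ-9 total (0-27) and depression flag (total >= 10).

    Respondents missing any of the nine items receive NaN for both, so
    they drop out of depression analyses, mirroring complete-case
    handling of the screener.
    """
    items = table[PHQ9_ITEMS]
    if not items.dropna().isin([0, 1, 2, 3]).all().all():
        raise ValueError("PHQ-9 item scores must be in {0,1,2,3}")
    total = items.sum(axis=1)
    total[items.isna().any(axis=1)] = np.nan
    depressed = (total >= PHQ9_DEPRESSION_CUTOFF).astype(float)
    depressed[total.isna()] = np.nan
    return pd.DataFrame({"phq9_total": total, "depressed": depressed})


def derive_flags(table: pd.DataFrame) -> pd.DataFrame:
    """Dichotomized analysis variables derived from raw survey fields.

    - ``significant_weight_loss``: lost >= 10% of body weight relative to
      the weight one year ago (inclusive boundary).
    - ``poor_srh``: self-reported health fair or poor (codes 4, 5 on the
      5-level excellent..poor item).
    - ``appetite_problem``: PHQ-9 appetite item affirmative (score >= 1).
    - ``depression_difficulty``: the functional-difficulty follow-up is
      anything other than "not at all difficult" (code >= 1).
    - ``pir_low``: income-to-poverty ratio <= 1.85.

    Each flag is NaN wherever its source field is missing.
    """
    out = pd.DataFrame(index=table.index)

    if {"weight_now", "weight_1y_ago"} <= set(table.columns):
        prior = table["weight_1y_ago"]
        if (prior.dropna() <= 0).any():
            raise ValueError("nonpositive 1-year-ago body weight")
        frac = (prior - table["weight_now"]) / prior
        flag = (frac >= WEIGHT_LOSS_FRACTION).astype(float)
        flag[frac.isna()] = np.nan
        out["significant_weight_loss"] = flag

    if "srh" in table.columns:
        srh = table["srh"]
        poor = srh.isin([4, 5]).astype(float)
        poor[srh.isna()] = np.nan
        out["poor_srh"] = poor

    if "phq8_appetite" in table.columns:
        app = table["phq8_appetite"]
        out["appetite_problem"] = _ge_flag(app, 1)

    if "phq_difficulty" in table.columns:
        out["depression_difficulty"] = _ge_flag(table["phq_difficulty"], 1)

    if "pir" in table.columns:
        pir = table["pir"]
        low = (pir <= PIR_LOW_CUTOFF).astype(float)
        low[pir.isna()] = np.nan
        out["pir_low"] = low

    return out


def _ge_flag(series: pd.Series, cutoff) -> pd.Series:
    flag = (series >= cutoff).astype(float)
    flag[series.isna()] = np.nan
    return flag
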
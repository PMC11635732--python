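"""Joint severity cross-classification of the two food-security scales.

A respondent is assigned the more severe of their two scale categories:
someone food insecure on either the resource-constraint dimension or the
physical-functioning dimension cannot be counted food secure overall.
Formally, for AFSSM category ``a`` and PFS category ``p``,

    joint = max(severity(a), severity(p))

which reproduces the full 4 x 4 assignment grid: one (High, High) cell
maps to joint High, three cells to Marginal, five to Low, and seven to
VeryLow.  The maximum rule generalizes to any pair of ordered scales;
the explicit 16-entry grid is kept in the test-suite as an independent
oracle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .categories import CATEGORIES, JOINT_LABELS, Category
from . import scales


def cross_classify(afssm_cat, pfs_cat):
    """Joint severity category: the maximum of the two scale severities.

    Accepts ``Category`` scalars or numeric vectors (NaN = missing).
    Missing on either scale yields a missing joint status.
    """
    if afssm_cat is None or pfs_cat is None:
        return None
    if isinstance(afssm_cat, Category) and isinstance(pfs_cat, Category):
        return Category(max(int(afssm_cat), int(pfs_cat)))
    a = np.asarray(afssm_cat, dtype=float)
    p = np.asarray(pfs_cat, dtype=float)
    for arr in (a, p):
        valid = arr[~np.isnan(arr)]
        if np.any((valid < 0) | (valid > 3)):
            raise ValueError("category codes must be in 0..3")
    return np.where(np.isnan(a) | np.isnan(p), np.nan, np.maximum(a, p))


def cross_classify_raw(afssm_raw, pfs_raw):
    """Cross-classify directly from raw scores (0-10 and 0-6)."""
    a = scales.categorize_afssm(afssm_raw)
    p = scales.categorize_pfs(pfs_raw)
    return cross_classify(a, p)


def classify_table(table: pd.DataFrame, screened_as: str = "negative") -> pd.DataFrame:
    """Append raw scores, per-scale categories and the joint category.

    Adds columns ``afssm_raw``, ``afssm_cat``, ``pfs_raw``, ``pfs_cat``
    and ``crossclass_cat`` (numeric severity codes, NaN where a battery
    is incomplete).
    """
    out = table.copy()
    out["afssm_raw"] = scales.afssm_raw_score(out, screened_as=screened_as)
    out["pfs_raw"] = scales.pfs_raw_score(out)
    out["afssm_cat"] = scales.categorize_afssm(out["afssm_raw"])
    out["pfs_cat"] = scales.categorize_pfs(out["pfs_raw"])
    out["crossclass_cat"] = cross_classify(out["afssm_cat"], out["pfs_cat"])
    return out


def tabulate_subcategories(table: pd.DataFrame) -> pd.DataFrame:
    """4 x 4 count matrix of (PFS category row, AFSSM category column).

    Cell (p, a) counts respondents with PFS category p and AFSSM
    category a; every respondent with both categories defined appears in
    exactly one cell, so the grand total equals the analytic n.
    """
    sub = table.dropna(subset=["afssm_cat", "pfs_cat"])
    counts = pd.crosstab(sub["pfs_cat"].astype(int), sub["afssm_cat"].astype(int))
    full = counts.reindex(
        index=[int(c) for c in CATEGORIES],
        columns=[int(c) for c in CATEGORIES],
        fill_value=0,
    )
    full.index = [c.label for c in CATEGORIES]
    full.columns = [c.label for c in CATEGORIES]
    full.index.name = "pfs"
    full.columns.name = "afssm"
    return full


def joint_label(cat) -> str:
    """Display label for a joint category, e.g. ``LFS/L-PFS``."""
    return JOINT_LABELS[Category(int(cat))]
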
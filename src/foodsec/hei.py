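"""Per-person simple HEI-2015 scoring from two-day dietary totals.

The simple scoring algorithm pools both 24-hour recalls before forming
densities: per-person totals of each constituent and of energy are
summed over the two days, the constituent-to-energy ratio is computed
once, and each of the 13 components is scored by linear interpolation
between its published standards, clipped to [0, max points].  Adequacy
components reward higher density; moderation components reward lower.
The total is the sum of component scores and lies in [0, 100].

Input columns follow the Food Patterns Equivalents conventions:
cup/oz equivalents per day for food groups, grams for fatty acids and
sodium, teaspoon equivalents for added sugars, with day suffixes
``_day1`` / ``_day2`` (e.g. ``f_total_cup_day1``).
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd
import yaml

DAY_SUFFIXES = ("_day1", "_day2")


def load_standards(path=None) -> dict:
    """Load a scoring-standards table (bundled HEI-2015 by default)."""
    if path is None:
        ref = importlib.resources.files("foodsec.data") / "hei2015_standards.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    comps = raw["components"]
    total = sum(c["max_points"] for c in comps.values())
    if total != 100:
        raise ValueError(f"component max points sum to {total}, expected 100")
    for name, c in comps.items():
        if c["min_standard"] == c["max_standard"]:
            raise ValueError(f"component {name}: min_standard equals max_standard")
    return comps


def pool_days(intake: pd.DataFrame) -> pd.DataFrame:
    """Sum the two recall days into per-person totals.

    A respondent missing either day's energy is marked unscorable
    (all pooled fields NaN), matching complete-recall inclusion rules.
    Pooled zero energy is retained here and rejected at scoring time.
    """
    base_cols = sorted(
        {c[: -len(DAY_SUFFIXES[0])] for c in intake.columns if c.endswith(DAY_SUFFIXES)}
    )
    pooled = pd.DataFrame(index=intake.index)
    for base in base_cols:
        d1, d2 = (f"{base}{s}" for s in DAY_SUFFIXES)
        pooled[base] = intake[d1] + intake[d2]
    incomplete = (
        intake[f"energy_kcal{DAY_SUFFIXES[0]}"].isna()
        | intake[f"energy_kcal{DAY_SUFFIXES[1]}"].isna()
    )
    pooled.loc[incomplete, :] = np.nan
    pooled["complete_recalls"] = ~incomplete
    return pooled


def score_component(amount, energy, spec) -> np.ndarray:
    """Score one component from pooled amount and pooled energy.

    ``spec`` is one entry of the standards table.  Density components
    use amount per 1,000 kcal; percent-energy components convert the
    amount with ``kcal_per_unit``; the fatty-acid ratio is passed as the
    precomputed ratio in ``amount`` with ``energy`` ignored.
    """
    amount = np.asarray(amount, dtype=float)
    energy = np.asarray(energy, dtype=float)
    kind = spec["kind"]
    if kind == "density":
        with np.errstate(divide="ignore", invalid="ignore"):
            d = amount / energy * 1000.0
    elif kind == "percent_energy":
        with np.errstate(divide="ignore", invalid="ignore"):
            d = amount * spec["kcal_per_unit"] / energy * 100.0
    elif kind == "ratio":
        d = amount
    else:
        raise ValueError(f"unknown component kind {kind!r}")
    lo, hi = spec["min_standard"], spec["max_standard"]
    frac = (d - lo) / (hi - lo)
    if spec["direction"] == "moderation":
        frac = 1.0 - frac
    score = spec["max_points"] * np.clip(frac, 0.0, 1.0)
    return np.where(np.isnan(d), np.nan, score)


def _fatty_acid_ratio(pooled: pd.DataFrame) -> np.ndarray:
    mu_pu = pooled["mufa_g"] + pooled["pufa_g"]
    sfa = pooled["sfa_g"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mu_pu / sfa
    # zero saturated fat: most favorable ratio if any unsaturated fat,
    # least favorable if the diet reports no fat at all
    ratio = np.where((sfa == 0) & (mu_pu > 0), np.inf, ratio)
    ratio = np.where((sfa == 0) & (mu_pu == 0), 0.0, ratio)
    return np.asarray(ratio, dtype=float)


def score_hei(pooled: pd.DataFrame, standards: dict | None = None) -> pd.DataFrame:
    """Score all 13 HEI-2015 components and the total per respondent.

    Expects pooled two-day totals (see :func:`pool_days`).  Respondents
    with missing or zero pooled energy are unscorable and carry NaN.
    """
    if standards is None:
        standards = load_standards()
    energy = pooled["energy_kcal"].to_numpy(dtype=float)
    scorable = np.isfinite(energy) & (energy > 0)
    out = pd.DataFrame(index=pooled.index)
    for name, spec in standards.items():
        if spec["kind"] == "ratio":
            amount = _fatty_acid_ratio(pooled)
        else:
            amount = pooled[spec["amount_field"]].to_numpy(dtype=float)
        s = score_component(amount, energy, spec)
        out[f"hei_{name}"] = np.where(scorable, s, np.nan)
    comp_cols = list(out.columns)
    out["hei_total"] = out[comp_cols].sum(axis=1)
    out.loc[out[comp_cols].isna().any(axis=1), "hei_total"] = np.nan
    return out


def score_recalls(intake: pd.DataFrame, standards: dict | None = None) -> pd.DataFrame:
    """Convenience wrapper: pool two recall days, then score."""
    return score_hei(pool_days(intake), standards)
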
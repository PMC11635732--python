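"""Synthetic survey microdata with the structure the analysis assumes.

The generator emulates pooled-cycle public microdata on adults aged 60
and over: a stratified two-PSUs-per-stratum design with log-normal
weight variation, 16 food-security item responses driven by three
correlated latent factors (resource constraint, physical limitation,
and a severity/frequency doublet carried by the two "whole day" items),
demographics, PHQ-9 depression items, self-reported health, weight
history, condition flags, and two-day dietary recalls with
category-dependent diet quality.

Item responses follow a correlated latent-threshold (probit) model:
item i is affirmative when ``lambda_i' f + e_i > tau_i`` with factors
``f ~ N(0, Phi)`` and unique noise scaled so each latent has unit
variance.  The default thresholds and the factor-1/factor-2 correlation
were calibrated once (see :func:`calibrate_thresholds`) so that the
model-implied AFSSM and PFS category shares match the published
benchmark distribution (86.0/6.0/4.7/3.3 and 52.7/31.4/11.4/4.4 percent)
and the joint cross-classified High share matches 48.3 percent.

Binary outcomes are drawn from logistic models on the joint category
with configurable odds ratios; every planted parameter is returned in a
truth ledger sufficient to recompute the generating quantities without
the pipeline.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from . import crossclass, scales
from .categories import CATEGORIES

# ---------------------------------------------------------------------------
# latent measurement model

#: Loadings of the 16 items (10 AFSSM then 6 PFS) on the three factors.
#: AFSSM items 9-10 are the "not eat for a whole day" pair carried by the
#: severity/frequency factor.
DEFAULT_LOADINGS = np.zeros((16, 3))
DEFAULT_LOADINGS[0:8, 0] = [0.93, 0.94, 0.92, 0.93, 0.90, 0.92, 0.89, 0.88]
DEFAULT_LOADINGS[8:10, 0] = [0.45, 0.45]
DEFAULT_LOADINGS[8:10, 2] = [0.80, 0.80]
DEFAULT_LOADINGS[10:16, 1] = [0.78, 0.80, 0.74, 0.70, 0.76, 0.72]

#: Affirmative base probabilities before calibration; decreasing within a
#: scale with item severity.
_BASE_P_AFSSM = np.array(
    [0.11, 0.10, 0.085, 0.065, 0.05, 0.035, 0.028, 0.022, 0.014, 0.010]
)
_BASE_P_PFS = np.array([0.30, 0.32, 0.14, 0.17, 0.09, 0.05])

#: Calibrated threshold adjustments (shift, log-spread, severe-tail shift)
#: per scale plus the factor-1/factor-2 correlation; produced by
#: calibrate_thresholds() against the benchmark category shares and frozen
#: as defaults.
CALIBRATED_PARAMS = {
    "afssm": (0.40305411, -0.15517854, -0.31720919),
    "pfs": (0.09030044, 0.00761794, -0.38817943),
    "rho12": 0.43131168,
    "rho13": 0.50,
    "rho23": 0.30,
}

#: Benchmark category shares used as calibration anchors (percent).
BENCHMARK_SHARES = {
    "crossclass": (48.3, 30.8, 13.6, 7.3),
    "afssm": (86.0, 6.0, 4.7, 3.3),
    "pfs": (52.7, 31.4, 11.4, 4.4),
}

#: Planted adjusted odds ratios (Marginal, Low, VeryLow vs High).
DEFAULT_DEPRESSION_ORS = (2.92, 6.36, 14.6)
DEFAULT_SRH_ORS = (3.44, 7.64, 12.7)
#: Mean HEI-2015 totals by joint category used by the dietary generator.
DEFAULT_HEI_MEANS = (58.5, 56.5, 55.1, 53.4)


def _thresholds(base_p: np.ndarray, shift: float, log_spread: float, tail: float,
                n_tail: int) -> np.ndarray:
    tau = scipy.stats.norm.ppf(1 - base_p)
    tau = tau * np.exp(log_spread) + shift
    tau[-n_tail:] += tail
    return tau


def default_thresholds() -> tuple[np.ndarray, np.ndarray]:
    """Calibrated item thresholds for the AFSSM and PFS batteries."""
    ta = _thresholds(_BASE_P_AFSSM, *CALIBRATED_PARAMS["afssm"], n_tail=5)
    tp = _thresholds(_BASE_P_PFS, *CALIBRATED_PARAMS["pfs"], n_tail=2)
    return ta, tp


def factor_correlation(rho12=None) -> np.ndarray:
    r12 = CALIBRATED_PARAMS["rho12"] if rho12 is None else rho12
    r13 = CALIBRATED_PARAMS["rho13"]
    r23 = CALIBRATED_PARAMS["rho23"]
    return np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1]])


@dataclasses.dataclass
class GeneratorConfig:
    """Parameters of the synthetic population.

    Defaults are the calibrated study conditions; see the module
    docstring.  ``weight_sigma`` is the log-normal sigma of the design
    weights (coefficient of variation about 0.53 at the default 0.5).
    """

    n: int = 10_000
    seed: int = 0
    n_strata: int = 15
    psus_per_stratum: int = 2
    n_cycles: int = 6
    weight_sigma: float = 0.5
    loadings: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_LOADINGS.copy()
    )
    rho12: float | None = None
    tau_afssm: np.ndarray | None = None
    tau_pfs: np.ndarray | None = None
    depression_ors: tuple = DEFAULT_DEPRESSION_ORS
    srh_ors: tuple = DEFAULT_SRH_ORS
    depression_base_rate: float = 0.035
    srh_base_rate: float = 0.12
    hei_means: tuple = DEFAULT_HEI_MEANS
    hei_sd: float = 10.0
    missingness: bool = False

    def resolve(self):
        ta = self.tau_afssm if self.tau_afssm is not None else default_thresholds()[0]
        tp = self.tau_pfs if self.tau_pfs is not None else default_thresholds()[1]
        return np.asarray(ta, float), np.asarray(tp, float), factor_correlation(self.rho12)


def _latent_items(rng, n, loadings, Phi, tau_a, tau_p):
    """Draw the 16 latent item variables and dichotomize."""
    Phi = np.asarray(Phi, float)
    Phi = (Phi + Phi.T) / 2
    L = np.linalg.cholesky(Phi)
    f = rng.standard_normal((n, 3)) @ L.T
    comm = np.einsum("ij,jk,ik->i", loadings, Phi, loadings)
    comm = np.clip(comm, 0, 0.98)
    ystar = f @ loadings.T + rng.standard_normal((n, 16)) * np.sqrt(1 - comm)
    tau = np.concatenate([tau_a, tau_p])
    aff = ystar > tau
    return f, ystar, aff


_SHARES_CACHE: dict = {}


def model_category_shares(config: GeneratorConfig, m: int = 200_000, seed: int = 12345):
    """Model-implied category shares by large-sample Monte Carlo.

    Returns a dict of length-4 probability vectors for the AFSSM scale,
    the PFS scale and the joint cross-classification.  Cached on the
    measurement-model parameters (shares do not depend on n or the
    generation seed).
    """
    ta, tp, Phi = config.resolve()
    key = (
        ta.tobytes(),
        tp.tobytes(),
        Phi.tobytes(),
        np.asarray(config.loadings, float).tobytes(),
        m,
        seed,
    )
    if key in _SHARES_CACHE:
        return _SHARES_CACHE[key]
    rng = np.random.default_rng(seed)
    _, _, aff = _latent_items(rng, m, config.loadings, Phi, ta, tp)
    raw_a = aff[:, :10].sum(axis=1)
    raw_p = aff[:, 10:].sum(axis=1)
    cat_a = np.asarray(scales.categorize_afssm(raw_a))
    cat_p = np.asarray(scales.categorize_pfs(raw_p))
    joint = np.maximum(cat_a, cat_p)
    out = {}
    for name, cat in (("afssm", cat_a), ("pfs", cat_p), ("crossclass", joint)):
        out[name] = np.array([(cat == int(c)).mean() for c in CATEGORIES])
    _SHARES_CACHE[key] = out
    return out


def calibrate_thresholds(
    targets: dict | None = None,
    loadings: np.ndarray | None = None,
    m: int = 200_000,
    seed: int = 12345,
) -> dict:
    """Fit threshold adjustments and rho12 to benchmark category shares.

    Seven parameters (shift, log-spread and severe-tail shift per scale,
    plus the resource/physical factor correlation) are fit by least
    squares over a fixed Monte-Carlo sample of the latent normals to
    seven anchors: the three free AFSSM shares, the three free PFS
    shares, and the joint cross-classified High share.  Raises if the
    residual share error exceeds half a percentage point (infeasible
    targets).
    """
    if targets is None:
        targets = BENCHMARK_SHARES
    lam = DEFAULT_LOADINGS if loadings is None else loadings
    rng = np.random.default_rng(seed)
    f0 = rng.standard_normal((m, 3))
    e0 = rng.standard_normal((m, 16))
    t_a = np.asarray(targets["afssm"], float) / 100
    t_p = np.asarray(targets["pfs"], float) / 100
    t_j = np.asarray(targets["crossclass"], float) / 100
    r13, r23 = CALIBRATED_PARAMS["rho13"], CALIBRATED_PARAMS["rho23"]

    def shares(theta):
        ca, sa, taila, cp, sp, tailp, z = theta
        r12 = 0.9 * np.tanh(z)
        Phi = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1]])
        L = np.linalg.cholesky(Phi)
        f = f0 @ L.T
        comm = np.clip(np.einsum("ij,jk,ik->i", lam, Phi, lam), 0, 0.98)
        ystar = f @ lam.T + e0 * np.sqrt(1 - comm)
        tau = np.concatenate(
            [
                _thresholds(_BASE_P_AFSSM, ca, sa, taila, n_tail=5),
                _thresholds(_BASE_P_PFS, cp, sp, tailp, n_tail=2),
            ]
        )
        aff = ystar > tau
        raw_a = aff[:, :10].sum(axis=1)
        raw_p = aff[:, 10:].sum(axis=1)
        cat_a = np.asarray(scales.categorize_afssm(raw_a))
        cat_p = np.asarray(scales.categorize_pfs(raw_p))
        joint = np.maximum(cat_a, cat_p)
        pa = np.array([(cat_a == k).mean() for k in range(4)])
        pp = np.array([(cat_p == k).mean() for k in range(4)])
        pj = np.array([(joint == k).mean() for k in range(4)])
        return pa, pp, pj

    def _simplex(x0, step):
        return np.vstack([x0] + [x0 + step * row for row in np.eye(len(x0))])

    def _nm(fun, x0, step):
        res = scipy.optimize.minimize(
            fun,
            x0,
            method="Nelder-Mead",
            options=dict(
                initial_simplex=_simplex(np.asarray(x0, float), step),
                xatol=1e-6,
                fatol=1e-14,
                maxiter=4000,
            ),
        )
        return res.x

    z0 = np.arctanh(0.35 / 0.9)
    # scale marginals do not depend on rho12, so calibrate per scale first
    xa = _nm(
        lambda x: ((shares([*x, 0, 0, 0, z0])[0][1:] - t_a[1:]) ** 2).sum(),
        np.zeros(3),
        0.3,
    )
    xp = _nm(
        lambda x: ((shares([*xa, *x, z0])[1][1:] - t_p[1:]) ** 2).sum(),
        np.zeros(3),
        0.3,
    )
    zj = scipy.optimize.minimize_scalar(
        lambda z: ((shares([*xa, *xp, z])[2][1:] - t_j[1:]) ** 2).sum(),
        bounds=(0.0, 1.8),
        method="bounded",
        options=dict(xatol=1e-5),
    ).x

    def total(theta):
        pa, pp, pj = shares(theta)
        return (
            ((pa[1:] - t_a[1:]) ** 2).sum()
            + ((pp[1:] - t_p[1:]) ** 2).sum()
            + ((pj[1:] - t_j[1:]) ** 2).sum()
        )

    theta = _nm(total, np.array([*xa, *xp, zj]), 0.05)
    pa, pp, pj = shares(theta)
    err = float(
        np.abs(
            np.concatenate([pa[1:] - t_a[1:], pp[1:] - t_p[1:], pj[1:] - t_j[1:]])
        ).max()
    )
    # a single inter-scale correlation cannot reproduce arbitrary joint
    # tails; anything beyond 2 percentage points means infeasible targets
    if err > 0.02:
        raise ValueError(
            f"calibration infeasible: max share error {err:.4f} against targets"
        )
    ca, sa, taila = theta[:3]
    cp, sp, tailp = theta[3:6]
    return {
        "afssm": (ca, sa, taila),
        "pfs": (cp, sp, tailp),
        "rho12": 0.9 * np.tanh(theta[6]),
        "max_share_error": err,
    }


# ---------------------------------------------------------------------------
# population generation

_RACE_P = np.array([0.05, 0.04, 0.75, 0.09, 0.07])
_EDU_P = np.array([0.18, 0.25, 0.57])
_HH_P = np.array([0.24, 0.55, 0.21])


def generate_population(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Draw a respondent table and the truth ledger of planted parameters.

    The table carries every column the analysis pipeline consumes (item
    batteries, demographics, design variables with 2-year weights, PHQ-9
    items, health outcomes).  The ledger records the planted odds
    ratios, base rates, model-implied category shares and the
    per-respondent true joint category.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    ta, tp, Phi = config.resolve()

    f, ystar, aff = _latent_items(rng, n, config.loadings, Phi, ta, tp)
    table = pd.DataFrame({"respondent_id": np.arange(1, n + 1)})
    for i, col in enumerate(scales.AFSSM_ITEMS):
        table[col] = aff[:, i].astype(float)
    # PFS items are 4-level: grade affirmative responses by latent excess
    for j, col in enumerate(scales.PFS_ITEMS):
        y = ystar[:, 10 + j]
        level = np.zeros(n)
        a = aff[:, 10 + j]
        excess = np.clip(y - tp[j], 0, None)
        level[a] = 1 + np.minimum(2, np.floor(excess[a] / 0.8))
        table[col] = level

    raw_a = aff[:, :10].sum(axis=1)
    raw_p = aff[:, 10:].sum(axis=1)
    cat_a = np.asarray(scales.categorize_afssm(raw_a))
    cat_p = np.asarray(scales.categorize_pfs(raw_p))
    joint = np.maximum(cat_a, cat_p).astype(int)

    # demographics, independent of the food-security factors
    table["age_years"] = 60 + np.minimum(rng.exponential(8.5, n).astype(int), 35)
    table["sex"] = rng.integers(0, 2, n)
    table["race_ethnicity"] = rng.choice(5, n, p=_RACE_P)
    table["education"] = rng.choice(3, n, p=_EDU_P)
    table["marital"] = rng.integers(0, 2, n)
    table["household_size"] = rng.choice([1, 2, 3], n, p=_HH_P)
    table["pir"] = np.round(np.minimum(np.exp(rng.normal(0.8, 0.7, n)), 5.0), 2)

    # binary outcomes from logistic models on the joint category
    covs = {
        "age_years": 0.02,
        "sex": 0.25,
        "education": -0.15,
        "marital": -0.10,
    }
    dep_logor = np.log(np.array([1.0, *config.depression_ors]))
    srh_logor = np.log(np.array([1.0, *config.srh_ors]))

    def draw_binary(base_rate, logor):
        eta_cov = sum(
            b * (table[c] - table[c].mean()).to_numpy() for c, b in covs.items()
        )
        alpha = np.log(base_rate / (1 - base_rate))
        eta = alpha + logor[joint] + eta_cov
        return (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)

    depressed = draw_binary(config.depression_base_rate, dep_logor)
    poor_srh = draw_binary(config.srh_base_rate, srh_logor)

    # PHQ-9 items consistent with the depression flag
    totals = np.where(
        depressed == 1,
        10 + rng.binomial(17, 0.25, n),
        np.minimum(rng.binomial(12, 0.2, n), 9),
    )
    items = _allocate_phq_items(rng, totals)
    for k, col in enumerate(scales.PHQ9_ITEMS):
        table[col] = items[:, k].astype(float)
    table["phq8_appetite"] = table["phq5"]
    diff_p = 1 / (1 + np.exp(-(-2.6 + 0.9 * joint)))
    table["phq_difficulty"] = (rng.random(n) < diff_p) * rng.integers(1, 4, n)

    table["srh"] = np.where(
        poor_srh == 1, rng.integers(4, 6, n), rng.integers(1, 4, n)
    ).astype(float)

    # weight history: loss probability rises with severity
    w1y = np.round(np.clip(rng.normal(78, 14, n), 45, 160), 1)
    p_loss = 0.05 + 0.03 * joint
    losing = rng.random(n) < p_loss
    frac = np.where(
        losing, rng.uniform(0.10, 0.22, n), rng.uniform(-0.06, 0.08, n)
    )
    table["weight_1y_ago"] = w1y
    table["weight_now"] = np.round(w1y * (1 - frac), 1)

    for cond, (base, slope) in {
        "arthritis": (0.40, 0.45),
        "coronary_artery_disease": (0.08, 0.25),
        "diabetes": (0.18, 0.30),
        "stroke": (0.03, 0.55),
        "cancer": (0.23, 0.0),
    }.items():
        p = 1 / (1 + np.exp(-(np.log(base / (1 - base)) + slope * joint)))
        table[cond] = (rng.random(n) < p).astype(float)

    # design: strata, two PSUs per stratum, log-normal 2-year weights
    table["stratum"] = rng.integers(0, config.n_strata, n)
    table["psu"] = rng.integers(0, config.psus_per_stratum, n)
    base_w = np.exp(
        rng.normal(np.log(10_000), config.weight_sigma, n)
    )
    table["wtint2yr"] = base_w
    table["wtmec2yr"] = base_w * np.exp(rng.normal(0, 0.1, n))
    table["wtdr2d2yr"] = base_w * np.exp(rng.normal(0, 0.15, n))
    table["cycle"] = rng.integers(1, config.n_cycles + 1, n)

    if config.missingness:
        for battery, rate in ((scales.PHQ9_ITEMS, 0.10), (["pir"], 0.09)):
            for col in battery:
                mask = rng.random(n) < rate / len(battery)
                table.loc[mask, col] = np.nan

    ledger = {
        "config": dataclasses.asdict(
            dataclasses.replace(config, loadings=None, tau_afssm=None, tau_pfs=None)
        ),
        "loadings": config.loadings.tolist(),
        "tau_afssm": ta.tolist(),
        "tau_pfs": tp.tolist(),
        "factor_correlation": Phi.tolist(),
        "depression_ors": list(config.depression_ors),
        "srh_ors": list(config.srh_ors),
        "covariate_log_odds": covs,
        "model_category_shares": {
            k: v.tolist() for k, v in model_category_shares(config).items()
        },
        "true_joint_category": joint.tolist(),
    }
    return table, ledger


def _allocate_phq_items(rng, totals):
    """Distribute each total over 9 items scored 0-3, uniformly at random."""
    n = len(totals)
    items = np.zeros((n, 9), dtype=int)
    remaining = totals.copy()
    for k in range(9):
        slots_left = 8 - k
        lo = np.maximum(0, remaining - 3 * slots_left)
        hi = np.minimum(3, remaining)
        items[:, k] = lo + (rng.random(n) * (hi - lo + 1)).astype(int)
        remaining = remaining - items[:, k]
    return items


# ---------------------------------------------------------------------------
# dietary generation

_ADEQUACY_FIELDS = {
    "f_total_cup": 0.8,
    "f_whole_cup": 0.4,
    "v_total_cup": 1.1,
    "v_greens_beans_cup": 0.2,
    "g_whole_oz": 1.5,
    "dairy_cup": 1.3,
    "pf_total_oz": 2.5,
    "pf_seafood_plant_oz": 0.8,
}
_MODERATION_FIELDS = {
    "g_refined_oz": (1.8, 4.3),
    "sodium_g": (1.1, 2.0),
}


def generate_dietary(config: GeneratorConfig, table: pd.DataFrame,
                     joint_category=None) -> pd.DataFrame:
    """Two-day dietary recalls with category-dependent diet quality.

    A latent quality u in [0, 1] is drawn per respondent with mean
    ``hei_means[category] / 100``; component densities interpolate
    between each component's zero-score and full-score standards in
    proportion to a noisy copy of u, which makes the expected HEI total
    approximately 100 u and strictly decreasing in severity when the
    configured means decrease.  Setting all ``hei_means`` equal removes
    the gradient.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(table)
    if joint_category is None:
        classified = crossclass.classify_table(table)
        joint_category = classified["crossclass_cat"].to_numpy()
    joint = np.nan_to_num(np.asarray(joint_category, float), nan=0.0).astype(int)
    mean_u = np.asarray(config.hei_means, float)[joint] / 100.0
    u = np.clip(rng.normal(mean_u, config.hei_sd / 100.0), 0.02, 0.98)

    out = pd.DataFrame(index=table.index)
    energy = np.clip(rng.normal(1850, 330, (n, 2)), 800, None)
    out["energy_kcal_day1"], out["energy_kcal_day2"] = energy.T
    etot = energy.sum(axis=1)

    def noisy_u():
        return np.clip(u + rng.normal(0, 0.06, n), 0.0, 1.0)

    def split_days(total_amount):
        share = energy[:, 0] / etot
        return total_amount * share, total_amount * (1 - share)

    for field, full_std in _ADEQUACY_FIELDS.items():
        density = noisy_u() * full_std
        d1, d2 = split_days(density * etot / 1000.0)
        out[f"{field}_day1"], out[f"{field}_day2"] = d1, d2
    for field, (full_std, zero_std) in _MODERATION_FIELDS.items():
        density = zero_std - noisy_u() * (zero_std - full_std)
        d1, d2 = split_days(density * etot / 1000.0)
        out[f"{field}_day1"], out[f"{field}_day2"] = d1, d2

    # percent-energy moderation components
    sug_pct = 26.0 - noisy_u() * (26.0 - 6.5)
    sug_tsp = sug_pct / 100.0 * etot / 16.0
    d1, d2 = split_days(sug_tsp)
    out["add_sugars_tsp_day1"], out["add_sugars_tsp_day2"] = d1, d2
    sfa_pct = 16.0 - noisy_u() * (16.0 - 8.0)
    sfa_g = sfa_pct / 100.0 * etot / 9.0
    d1, d2 = split_days(sfa_g)
    out["sfa_g_day1"], out["sfa_g_day2"] = d1, d2
    # fatty-acid ratio component built on top of the generated SFA
    ratio = 1.2 + noisy_u() * (2.5 - 1.2)
    unsat = ratio * sfa_g
    for name, frac in (("mufa_g", 0.6), ("pufa_g", 0.4)):
        d1, d2 = split_days(unsat * frac)
        out[f"{name}_day1"], out[f"{name}_day2"] = d1, d2
    return out
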
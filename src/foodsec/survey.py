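"""Design-based estimation for stratified multistage survey samples.

All variance estimation uses first-stage Taylor linearization: score or
residual contributions are totalled within primary sampling units (PSUs)
and the between-PSU covariance is accumulated within strata with the
with-replacement approximation

    V = sum_h  n_h / (n_h - 1)  sum_j  (z_hj - zbar_h)(z_hj - zbar_h)'

where z_hj is the PSU-j total in stratum h.  Design degrees of freedom
are (#PSUs - #strata).  This is the standard NHANES analytic setup:
weights are nonnegative, at least two PSUs per stratum, and multiyear
weights are the 2-year weights divided by the number of pooled cycles.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "SurveyDesign",
    "build_multiyear_weights",
    "select_weight",
    "weighted_prevalence",
    "rao_scott_test",
    "design_ttest_bonferroni",
    "weighted_logistic",
    "weighted_linear",
    "compare_models",
]

WEIGHT_COLUMNS = {
    "interview": "wtint12yr",
    "mec": "wtmec12yr",
    "dietary": "wtdr2d12yr",
}
_TWO_YEAR_COLUMNS = {
    "wtint12yr": "wtint2yr",
    "wtmec12yr": "wtmec2yr",
    "wtdr2d12yr": "wtdr2d2yr",
}


@dataclasses.dataclass(frozen=True)
class SurveyDesign:
    """Stratum/PSU identifiers and a weight vector for one analysis.

    Parameters
    ----------
    stratum, psu
        Categorical identifiers; PSUs are nested within strata (the same
        psu code in two strata denotes two distinct units).
    weights
        Nonnegative analysis weights, one per respondent.
    lonely_psu
        ``"error"`` (default) raises when a stratum contains a single
        PSU; ``"center"`` centers a lonely PSU at the overall mean of
        PSU totals instead (grand-mean centering).
    """

    stratum: np.ndarray
    psu: np.ndarray
    weights: np.ndarray
    lonely_psu: str = "error"

    def __post_init__(self):
        s = np.asarray(self.stratum)
        p = np.asarray(self.psu)
        w = np.asarray(self.weights, dtype=float)
        if not (len(s) == len(p) == len(w)):
            raise ValueError("stratum, psu and weights must share length")
        if np.any(w < 0) or np.any(~np.isfinite(w)):
            raise ValueError("weights must be finite and nonnegative")
        if self.lonely_psu not in ("error", "center"):
            raise ValueError("lonely_psu must be 'error' or 'center'")
        object.__setattr__(self, "stratum", s)
        object.__setattr__(self, "psu", p)
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_table(cls, table: pd.DataFrame, weight: str, *, lonely_psu="error"):
        return cls(
            stratum=table["stratum"].to_numpy(),
            psu=table["psu"].to_numpy(),
            weights=table[weight].to_numpy(dtype=float),
            lonely_psu=lonely_psu,
        )

    def subset(self, mask: np.ndarray) -> "SurveyDesign":
        """Restrict to a boolean mask of respondents (a domain).

        Degrees of freedom should still come from the full design, so
        prefer zero-weighting for domain estimation; ``subset`` is for
        hard exclusions (records outside the analysis entirely).
        """
        return SurveyDesign(
            self.stratum[mask], self.psu[mask], self.weights[mask], self.lonely_psu
        )

    @property
    def n(self) -> int:
        return len(self.weights)

    def _cluster_codes(self):
        strat = pd.factorize(self.stratum)[0]
        clust = pd.factorize(
            pd.Series(self.stratum).astype(str) + "\x1f" + pd.Series(self.psu).astype(str)
        )[0]
        return strat, clust

    @property
    def degrees_of_freedom(self) -> int:
        strat, clust = self._cluster_codes()
        return len(np.unique(clust)) - len(np.unique(strat))

    def linearized_cov(self, z: np.ndarray) -> np.ndarray:
        """Design covariance of a total from per-respondent contributions.

        ``z`` has one row per respondent (weights already applied).
        Returns the k x k covariance of ``z.sum(axis=0)``.
        """
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[0] != self.n:
            z = z.T
        k = z.shape[1]
        strat, clust = self._cluster_codes()
        V = np.zeros((k, k))
        psu_tot = np.zeros((len(np.unique(clust)), k))
        np.add.at(psu_tot, clust, z)
        psu_strat = np.zeros(len(np.unique(clust)), dtype=int)
        psu_strat[clust] = strat
        grand_mean = psu_tot.mean(axis=0)
        for h in np.unique(psu_strat):
            th = psu_tot[psu_strat == h]
            nh = th.shape[0]
            if nh < 2:
                if self.lonely_psu == "error":
                    raise ValueError(
                        f"stratum {h} has a single PSU; variance undefined "
                        "(set lonely_psu='center' to center at the grand mean)"
                    )
                d = th[0] - grand_mean
                V += np.outer(d, d)
                continue
            dev = th - th.mean(axis=0)
            V += nh / (nh - 1) * dev.T @ dev
        return V


def build_multiyear_weights(table: pd.DataFrame, n_cycles: int) -> pd.DataFrame:
    """Derive pooled multiyear weights from per-cycle 2-year weights.

    Each multiyear weight is the 2-year weight divided by the number of
    pooled 2-year cycles (6 for a 2007-2018 pool).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    out = table.copy()
    for multi, two_year in _TWO_YEAR_COLUMNS.items():
        if two_year in out.columns:
            out[multi] = out[two_year] / n_cycles
    return out


def select_weight(analysis_kind: str) -> str:
    """Weight column for an analysis: interview, mec or dietary."""
    try:
        return WEIGHT_COLUMNS[analysis_kind]
    except KeyError:
        raise ValueError(
            f"unknown analysis kind {analysis_kind!r}; expected one of "
            f"{sorted(WEIGHT_COLUMNS)}"
        ) from None


def _t_ci(est, se, df, level=0.95):
    tcrit = scipy.stats.t.ppf(0.5 + level / 2, df)
    return est - tcrit * se, est + tcrit * se


def weighted_prevalence(
    values, design: SurveyDesign, *, level: float = 0.95, ci_method: str = "logit"
) -> pd.DataFrame:
    """Design-based category proportions with linearized SEs and CIs.

    The proportion for category c is the Horvitz-Thompson ratio
    ``sum(w * 1[y=c]) / sum(w)``; its variance comes from linearizing
    the ratio and totalling over PSUs.  Confidence intervals are Wald
    intervals on the logit scale (guaranteed inside [0, 1]) with the
    design degrees of freedom; ``ci_method="wald"`` gives plain Wald.
    """
    y = np.asarray(values, dtype=float)
    ok = ~np.isnan(y)
    w = np.where(ok, design.weights, 0.0)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("no positive weights among non-missing values")
    cats = np.unique(y[ok])
    df = design.degrees_of_freedom
    rows = []
    for c in cats:
        ind = np.where(ok, (y == c).astype(float), 0.0)
        p = float((w * ind).sum() / wsum)
        # linearized contribution of the ratio estimator
        z = w * (ind - p) / wsum
        se = float(np.sqrt(design.linearized_cov(z[:, None])[0, 0]))
        if se == 0:
            lo, hi = p, p
        elif ci_method == "logit" and 0 < p < 1:
            lp = np.log(p / (1 - p))
            lse = se / (p * (1 - p))
            llo, lhi = _t_ci(lp, lse, df, level)
            lo, hi = 1 / (1 + np.exp(-llo)), 1 / (1 + np.exp(-lhi))
        else:
            lo, hi = _t_ci(p, se, df, level)
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        rows.append(
            {
                "category": c,
                "proportion": p,
                "se": se,
                "ci_low": lo,
                "ci_high": hi,
                "n_unweighted": int(ok[y == c].sum()),
            }
        )
    return pd.DataFrame(rows)


def _weighted_crosstab(r, c, w):
    rc, r_codes = np.unique(r, return_inverse=True)
    cc, c_codes = np.unique(c, return_inverse=True)
    R, C = len(rc), len(cc)
    tot = np.zeros((R, C))
    np.add.at(tot, (r_codes, c_codes), w)
    return tot, r_codes, c_codes, R, C


def rao_scott_test(
    row_values, col_values, design: SurveyDesign, *, order: int = 2
) -> dict:
    """Rao-Scott corrected chi-square test of independence.

    The Pearson statistic is computed on the design-weighted estimated
    cell proportions scaled by the unweighted sample size, then adjusted
    by the eigenvalues of the generalized design-effect matrix of the
    independence residuals.  ``order=2`` (default) applies the
    second-order Satterthwaite correction and reports an F statistic
    with df1 = d / (1 + a^2); ``order=1`` divides by the mean design
    effect only.
    """
    r = np.asarray(row_values)
    c = np.asarray(col_values)
    ok = ~(pd.isna(r) | pd.isna(c))
    r, c = r[ok], c[ok]
    dsub = design.subset(ok)
    w = dsub.weights
    n = len(r)
    tot, r_codes, c_codes, R, C = _weighted_crosstab(r, c, w)
    if R < 2 or C < 2:
        raise ValueError("both variables need at least two observed categories")
    p_hat = tot / w.sum()
    prow = p_hat.sum(axis=1)
    pcol = p_hat.sum(axis=0)
    expected = np.outer(prow, pcol)
    X2 = n * float(((p_hat - expected) ** 2 / expected).sum())

    # design covariance of the vec'd cell proportions
    cell = r_codes * C + c_codes
    K = R * C
    ind = np.zeros((n, K))
    ind[np.arange(n), cell] = 1.0
    pv = p_hat.ravel()
    z = w[:, None] * (ind - pv) / w.sum()
    Vhat = dsub.linearized_cov(z)

    # residual Jacobian: u = p_rc - prow_r * pcol_c
    J = np.eye(K)
    for rr in range(R):
        for cc2 in range(C):
            k = rr * C + cc2
            for ss in range(R):
                for tt in range(C):
                    m = ss * C + tt
                    if ss == rr:
                        J[k, m] -= pcol[cc2]
                    if tt == cc2:
                        J[k, m] -= prow[rr]
    Vu = J @ Vhat @ J.T
    A = np.diag(1.0 / np.sqrt(expected.ravel()))
    M = n * (A @ Vu @ A)
    d = (R - 1) * (C - 1)
    delta = np.sort(np.linalg.eigvalsh(M))[::-1][:d]
    delta = np.clip(delta, 1e-12, None)
    dbar = delta.mean()
    df_design = dsub.degrees_of_freedom
    if order == 1:
        stat = X2 / dbar
        p = float(scipy.stats.chi2.sf(stat, d))
        return {"statistic": stat, "df1": d, "df2": np.inf, "p": p, "X2": X2}
    # Satterthwaite: sum_k delta_k chi2_1 matched to a scaled chi2;
    # F = X2 / trace(Delta) on (d/(1+a2), d/(1+a2) * design df)
    a2 = float(delta.var() / dbar**2)
    df1 = d / (1 + a2)
    df2 = df1 * df_design
    F = X2 / (d * dbar)
    p = float(scipy.stats.f.sf(F, df1, df2))
    return {"statistic": F, "df1": df1, "df2": df2, "p": p, "X2": X2}


def design_ttest_bonferroni(
    outcome, groups, design: SurveyDesign, *, group_pairs=None, m: int | None = None
) -> pd.DataFrame:
    """Design-based pairwise t-tests of group means, Bonferroni adjusted.

    Each group mean is a domain ratio estimator; the difference variance
    is linearized jointly so the PSU-level covariance between domains is
    respected.  The raw two-sided p is multiplied by ``m`` (default: the
    number of pairs; 6 for four groups) and capped at 1.
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(groups)
    ok = ~(np.isnan(y) | pd.isna(g))
    labels = np.unique(g[ok])
    if group_pairs is None:
        group_pairs = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    if m is None:
        m = len(group_pairs)
    if m < 1:
        raise ValueError("m must be >= 1")
    df = design.degrees_of_freedom
    w = np.where(ok, design.weights, 0.0)
    rows = []
    for a, b in group_pairs:
        for lab in (a, b):
            if lab not in labels:
                raise ValueError(f"unknown group label {lab!r}")
        za, mua = _domain_mean_lin(y, g, a, w, ok)
        zb, mub = _domain_mean_lin(y, g, b, w, ok)
        diff = mua - mub
        se = float(np.sqrt(design.linearized_cov((za - zb)[:, None])[0, 0]))
        t = diff / se if se > 0 else 0.0
        praw = 2 * scipy.stats.t.sf(abs(t), df)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_a": mua,
                "mean_b": mub,
                "difference": diff,
                "se": se,
                "t": t,
                "p_raw": praw,
                "p_adjusted": min(1.0, praw * m),
            }
        )
    return pd.DataFrame(rows)


def _domain_mean_lin(y, g, label, w, ok):
    dom = ok & (g == label)
    wd = np.where(dom, w, 0.0)
    wsum = wd.sum()
    if wsum <= 0:
        raise ValueError(f"group {label!r} has no weight")
    mu = float((wd * np.where(dom, y, 0.0)).sum() / wsum)
    z = wd * (np.where(dom, y, 0.0) - mu) / wsum
    return z, mu


def _design_glm(table, outcome, exposure, covariates, design, family):
    y = table[outcome].to_numpy(dtype=float)
    X, names = _build_design_matrix(table, exposure, covariates)
    ok = ~np.isnan(y) & ~np.isnan(X).any(axis=1) & (design.weights > 0)
    y, X = y[ok], X[ok]
    dsub = design.subset(ok)
    w = dsub.weights
    if isinstance(family, sm.families.Binomial):
        if len(np.unique(y)) < 2:
            raise ValueError("outcome is constant; logistic fit undefined")
    for j, name in enumerate(names):
        if name != "intercept" and X[:, j].std() == 0:
            raise ValueError(f"term {name!r} is constant in the analysis sample")
    model = sm.GLM(y, X, family=family, freq_weights=w)
    try:
        fit = model.fit(maxiter=200, tol=1e-10)
    except Exception as exc:  # pragma: no cover - statsmodels failures
        raise ValueError(f"model failed to converge: {exc}") from exc
    beta = fit.params
    mu = fit.fittedvalues
    if isinstance(family, sm.families.Binomial):
        if np.any(mu > 1 - 1e-10) or np.any(mu < 1e-10):
            raise ValueError("separation detected: fitted probabilities at 0/1")
        irls_w = mu * (1 - mu)
    else:
        irls_w = np.ones_like(mu)
    # sandwich: B^{-1} G B^{-1} with clustered score totals
    score = (w * (y - mu))[:, None] * X
    B = (X * (w * irls_w)[:, None]).T @ X
    G = dsub.linearized_cov(score)
    Binv = np.linalg.inv(B)
    V = Binv @ G @ Binv
    se = np.sqrt(np.diag(V))
    df = dsub.degrees_of_freedom - (len(beta) - 1)
    df = max(df, 1)
    return beta, se, V, names, df, int(ok.sum()), fit


def _build_design_matrix(table, exposure, covariates):
    cols = [np.ones(len(table))]
    names = ["intercept"]
    exp_vals = table[exposure["column"]]
    levels = exposure.get("levels")
    if levels is None:
        levels = sorted(exp_vals.dropna().unique())
    ref = exposure.get("reference", levels[0])
    for lev in levels:
        if lev == ref:
            continue
        col = (exp_vals == lev).astype(float).to_numpy()
        col[exp_vals.isna().to_numpy()] = np.nan
        if np.nansum(col) == 0:
            raise ValueError(f"exposure level {lev!r} is empty")
        cols.append(col)
        names.append(f"{exposure['column']}={lev}")
    for cov in covariates:
        if isinstance(cov, str):
            cols.append(table[cov].to_numpy(dtype=float))
            names.append(cov)
        else:  # categorical covariate spec: (column, reference)
            col_name, cref = cov
            vals = table[col_name]
            for lev in sorted(vals.dropna().unique()):
                if lev == cref:
                    continue
                dummy = (vals == lev).astype(float).to_numpy()
                dummy[vals.isna().to_numpy()] = np.nan
                cols.append(dummy)
                names.append(f"{col_name}={lev}")
    return np.column_stack(cols), names


def _result_frame(beta, se, names, df, n, level, odds_ratio):
    tcrit = scipy.stats.t.ppf(0.5 + level / 2, df)
    out = pd.DataFrame(
        {
            "term": names,
            "estimate": beta,
            "se": se,
            "ci_low": beta - tcrit * se,
            "ci_high": beta + tcrit * se,
            "t": beta / se,
            "p": 2 * scipy.stats.t.sf(np.abs(beta / se), df),
        }
    )
    if odds_ratio:
        out["odds_ratio"] = np.exp(out["estimate"])
        out["or_ci_low"] = np.exp(out["ci_low"])
        out["or_ci_high"] = np.exp(out["ci_high"])
    out.attrs["df"] = df
    out.attrs["n"] = n
    return out


def weighted_logistic(
    table, outcome, exposure, covariates, design, *, level: float = 0.95
) -> pd.DataFrame:
    """Survey-weighted logistic regression with clustered sandwich SEs.

    Point estimates are pseudo-maximum-likelihood (weighted IRLS);
    variance is the linearized sandwich clustered on PSU within stratum;
    CIs use t with design df reduced by the number of non-intercept
    parameters.  ``exposure`` is a dict with keys ``column``,
    ``reference`` and optional ``levels``; reference-level respondents
    carry estimate 0 by construction and are not listed.
    """
    beta, se, V, names, df, n, _ = _design_glm(
        table, outcome, exposure, covariates, design, sm.families.Binomial()
    )
    return _result_frame(beta, se, names, df, n, level, odds_ratio=True)


def weighted_linear(
    table, outcome, exposure, covariates, design, *, level: float = 0.95
) -> pd.DataFrame:
    """Survey-weighted linear regression with clustered sandwich SEs."""
    beta, se, V, names, df, n, _ = _design_glm(
        table, outcome, exposure, covariates, design, sm.families.Gaussian()
    )
    return _result_frame(beta, se, names, df, n, level, odds_ratio=False)


def compare_models(
    table,
    spec_a: dict,
    spec_b: dict,
    design: SurveyDesign,
    *,
    reps: int = 200,
    seed: int | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Paired-bootstrap comparison of coefficients across two models.

    PSUs are resampled with replacement within strata (n_h draws per
    stratum); both models are refit on every replicate from the same
    resample, so sampling noise shared by the two fits cancels in the
    coefficient difference.  Returns, per shared term position, the
    observed difference, a percentile CI and a two-sided bootstrap p.

    Each spec dict holds ``outcome``, ``exposure``, ``covariates`` and
    an optional ``match`` mapping from this model's term names to a
    common label used for pairing terms across models (defaults to the
    exposure's severity position: 1st, 2nd, ... non-reference level).
    """

    def fit(tab, des, spec):
        kind = spec.get("kind", "linear")
        fn = weighted_linear if kind == "linear" else weighted_logistic
        res = fn(tab, spec["outcome"], spec["exposure"], spec["covariates"], des)
        keep = res[res["term"].str.startswith(spec["exposure"]["column"] + "=")]
        return keep["estimate"].to_numpy()

    base_a = fit(table, design, spec_a)
    base_b = fit(table, design, spec_b)
    if len(base_a) != len(base_b):
        raise ValueError("models expose different numbers of exposure terms")
    obs = base_a - base_b

    rng = np.random.default_rng(seed)
    strat = pd.Series(design.stratum).astype(str)
    psu = strat + "\x1f" + pd.Series(design.psu).astype(str)
    idx_by_psu = pd.Series(np.arange(design.n)).groupby(psu.values).apply(np.array)
    psu_by_stratum = {
        h: [p for p in idx_by_psu.index if p.split("\x1f")[0] == h]
        for h in strat.unique()
    }
    diffs = np.empty((reps, len(obs)))
    for r in range(reps):
        take = []
        new_psu = []
        counter = 0
        for h, psus in psu_by_stratum.items():
            draw = rng.choice(len(psus), size=len(psus), replace=True)
            for d in draw:
                rows = idx_by_psu[psus[d]]
                take.append(rows)
                new_psu.append(np.full(len(rows), counter))
                counter += 1
        rows = np.concatenate(take)
        tab_r = table.iloc[rows].reset_index(drop=True)
        des_r = SurveyDesign(
            design.stratum[rows],
            np.concatenate(new_psu),
            design.weights[rows],
            lonely_psu="center",
        )
        try:
            diffs[r] = fit(tab_r, des_r, spec_a) - fit(tab_r, des_r, spec_b)
        except ValueError:
            diffs[r] = np.nan
    valid = ~np.isnan(diffs).any(axis=1)
    diffs = diffs[valid]
    alpha = 1 - level
    lo = np.percentile(diffs, 100 * alpha / 2, axis=0)
    hi = np.percentile(diffs, 100 * (1 - alpha / 2), axis=0)
    n_b = len(diffs)
    p = np.array(
        [
            2 * min((diffs[:, k] <= 0).sum() + 1, (diffs[:, k] >= 0).sum() + 1) / (n_b + 1)
            for k in range(diffs.shape[1])
        ]
    )
    return pd.DataFrame(
        {
            "term_position": np.arange(1, len(obs) + 1),
            "difference": obs,
            "ci_low": lo,
            "ci_high": hi,
            "p": np.minimum(p, 1.0),
            "n_boot": n_b,
        }
    )
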
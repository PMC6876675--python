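"""Propensity-score matching and covariate balance diagnostics.

Three matching algorithms (nearest-neighbour with replacement, radius,
Epanechnikov kernel) produce per-household weights; balance is quantified
per covariate by the standardized bias (Rosenbaum-Rubin form) and two-sample
t-statistics, and overall by the mean absolute bias plus a probit re-fit on
the weighted sample (pseudo-R² and likelihood-ratio test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import EstimationError, ValidationError

__all__ = [
    "MatchResult",
    "BalanceReport",
    "match",
    "standardized_bias",
    "welch_t",
    "balance_report",
]

ALGORITHMS = ("nearest_neighbour", "radius", "kernel")


@dataclass
class MatchResult:
    """Weights produced by a matching algorithm.

    Treated weights are 1 (0 if dropped for lack of matches); control
    weights accumulate the per-treated allocations, so they sum to the
    number of matched treated households under every algorithm.
    """

    algorithm: str
    weights: pd.Series
    treated: pd.Series
    params: Mapping[str, object] = field(default_factory=dict)
    n_treated_matched: int = 0
    n_control_matched: int = 0
    n_treated_dropped: int = 0

    @property
    def matched(self) -> pd.Series:
        return self.weights > 0


def match(
    scores: pd.Series,
    treated: pd.Series | np.ndarray,
    algorithm: str = "radius",
    radius: float = 0.05,
    bandwidth: float = 0.06,
    k: int = 1,
) -> MatchResult:
    """Match controls to treated households on the propensity score.

    nearest_neighbour
        Each treated matched to its ``k`` nearest controls (with
        replacement); distance ties broken by lowest household index.
    radius
        All controls within ``radius`` of a treated share its unit weight
        equally; treated with no control in range are dropped with a warning.
    kernel
        Epanechnikov weights ``K((p_i - p_j)/bandwidth)`` normalized to sum
        to one per treated household.
    """
    if algorithm not in ALGORITHMS:
        raise ValidationError(f"unknown matching algorithm {algorithm!r}; choose from {ALGORITHMS}")
    s = pd.Series(scores).astype(float)
    w = pd.Series(np.asarray(treated).astype(int), index=s.index)
    t_idx = s.index[w == 1]
    c_idx = s.index[w == 0]
    if len(t_idx) == 0 or len(c_idx) == 0:
        raise ValidationError("both arms must be non-empty for matching")

    st = s.loc[t_idx].to_numpy()
    sc = s.loc[c_idx].to_numpy()
    out = pd.Series(0.0, index=s.index)
    dropped = 0

    # distances: n_treated x n_control (samples here are small; dense is fine)
    dist = np.abs(st[:, None] - sc[None, :])

    if algorithm == "nearest_neighbour":
        kk = min(k, len(c_idx))
        for i in range(len(t_idx)):
            # argsort is stable, so ties resolve to the lowest control index
            nearest = np.argsort(dist[i], kind="stable")[:kk]
            out.loc[t_idx[i]] = 1.0
            for j in nearest:
                out.loc[c_idx[j]] += 1.0 / kk
    elif algorithm == "radius":
        within = dist <= radius
        for i in range(len(t_idx)):
            m = within[i].sum()
            if m == 0:
                dropped += 1
                continue
            out.loc[t_idx[i]] = 1.0
            out.loc[c_idx[within[i]]] += 1.0 / m
    else:  # kernel
        u = dist / bandwidth
        kern = np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u**2), 0.0)
        for i in range(len(t_idx)):
            tot = kern[i].sum()
            if tot <= 0:
                dropped += 1
                continue
            out.loc[t_idx[i]] = 1.0
            out.loc[c_idx] += kern[i] / tot

    if dropped:
        warnings.warn(
            f"{algorithm}: dropped {dropped} treated household(s) with no control "
            "within range",
            UserWarning,
            stacklevel=2,
        )
    params = {"radius": radius, "bandwidth": bandwidth, "k": k, "kernel": "epanechnikov"}
    return MatchResult(
        algorithm=algorithm,
        weights=out,
        treated=w,
        params=params,
        n_treated_matched=int((out.loc[t_idx] > 0).sum()),
        n_control_matched=int((out.loc[c_idx] > 0).sum()),
        n_treated_dropped=dropped,
    )


def standardized_bias(
    mean_t: float, mean_c: float, var_t: float, var_c: float
) -> float:
    """Standardized covariate bias in percent.

    ``100 * (mean_t - mean_c) / sqrt((var_t + var_c) / 2)``.  For binary
    covariates pass ``p*(1-p)`` as the variance.
    """
    if var_t < 0 or var_c < 0:
        raise ValidationError("variances must be non-negative")
    denom = np.sqrt((var_t + var_c) / 2.0)
    if denom == 0:
        if mean_t == mean_c:
            return 0.0
        raise ValidationError("zero variance in both arms with unequal means")
    return float(100.0 * (mean_t - mean_c) / denom)


def welch_t(
    mean_t: float, mean_c: float, var_t: float, var_c: float, n_t: int, n_c: int,
    pooled: bool = False,
) -> float:
    """Two-sample t statistic from group summaries (Welch by default)."""
    if n_t < 2 or n_c < 2:
        raise ValidationError("need at least two observations per arm")
    if pooled:
        sp2 = ((n_t - 1) * var_t + (n_c - 1) * var_c) / (n_t + n_c - 2)
        se = np.sqrt(sp2 * (1.0 / n_t + 1.0 / n_c))
    else:
        se = np.sqrt(var_t / n_t + var_c / n_c)
    if se == 0:
        raise ValidationError("zero standard error in two-sample t")
    return float((mean_t - mean_c) / se)


def _weighted_moments(x: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Weighted mean, ddof-1-style variance, and effective sample size."""
    wsum = w.sum()
    mean = float((w * x).sum() / wsum)
    n_eff = float(wsum**2 / (w**2).sum())
    var = float((w * (x - mean) ** 2).sum() / wsum)
    if n_eff > 1:
        var *= n_eff / (n_eff - 1)
    return mean, var, n_eff


@dataclass
class BalanceReport:
    """Per-covariate and overall balance, raw vs weighted."""

    table: pd.DataFrame
    mean_abs_bias_before: float
    mean_abs_bias_after: float
    pseudo_r2_before: float
    pseudo_r2_after: float
    lr_chi2_before: float
    lr_p_before: float
    lr_chi2_after: float
    lr_p_after: float
    n_treated: int
    n_control: int
    n_treated_weighted: float
    n_control_weighted: float


def _weighted_probit_fit(X: pd.DataFrame, w01: np.ndarray, weights: np.ndarray):
    """Weighted probit via GLM; returns (pseudo_r2, lr_chi2, lr_p, df)."""
    exog = sm.add_constant(X.astype(float), has_constant="add")
    fam = sm.families.Binomial(link=sm.families.links.Probit())
    full = sm.GLM(w01, exog, family=fam, var_weights=weights).fit()
    null = sm.GLM(w01, np.ones((len(w01), 1)), family=fam, var_weights=weights).fit()
    llf, lln = float(full.llf), float(null.llf)
    pseudo = 1.0 - llf / lln if lln != 0 else 0.0
    lr = max(0.0, 2.0 * (llf - lln))
    df = exog.shape[1] - 1
    return pseudo, lr, float(stats.chi2.sf(lr, df)), df


def balance_report(
    covariates: pd.DataFrame,
    treated: pd.Series | np.ndarray,
    weights: pd.Series | np.ndarray,
    binary: Sequence[str] | None = None,
    pooled_t: bool = False,
    refit: bool = True,
) -> BalanceReport:
    """Quantify covariate balance before and after matching/weighting.

    ``weights`` are per-household match or IPW weights (0 = excluded).
    ``binary`` names covariates whose variance is computed as ``p(1-p)``
    (with an ``n/(n-1)`` correction); by default any two-valued 0/1 column.
    ``refit=False`` skips the probit re-fit diagnostics (pseudo-R², LR test
    reported as NaN), useful inside simulation loops.
    """
    X = covariates.astype(float)
    w01 = np.asarray(treated).astype(int)
    wt = np.asarray(weights, dtype=float)
    if (wt < 0).any():
        raise ValidationError("weights must be non-negative")
    if wt[w01 == 1].sum() == 0 or wt[w01 == 0].sum() == 0:
        raise EstimationError("weighted sample is empty in at least one arm")
    if binary is None:
        binary = [c for c in X.columns if set(np.unique(X[c])) <= {0.0, 1.0}]

    rows = []
    for col in X.columns:
        x = X[col].to_numpy()
        xt, xc = x[w01 == 1], x[w01 == 0]
        n_t, n_c = len(xt), len(xc)
        if col in binary:
            pt, pc = xt.mean(), xc.mean()
            vt = pt * (1 - pt) * n_t / (n_t - 1)
            vc = pc * (1 - pc) * n_c / (n_c - 1)
        else:
            vt, vc = xt.var(ddof=1), xc.var(ddof=1)
        mean_t, mean_c = xt.mean(), xc.mean()
        bias_before = standardized_bias(mean_t, mean_c, vt, vc)
        t_before = welch_t(mean_t, mean_c, vt, vc, n_t, n_c, pooled=pooled_t)

        wt_t, wt_c = wt[w01 == 1], wt[w01 == 0]
        mt, vt_w, ne_t = _weighted_moments(xt, wt_t)
        mc, vc_w, ne_c = _weighted_moments(xc, wt_c)
        if col in binary:
            vt_w = mt * (1 - mt) * (ne_t / (ne_t - 1) if ne_t > 1 else 1.0)
            vc_w = mc * (1 - mc) * (ne_c / (ne_c - 1) if ne_c > 1 else 1.0)
        try:
            bias_after = standardized_bias(mt, mc, vt_w, vc_w)
        except ValidationError:
            bias_after = 0.0
        try:
            t_after = welch_t(mt, mc, vt_w, vc_w, max(2, int(ne_t)), max(2, int(ne_c)),
                              pooled=pooled_t)
        except ValidationError:
            t_after = 0.0
        rows.append(
            {
                "covariate": col,
                "mean_treated": mean_t,
                "mean_control": mean_c,
                "bias_before": bias_before,
                "t_before": t_before,
                "mean_treated_weighted": mt,
                "mean_control_weighted": mc,
                "bias_after": bias_after,
                "t_after": t_after,
            }
        )
    table = pd.DataFrame(rows).set_index("covariate")

    if refit:
        ones = np.ones_like(wt)
        pr2_b, lr_b, lrp_b, _ = _weighted_probit_fit(X, w01, ones)
        mask = wt > 0
        pr2_a, lr_a, lrp_a, _ = _weighted_probit_fit(X.loc[mask], w01[mask], wt[mask])
    else:
        pr2_b = lr_b = lrp_b = pr2_a = lr_a = lrp_a = float("nan")

    return BalanceReport(
        table=table,
        mean_abs_bias_before=float(table["bias_before"].abs().mean()),
        mean_abs_bias_after=float(table["bias_after"].abs().mean()),
        pseudo_r2_before=pr2_b,
        pseudo_r2_after=pr2_a,
        lr_chi2_before=lr_b,
        lr_p_before=lrp_b,
        lr_chi2_after=lr_a,
        lr_p_after=lrp_a,
        n_treated=int((w01 == 1).sum()),
        n_control=int((w01 == 0).sum()),
        n_treated_weighted=float(wt[w01 == 1].sum()),
        n_control_weighted=float(wt[w01 == 0].sum()),
    )
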
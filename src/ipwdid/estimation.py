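"""Weighted difference-in-differences estimation with clustered inference.

The estimator regresses the outcome on {1, time, treated, treated x time,
controls} by weighted least squares, using inverse-probability-of-treatment
weights (1/p for treated, 1/(1-p) for controls) attached to both waves of
each household, and reports sandwich standard errors clustered at the
village level with a CR1 small-sample factor.  A placebo variant regresses
baseline outcomes on later treatment status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, ValidationError

__all__ = [
    "IPWWeights",
    "DIDResult",
    "ipw_weights",
    "cluster_se",
    "wls",
    "did_estimate",
    "placebo_test",
]

INTERACTION = "treated_x_post"


@dataclass(frozen=True)
class IPWWeights:
    """Inverse-probability-of-treatment weights, one per household."""

    weights: pd.Series
    treated: pd.Series
    scores: pd.Series

    def __post_init__(self):
        if (self.weights < 1).any():
            raise ValidationError("IPW weights must be >= 1 (scores inside (0,1))")


def ipw_weights(scores: pd.Series, treated: pd.Series | np.ndarray) -> IPWWeights:
    """phi = 1/p for treated households and 1/(1-p) for controls."""
    p = pd.Series(scores).astype(float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValidationError("propensity scores must lie strictly in (0,1)")
    w01 = pd.Series(np.asarray(treated).astype(int), index=p.index)
    phi = np.where(w01 == 1, 1.0 / p, 1.0 / (1.0 - p))
    return IPWWeights(weights=pd.Series(phi, index=p.index), treated=w01, scores=p)


def cluster_se(
    X: np.ndarray,
    resid: np.ndarray,
    weights: np.ndarray,
    clusters: np.ndarray,
    correction: str = "CR1",
) -> np.ndarray:
    """Cluster-robust sandwich covariance for weighted least squares.

    Scores are the weighted per-observation moments ``w_i x_i e_i`` summed
    within cluster; ``CR1`` applies ``(G/(G-1)) * ((n-1)/(n-k))``, ``CR0``
    no correction.
    """
    if correction not in ("CR0", "CR1"):
        raise ValidationError(f"unknown small-sample correction {correction!r}")
    labels = np.unique(clusters)
    G = len(labels)
    if G < 2:
        raise EstimationError("cluster-robust covariance needs at least 2 clusters")
    n, k = X.shape
    Xw = X * weights[:, None]
    bread = np.linalg.inv(X.T @ Xw)
    u = Xw * resid[:, None]
    meat = np.zeros((k, k))
    for g in labels:
        sg = u[clusters == g].sum(axis=0)
        meat += np.outer(sg, sg)
    cov = bread @ meat @ bread
    if correction == "CR1":
        cov *= (G / (G - 1)) * ((n - 1) / (n - k))
    return cov


def wls(y: np.ndarray, X: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least squares; returns (beta, residuals, weighted R²)."""
    n, k = X.shape
    Xw = X * weights[:, None]
    XtWX = X.T @ Xw
    rank = np.linalg.matrix_rank(XtWX)
    if rank < k:
        raise EstimationError(f"singular design matrix: rank {rank} < {k} columns")
    beta = np.linalg.solve(XtWX, Xw.T @ y)
    resid = y - X @ beta
    ybar = (weights * y).sum() / weights.sum()
    tss = (weights * (y - ybar) ** 2).sum()
    rss = (weights * resid**2).sum()
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return beta, resid, float(r2)


@dataclass
class DIDResult:
    """Coefficient table for one outcome with clustered inference."""

    outcome: str
    params: pd.Series
    se: pd.Series
    r2: float
    n: int
    n_clusters: int
    meta: Mapping[str, object] = field(default_factory=dict)

    @property
    def theta(self) -> float:
        """The treated-by-post interaction coefficient (the DID effect)."""
        return float(self.params[INTERACTION])

    @property
    def theta_se(self) -> float:
        return float(self.se[INTERACTION])

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.se

    @property
    def pvalues(self) -> pd.Series:
        # t reference with G-1 degrees of freedom
        df = max(self.n_clusters - 1, 1)
        return pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues), df), index=self.params.index
        )

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        df = max(self.n_clusters - 1, 1)
        q = stats.t.ppf(0.5 + level / 2.0, df)
        return pd.DataFrame(
            {"lo": self.params - q * self.se, "hi": self.params + q * self.se}
        )

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coefficient": self.params, "cluster_se": self.se,
             "t": self.tvalues, "p": self.pvalues}
        )


def _prepare_controls(
    df: pd.DataFrame, controls: Sequence[str], baseline_values: bool
) -> pd.DataFrame:
    missing = [c for c in controls if c not in df.columns]
    if missing:
        raise ValidationError(f"unknown control variables: {missing}")
    ctrl = df[list(controls)].astype(float)
    if baseline_values:
        base = df[df["wave"] == 0].set_index("household_id")[list(controls)].astype(float)
        ctrl = base.reindex(df["household_id"]).reset_index(drop=True)
        ctrl.index = df.index
    return ctrl


def did_estimate(
    df: pd.DataFrame,
    outcome: str,
    weights: pd.Series | Mapping[int, float] | None = None,
    controls: Sequence[str] = (),
    cluster: str = "village_id",
    correction: str = "CR1",
    baseline_controls: bool = True,
    normalize_weights: bool = False,
) -> DIDResult:
    """Estimate the treatment effect by weighted DID.

    ``df`` is the long two-wave panel (matched/support-retained households);
    ``weights`` maps household_id to its weight (applied to both waves;
    households with zero or missing weight are excluded).  Controls are
    replicated at their baseline values across waves by default.  With no
    controls and unit weights the interaction coefficient equals the
    four-group-means difference in differences.
    """
    if outcome not in df.columns:
        raise ValidationError(f"outcome {outcome!r} not in panel")
    if cluster not in df.columns:
        raise ValidationError(f"cluster column {cluster!r} not in panel")
    data = df.copy()
    if weights is None:
        data["_w"] = 1.0
    else:
        wmap = pd.Series(weights)
        data["_w"] = data["household_id"].map(wmap)
        data = data[data["_w"].notna() & (data["_w"] > 0)]
    if len(data) == 0:
        raise EstimationError("no observations carry positive weight")
    y = data[outcome].to_numpy(float)
    if np.all(y == y[0]):
        raise EstimationError(f"outcome {outcome!r} is constant")
    if normalize_weights:
        for arm in (0, 1):
            m = data["treated"] == arm
            data.loc[m, "_w"] *= m.sum() / data.loc[m, "_w"].sum()

    t = data["wave"].to_numpy(float)
    W = data["treated"].to_numpy(float)
    names = ["const", "post", "treated", INTERACTION]
    cols = [np.ones(len(data)), t, W, W * t]
    if controls:
        ctrl = _prepare_controls(data, controls, baseline_controls)
        for c in controls:
            names.append(c)
            cols.append(ctrl[c].to_numpy(float))
    X = np.column_stack(cols)
    wvec = data["_w"].to_numpy(float)

    beta, resid, r2 = wls(y, X, wvec)
    cov = cluster_se(X, resid, wvec, data[cluster].to_numpy(), correction=correction)
    se = np.sqrt(np.diag(cov))
    if not np.isfinite(se).all():
        raise EstimationError("non-finite standard error encountered")
    # zero SEs can arise in exactly-fitting or few-cluster toy designs

    return DIDResult(
        outcome=outcome,
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        r2=r2,
        n=len(data),
        n_clusters=int(data[cluster].nunique()),
        meta={
            "controls": list(controls),
            "weighted": weights is not None,
            "correction": correction,
            "baseline_controls": baseline_controls,
        },
    )


def placebo_test(
    df: pd.DataFrame,
    outcome: str,
    weights: pd.Series | Mapping[int, float] | None = None,
    controls: Sequence[str] = (),
    cluster: str = "village_id",
    correction: str = "CR1",
) -> DIDResult:
    """Cross-sectional regression of the baseline outcome on endline
    participation.

    A coefficient near zero supports the claim that participants were not
    already better off before the intervention.
    """
    base = df[df["wave"] == 0].copy()
    if len(base) == 0:
        raise ValidationError("panel has no baseline wave")
    if outcome not in base.columns:
        raise ValidationError(f"outcome {outcome!r} not in panel")
    if weights is None:
        base["_w"] = 1.0
    else:
        base["_w"] = base["household_id"].map(pd.Series(weights))
        base = base[base["_w"].notna() & (base["_w"] > 0)]
    y = base[outcome].to_numpy(float)
    if len(base) == 0 or np.all(y == y[0]):
        raise EstimationError(f"placebo outcome {outcome!r} constant or empty")

    names = ["const", "treated"]
    cols = [np.ones(len(base)), base["treated"].to_numpy(float)]
    for c in controls:
        if c not in base.columns:
            raise ValidationError(f"unknown control variable {c!r}")
        names.append(c)
        cols.append(base[c].to_numpy(float))
    X = np.column_stack(cols)
    wvec = base["_w"].to_numpy(float)
    beta, resid, r2 = wls(y, X, wvec)
    cov = cluster_se(X, resid, wvec, base[cluster].to_numpy(), correction=correction)
    se = np.sqrt(np.diag(cov))
    return DIDResult(
        outcome=outcome,
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        r2=r2,
        n=len(base),
        n_clusters=int(base[cluster].nunique()),
        meta={"placebo": True, "controls": list(controls)},
    )
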
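"""Participation model: probit MLE, marginal effects, common support.

The probit fit is delegated to statsmodels behind this module's contract:
binary response checks, constant-covariate and perfect-separation
diagnostics that name the offending column, an explicit gradient tolerance
on the solution, HC1 robust covariance, and McFadden pseudo-R².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import ConvergenceError, DisjointSupportError, SeparationError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PropensityFit",
    "SupportRegion",
    "design_matrix",
    "fit_probit",
    "marginal_effects",
    "common_support",
]

GRADIENT_TOL = 1e-6
SCORE_CLAMP = 1e-6


@dataclass
class PropensityFit:
    """Fitted probit participation model."""

    params: pd.Series              # coefficients incl. "const"
    cov_robust: pd.DataFrame       # HC1 sandwich covariance
    bse: pd.Series
    scores: pd.Series              # fitted P(W=1|z), clamped to (0,1)
    llf: float
    llnull: float
    exog: pd.DataFrame             # design incl. constant, row-aligned to scores
    endog: pd.Series

    @property
    def pseudo_r2(self) -> float:
        """McFadden likelihood-ratio index, 1 - llf/llnull."""
        if self.llnull == 0:
            return 0.0
        return 1.0 - self.llf / self.llnull

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * norm.sf(np.abs(self.zvalues)), index=self.params.index)

    def table(self, ame_method: str = "derivative") -> pd.DataFrame:
        """Coefficient table: coefficient, robust SE, marginal effect, z, p."""
        ame = marginal_effects(self, method=ame_method)
        tab = pd.DataFrame(
            {
                "coefficient": self.params,
                "robust_se": self.bse,
                "marginal_effect": ame.reindex(self.params.index),
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )
        return tab


def design_matrix(
    covariates: pd.DataFrame,
    log_vars: Sequence[str] = (),
    add_const: bool = True,
) -> pd.DataFrame:
    """Assemble the probit design, log-transforming the named columns.

    Logged columns are renamed ``log_<name>``; values must be positive.
    """
    X = covariates.copy().astype(float)
    for name in log_vars:
        if name not in X.columns:
            raise ValidationError(f"log-transform requested for unknown covariate {name!r}")
        if (X[name] <= 0).any():
            raise ValidationError(f"covariate {name!r} must be positive to log-transform")
        X[f"log_{name}"] = np.log(X[name])
        X = X.drop(columns=[name])
    if add_const:
        X = sm.add_constant(X, has_constant="add")
    return X


def _find_separating_covariate(X: pd.DataFrame, w: np.ndarray) -> str | None:
    """Look for a single covariate whose ranges split the two arms."""
    for col in X.columns:
        if col == "const":
            continue
        xt, xc = X[col].to_numpy()[w == 1], X[col].to_numpy()[w == 0]
        if xt.min() > xc.max() or xt.max() < xc.min():
            return col
    return None


def fit_probit(
    covariates: pd.DataFrame,
    treated: pd.Series | np.ndarray,
    log_vars: Sequence[str] = (),
    maxiter: int = 100,
) -> PropensityFit:
    """Probit MLE of treatment on pre-treatment covariates.

    Raises :class:`SeparationError` on perfect separation (naming the
    separating covariate when one column alone separates) and
    :class:`ConvergenceError` when the gradient max-norm at the solution
    exceeds ``1e-6``.
    """
    w = np.asarray(treated, dtype=float)
    if not np.isin(w, (0, 1)).all():
        raise ValidationError("treatment indicator must be binary 0/1")
    if w.min() == w.max():
        raise ValidationError("treatment indicator is constant; both arms required")
    X = design_matrix(covariates, log_vars=log_vars)
    constant_cols = [c for c in X.columns if c != "const" and X[c].nunique() <= 1]
    if constant_cols:
        raise ValidationError(f"constant covariates in probit design: {constant_cols}")

    model = sm.Probit(w, X)
    import warnings as _warnings

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(
                method="newton",
                maxiter=maxiter,
                disp=0,
                start_params=np.zeros(X.shape[1]),
                cov_type="HC1",
            )
    except (PerfectSeparationError, PerfectSeparationWarning):
        raise SeparationError(_find_separating_covariate(X, w)) from None
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(f"probit Hessian singular: {exc}") from None

    grad = model.score(res.params)
    if not np.all(np.isfinite(res.params)) or np.max(np.abs(grad)) > GRADIENT_TOL * max(1.0, len(w)):
        # retry with BFGS before giving up
        res = model.fit(method="bfgs", maxiter=500, disp=0, cov_type="HC1")
        grad = model.score(res.params)
        if np.max(np.abs(grad)) > GRADIENT_TOL * max(1.0, len(w)):
            raise ConvergenceError(
                f"probit did not converge: gradient max-norm {np.max(np.abs(grad)):.3e}, "
                f"iterations {res.mle_retvals}"
            )

    raw = np.asarray(res.predict(X))
    clamped = np.clip(raw, SCORE_CLAMP, 1 - SCORE_CLAMP)
    n_clamped = int((raw != clamped).sum())
    if n_clamped:
        logger.info("clamped %d propensity scores into (%.0e, 1-%.0e)", n_clamped, SCORE_CLAMP, SCORE_CLAMP)

    params = pd.Series(res.params, index=X.columns)
    return PropensityFit(
        params=params,
        cov_robust=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        bse=pd.Series(res.bse, index=X.columns),
        scores=pd.Series(clamped, index=X.index),
        llf=float(res.llf),
        llnull=float(res.llnull),
        exog=X,
        endog=pd.Series(w, index=X.index),
    )


def marginal_effects(fit: PropensityFit, method: str = "derivative") -> pd.Series:
    """Average marginal effects per covariate.

    ``"derivative"`` (default) applies the density formula
    ``mean(phi(z'b)) * b_k`` to every covariate, binary ones included, so
    the ratio AME/coefficient is a common factor.  ``"discrete"`` switches
    binary covariates (detected as two-valued 0/1 columns) to the average
    discrete change ``Phi(z'b | x=1) - Phi(z'b | x=0)``.
    """
    if method not in ("derivative", "discrete"):
        raise ValidationError(f"unknown marginal-effects method {method!r}")
    X = fit.exog
    xb = X.to_numpy() @ fit.params.to_numpy()
    dens = norm.pdf(xb).mean()
    cols = [c for c in X.columns if c != "const"]
    ame = pd.Series({c: dens * fit.params[c] for c in cols})
    if method == "discrete":
        for c in cols:
            vals = set(np.unique(X[c]))
            if vals <= {0.0, 1.0}:
                X1, X0 = X.copy(), X.copy()
                X1[c], X0[c] = 1.0, 0.0
                p1 = norm.cdf(X1.to_numpy() @ fit.params.to_numpy())
                p0 = norm.cdf(X0.to_numpy() @ fit.params.to_numpy())
                ame[c] = float(np.mean(p1 - p0))
    return ame


@dataclass
class SupportRegion:
    """Common-support interval with per-household retention flags."""

    lo: float
    hi: float
    kept: pd.Series            # boolean, aligned to the score index
    n_trimmed_treated: int
    n_trimmed_control: int
    convention: str


def common_support(
    scores: pd.Series,
    treated: pd.Series | np.ndarray,
    convention: str = "intersection",
) -> SupportRegion:
    """Determine the overlap region of the two score distributions.

    ``"intersection"`` uses [max of minima, min of maxima] and trims both
    arms outside it.  ``"treated_preserving"`` keeps every treated household
    and trims only controls outside the treated score range.
    """
    w = np.asarray(treated).astype(int)
    s = np.asarray(scores, dtype=float)
    if (w == 1).sum() == 0 or (w == 0).sum() == 0:
        raise ValidationError("both arms must be non-empty for common support")
    st, sc = s[w == 1], s[w == 0]
    if convention == "intersection":
        lo, hi = max(st.min(), sc.min()), min(st.max(), sc.max())
    elif convention == "treated_preserving":
        lo, hi = st.min(), st.max()
    else:
        raise ValidationError(f"unknown support convention {convention!r}")
    if lo > hi:
        raise DisjointSupportError(
            f"treated scores span [{st.min():.3f}, {st.max():.3f}] and control "
            f"[{sc.min():.3f}, {sc.max():.3f}]; no overlap"
        )
    kept = (s >= lo) & (s <= hi)
    if convention == "treated_preserving":
        kept = kept | (w == 1)
    kept_s = pd.Series(kept, index=scores.index)
    return SupportRegion(
        lo=float(lo),
        hi=float(hi),
        kept=kept_s,
        n_trimmed_treated=int(((~kept) & (w == 1)).sum()),
        n_trimmed_control=int(((~kept) & (w == 0)).sum()),
        convention=convention,
    )
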
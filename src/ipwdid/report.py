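"""End-to-end pipeline: simulate/load -> indicators -> propensity -> match ->
estimate -> placebo, with all tables written as CSV plus a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .estimation import did_estimate, ipw_weights, placebo_test
from .indicators import build_indicators, default_food_group_map
from .matching import ALGORITHMS, balance_report, match
from .propensity import common_support, fit_probit
from .synthdata import DGPConfig, default_config, generate_panel, read_panel

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "support_histogram"]


@dataclass
class RunConfig:
    """One fully-specified pipeline run.

    Exactly one of ``panel_path`` (a panel CSV) or ``dgp`` (a synthetic
    configuration) must be given.  ``covariates`` drives the probit;
    ``log_vars`` are log-transformed first.  ``outcomes`` names panel or
    indicator columns to estimate effects for.
    """

    covariates: Sequence[str]
    outcomes: Sequence[str]
    panel_path: str | None = None
    dgp: DGPConfig | None = None
    log_vars: Sequence[str] = ()
    algorithm: str = "radius"
    algorithm_params: Mapping[str, float] = field(default_factory=dict)
    support_convention: str = "intersection"
    use_ipw: bool = True
    controls: Sequence[str] | None = None  # default: same as covariates (logged)
    placebo_outcomes: Sequence[str] | None = None
    out_dir: str = "runs/latest"
    seed: int = 0

    def __post_init__(self):
        if (self.panel_path is None) == (self.dgp is None):
            raise ValidationError("exactly one of panel_path or dgp must be set")
        if self.algorithm not in ALGORITHMS:
            raise ValidationError(
                f"unknown matching algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        dgp = None
        if raw.get("dgp") == "default":
            dgp = default_config(seed=int(raw.get("seed", 0)))
        elif isinstance(raw.get("dgp"), dict):
            dgp = default_config(seed=int(raw.get("seed", 0)), **raw["dgp"])
        return cls(
            covariates=raw["covariates"],
            outcomes=raw["outcomes"],
            panel_path=raw.get("panel_path"),
            dgp=dgp,
            log_vars=raw.get("log_vars", ()),
            algorithm=raw.get("algorithm", "radius"),
            algorithm_params=raw.get("algorithm_params", {}),
            support_convention=raw.get("support_convention", "intersection"),
            use_ipw=raw.get("use_ipw", True),
            controls=raw.get("controls"),
            placebo_outcomes=raw.get("placebo_outcomes"),
            out_dir=raw.get("out_dir", "runs/latest"),
            seed=int(raw.get("seed", 0)),
        )


def support_histogram(
    scores: pd.Series,
    treated: pd.Series | np.ndarray,
    bins: int = 20,
    weights: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Binned propensity-score counts per arm, raw and weighted.

    Raw counts sum to the arm sizes; weighted counts sum to the total
    weight per arm.
    """
    if bins < 2:
        raise ValidationError("need at least 2 bins")
    w01 = np.asarray(treated).astype(int)
    s = np.asarray(scores, dtype=float)
    if (w01 == 1).sum() == 0 or (w01 == 0).sum() == 0:
        raise ValidationError("both arms must be non-empty")
    edges = np.histogram_bin_edges(s, bins=bins)
    rows = {"bin_left": edges[:-1], "bin_right": edges[1:]}
    wt = np.ones_like(s) if weights is None else np.asarray(weights, dtype=float)
    for arm, label in ((1, "treated"), (0, "control")):
        m = w01 == arm
        rows[f"count_{label}"], _ = np.histogram(s[m], bins=edges)
        rows[f"weighted_{label}"], _ = np.histogram(s[m], bins=edges, weights=wt[m])
    return pd.DataFrame(rows)


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write the artifact set to ``config.out_dir``.

    Artifacts: ``panel.csv``, ``indicators.csv``, ``propensity.csv``,
    ``balance.csv``, ``balance_summary.csv``, ``effects.csv``,
    ``placebo.csv``, ``support_hist.csv`` and ``manifest.json``.
    Deterministic given the config (including its seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }

    # stage 1: data
    if config.dgp is not None:
        panel = generate_panel(config.dgp)
        logger.info("simulated panel: %d households", panel.n_households)
    else:
        panel = read_panel(config.panel_path)
    from .synthdata import write_panel

    write_panel(panel, out / "panel.csv")
    manifest["stages"]["data"] = {
        "n_households": panel.n_households,
        "treated_share": float(panel.baseline()["treated"].mean()),
    }

    # stage 2: indicators
    indicators = build_indicators(panel, default_food_group_map())
    indicators.to_csv(out / "indicators.csv", index=False)
    # panel columns win name clashes (a DGP outcome may share an indicator name)
    df = panel.df.merge(
        indicators, on=["household_id", "wave"], how="left", suffixes=("", "_indicator")
    )
    manifest["stages"]["indicators"] = {"columns": list(indicators.columns)}

    # stage 3: propensity (baseline covariates only)
    base = df[df["wave"] == 0].set_index("household_id")
    missing = [c for c in config.covariates if c not in base.columns]
    if missing:
        raise ValidationError(f"covariates not in panel: {missing}")
    fit = fit_probit(base[list(config.covariates)], base["treated"], log_vars=config.log_vars)
    fit.table().to_csv(out / "propensity.csv")
    support = common_support(fit.scores, base["treated"], convention=config.support_convention)
    manifest["stages"]["propensity"] = {
        "pseudo_r2": fit.pseudo_r2,
        "support": [support.lo, support.hi],
        "n_trimmed_treated": support.n_trimmed_treated,
        "n_trimmed_control": support.n_trimmed_control,
    }

    kept = support.kept[support.kept].index
    scores = fit.scores.loc[kept]
    treated = base.loc[kept, "treated"]

    # stage 4: matching + balance
    mres = match(scores, treated, algorithm=config.algorithm, **dict(config.algorithm_params))
    ipw = ipw_weights(scores, treated)
    est_weights = ipw.weights if config.use_ipw else pd.Series(1.0, index=kept)
    # restrict estimation to the matched sample for NN/radius/kernel diagnostics
    breport = balance_report(fit.exog.loc[kept].drop(columns="const"), treated, mres.weights)
    breport.table.to_csv(out / "balance.csv")
    pd.DataFrame(
        [
            {
                "algorithm": config.algorithm,
                "pseudo_r2_before": breport.pseudo_r2_before,
                "pseudo_r2_after": breport.pseudo_r2_after,
                "lr_chi2_before": breport.lr_chi2_before,
                "lr_p_before": breport.lr_p_before,
                "lr_chi2_after": breport.lr_chi2_after,
                "lr_p_after": breport.lr_p_after,
                "mean_bias_before": breport.mean_abs_bias_before,
                "mean_bias_after": breport.mean_abs_bias_after,
                "n_treated": breport.n_treated,
                "n_control": breport.n_control,
            }
        ]
    ).to_csv(out / "balance_summary.csv", index=False)
    manifest["stages"]["matching"] = {
        "algorithm": config.algorithm,
        "n_treated_matched": mres.n_treated_matched,
        "n_control_matched": mres.n_control_matched,
        "n_treated_dropped": mres.n_treated_dropped,
    }

    support_histogram(scores, treated, bins=20, weights=est_weights).to_csv(
        out / "support_hist.csv", index=False
    )

    # stage 5: estimation on the support-retained sample with IPW weights
    controls = (
        list(config.controls) if config.controls is not None else list(config.covariates)
    )
    est_df = df[df["household_id"].isin(kept)].copy()
    for name in config.log_vars:
        if name in est_df.columns and name in controls:
            est_df[f"log_{name}"] = np.log(est_df[name].astype(float))
            controls[controls.index(name)] = f"log_{name}"
    rows = []
    for outcome in config.outcomes:
        if outcome not in est_df.columns:
            raise ValidationError(f"outcome {outcome!r} not found in panel or indicators")
        res = did_estimate(est_df, outcome, weights=est_weights, controls=controls)
        rows.append(
            {
                "outcome": outcome,
                "theta": res.theta,
                "cluster_se": res.theta_se,
                "t": res.theta / res.theta_se,
                "p": float(res.pvalues["treated_x_post"]),
                "r2": res.r2,
                "n": res.n,
                "n_clusters": res.n_clusters,
            }
        )
    effects = pd.DataFrame(rows)
    effects.to_csv(out / "effects.csv", index=False)
    manifest["stages"]["estimation"] = {"n_outcomes": len(rows)}

    # stage 6: placebo on baseline outcomes
    placebo_outcomes = (
        list(config.placebo_outcomes)
        if config.placebo_outcomes is not None
        else list(config.outcomes)
    )
    prows = []
    for outcome in placebo_outcomes:
        res = placebo_test(est_df, outcome, weights=est_weights, controls=controls)
        prows.append(
            {
                "outcome": outcome,
                "coefficient": float(res.params["treated"]),
                "cluster_se": float(res.se["treated"]),
                "r2": res.r2,
                "n": res.n,
            }
        )
    pd.DataFrame(prows).to_csv(out / "placebo.csv", index=False)
    manifest["stages"]["placebo"] = {"n_outcomes": len(prows)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
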
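"""Synthetic two-wave household panels with selection on observables.

The generator mimics the structure the estimators downstream assume: a
balanced two-wave panel of households clustered in villages, a latent-index
probit selection rule on pre-treatment covariates, outcome equations with a
common time effect, a treated-level term, a treatment-by-time interaction
(the quantity of interest), village random intercepts and idiosyncratic
noise, plus raw instrument responses (exam items, 24-hour recall, 7-day
frequencies, month calendars) consistent with the latent outcome structure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import DegenerateSelectionError, ValidationError

__all__ = [
    "CovariateSpec",
    "OutcomeSpec",
    "ExamSpec",
    "DGPConfig",
    "PanelDataset",
    "default_config",
    "generate_panel",
    "write_panel",
    "read_panel",
]

N_CATEGORIES = 12  # survey food categories (24h recall and 7-day frequency)
N_MONTHS = 12


@dataclass(frozen=True)
class CovariateSpec:
    """One pre-treatment covariate.

    ``kind`` is ``"binary"`` (Bernoulli at ``p``) or ``"continuous"``
    (lognormal with the stated mean and SD of the *level*).  When
    ``selection_on_log`` is set, the selection equation and outcome
    equations use the natural log of the covariate.
    """

    name: str
    kind: str
    p: float | None = None
    mean: float | None = None
    sd: float | None = None
    selection_on_log: bool = False

    def __post_init__(self):
        if self.kind not in ("binary", "continuous"):
            raise ValidationError(f"covariate {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "binary":
            if self.p is None or not 0 < self.p < 1:
                raise ValidationError(f"covariate {self.name!r}: p must be in (0,1)")
        else:
            if self.mean is None or self.sd is None or self.mean <= 0 or self.sd <= 0:
                raise ValidationError(
                    f"covariate {self.name!r}: continuous needs positive mean and sd"
                )


@dataclass(frozen=True)
class OutcomeSpec:
    """Generating equation for one continuous outcome.

    mean(y_it) = baseline + time_effect*t + effect*W*t + treated_level*W
                 + sum_k covariate_effects[k] * x_k
    plus a village random intercept and Gaussian noise.
    """

    baseline: float = 0.0
    time_effect: float = 0.0
    effect: float = 0.0
    treated_level: float = 0.0
    covariate_effects: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ExamSpec:
    """One-parameter item-response model for the knowledge exam.

    Each item has a difficulty in (0,1): the probability that a household of
    zero ability answers it correctly.  A household answers item q correctly
    with probability ``expit(logit(difficulty_q) + ability_it)`` where
    ``ability_it = ability_i + treatment_shift * W_i * t``.
    """

    difficulties: tuple[float, ...]
    ability_sd: float = 1.0
    treatment_shift: float = 0.0
    n_production_items: int | None = None

    def __post_init__(self):
        if not self.difficulties:
            raise ValidationError("exam needs at least one item")
        if any(not 0 < d < 1 for d in self.difficulties):
            raise ValidationError("item difficulties must lie in (0,1)")
        k = self.n_production_items
        if k is not None and not 0 <= k <= len(self.difficulties):
            raise ValidationError("n_production_items out of range")


@dataclass(frozen=True)
class DGPConfig:
    """Full data-generating configuration.

    ``selection`` maps covariate names (plus ``"const"``) to latent-index
    coefficients; treatment is assigned where the index plus standard-normal
    noise is positive.  ``outcomes`` maps outcome names to their generating
    equations; the interaction coefficients there are the ground-truth
    effects recovery tests target.
    """

    n_households: int = 434
    n_villages: int = 30
    covariates: tuple[CovariateSpec, ...] = ()
    selection: Mapping[str, float] = field(default_factory=dict)
    outcomes: Mapping[str, OutcomeSpec] = field(default_factory=dict)
    exam: ExamSpec = field(default_factory=lambda: ExamSpec(difficulties=(0.5,)))
    village_sd: float = 0.0
    noise_sd: float = 1.0
    recall_base: tuple[float, ...] = (0.9, 0.5, 0.3, 0.5, 0.25, 0.3, 0.05, 0.35, 0.15, 0.55, 0.2, 0.6)
    recall_effect: float = 0.0  # logit shift on each category for W*t
    freq_base: tuple[float, ...] = (0.9, 0.5, 0.3, 0.4, 0.2, 0.25, 0.03, 0.3, 0.1, 0.5, 0.15, 0.6)
    freq_effect: float = 0.0
    month_low_rate: float = 0.15
    month_relief_rate: float = 0.05
    month_effect: float = 0.0  # logit shift (per month) for W*t; negative = improvement
    sold_asset_rate: float = 0.55
    strategies_rate: float = 3.5
    seed: int = 0

    def __post_init__(self):
        if self.n_households < 2:
            raise ValidationError("need at least 2 households")
        if self.n_villages < 2:
            raise ValidationError("need at least 2 villages")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ValidationError("covariate names must be unique")
        for key in self.selection:
            if key != "const" and key not in names:
                raise ValidationError(f"selection references unknown covariate {key!r}")
        for out, spec in self.outcomes.items():
            for key in spec.covariate_effects:
                if key not in names:
                    raise ValidationError(
                        f"outcome {out!r} references unknown covariate {key!r}"
                    )
        for name, probs in (("recall_base", self.recall_base), ("freq_base", self.freq_base)):
            if len(probs) != N_CATEGORIES:
                raise ValidationError(f"{name} must have {N_CATEGORIES} entries")
            if any(not 0 < p < 1 for p in probs):
                raise ValidationError(f"{name} entries must lie in (0,1)")
        for name, p in (("month_low_rate", self.month_low_rate),
                        ("month_relief_rate", self.month_relief_rate),
                        ("sold_asset_rate", self.sold_asset_rate)):
            if not 0 < p < 1:
                raise ValidationError(f"{name} must lie in (0,1)")

    @property
    def true_effects(self) -> dict[str, float]:
        return {name: spec.effect for name, spec in self.outcomes.items()}

    @property
    def covariate_names(self) -> list[str]:
        return [c.name for c in self.covariates]


def default_config(seed: int = 0, **overrides) -> DGPConfig:
    """A 434-household, 30-village configuration with confounded selection.

    Binary covariate rates and continuous scales follow the pooled baseline
    summary statistics of the motivating survey; selection coefficients give
    female-headed, younger, better-educated households in the focal region a
    higher participation probability, and the same covariates enter the
    outcome levels so that naive cross-sectional contrasts are confounded.
    """
    covariates = (
        CovariateSpec("male_head", "binary", p=0.78),
        CovariateSpec("age_head", "continuous", mean=47.0, sd=12.0, selection_on_log=True),
        CovariateSpec("farming", "binary", p=0.95),
        CovariateSpec("casual_labour", "binary", p=0.25),
        CovariateSpec("educ_share", "binary", p=0.08),
        CovariateSpec("valley_bottom", "binary", p=0.70),
        CovariateSpec("cassava_disease", "binary", p=0.41),
        CovariateSpec("land_ha", "continuous", mean=2.7, sd=2.0),
        CovariateSpec("assets_usd", "continuous", mean=29.5, sd=25.0, selection_on_log=True),
        CovariateSpec("mwanza", "binary", p=0.61),
    )
    selection = {
        "const": 1.35,
        "male_head": -0.46,
        "age_head": -0.46,
        "farming": 0.02,
        "casual_labour": -0.10,
        "educ_share": 0.88,
        "valley_bottom": 0.25,
        "cassava_disease": 0.08,
        "land_ha": 0.015,
        "assets_usd": 0.015,
        "mwanza": 0.64,
    }
    outcomes = {
        "adoption": OutcomeSpec(
            baseline=0.03, time_effect=0.05, effect=0.74, treated_level=0.15,
            covariate_effects={"mwanza": 0.05, "educ_share": 0.10},
        ),
        "knowledge": OutcomeSpec(
            baseline=16.0, time_effect=0.0, effect=2.15, treated_level=1.5,
            covariate_effects={"educ_share": 3.0, "mwanza": 1.0, "male_head": 0.8},
        ),
        "hdds_latent": OutcomeSpec(
            baseline=4.4, time_effect=-1.2, effect=0.17, treated_level=0.15,
            covariate_effects={"assets_usd": 0.3, "mwanza": 0.2},
        ),
        "relief_months": OutcomeSpec(
            baseline=0.6, time_effect=-0.16, effect=-0.21, treated_level=0.30,
            covariate_effects={"casual_labour": 0.2, "valley_bottom": -0.1},
        ),
    }
    exam = ExamSpec(
        difficulties=(0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.85, 0.65, 0.45, 0.3, 0.2, 0.1),
        ability_sd=1.0,
        treatment_shift=0.5,
        n_production_items=6,
    )
    base = dict(
        n_households=434,
        n_villages=30,
        covariates=covariates,
        selection=selection,
        outcomes=outcomes,
        exam=exam,
        village_sd=0.3,
        noise_sd=1.0,
        recall_effect=0.1,
        freq_effect=0.1,
        month_effect=-0.2,
        seed=seed,
    )
    base.update(overrides)
    return DGPConfig(**base)


# ---------------------------------------------------------------------------
# panel container and I/O
# ---------------------------------------------------------------------------

@dataclass
class PanelDataset:
    """Balanced two-wave household panel.

    ``df`` holds one row per household x wave in the canonical column order;
    ``covariate_kinds`` records which covariates are binary vs continuous so
    downstream stages can choose transforms and variance formulas.
    """

    df: pd.DataFrame
    covariate_kinds: dict[str, str]
    outcome_names: list[str]
    n_exam_items: int

    REQUIRED = ("household_id", "village_id", "wave", "treated")

    def validate(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"panel missing required columns: {missing}")
        waves = set(self.df["wave"].unique())
        if waves != {0, 1}:
            raise ValidationError(f"panel must contain exactly waves {{0,1}}, got {sorted(waves)}")
        counts = self.df.groupby("household_id")["wave"].agg(["count", "nunique"])
        bad = counts[(counts["count"] != 2) | (counts["nunique"] != 2)]
        if len(bad):
            raise ValidationError(
                f"panel not balanced: {len(bad)} households lack exactly one row per wave"
            )
        tvar = self.df.groupby("household_id")["treated"].nunique()
        if (tvar > 1).any():
            raise ValidationError(
                f"treatment not constant within household for "
                f"{int((tvar > 1).sum())} households"
            )

    @property
    def n_households(self) -> int:
        return self.df["household_id"].nunique()

    def wave(self, t: int) -> pd.DataFrame:
        return self.df[self.df["wave"] == t]

    def baseline(self) -> pd.DataFrame:
        return self.wave(0)

    def endline(self) -> pd.DataFrame:
        return self.wave(1)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PanelDataset):
            return NotImplemented
        return (
            self.covariate_kinds == other.covariate_kinds
            and self.outcome_names == other.outcome_names
            and self.n_exam_items == other.n_exam_items
            and self.df.shape == other.df.shape
            and list(self.df.columns) == list(other.df.columns)
            and self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))
        )


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying normal (mu, sigma) for a lognormal with given level moments."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def generate_panel(config: DGPConfig) -> PanelDataset:
    """Draw a balanced two-wave panel from the configured DGP."""
    n = config.n_households
    rngs = _spawn(config.seed, 10)
    (r_cov, r_village, r_select, r_veff, r_out, r_exam, r_recall, r_freq,
     r_month, r_misc) = rngs

    # covariates (time-invariant)
    cov = {}
    for spec in config.covariates:
        if spec.kind == "binary":
            cov[spec.name] = (r_cov.random(n) < spec.p).astype(float)
        else:
            mu, sig = _lognormal_params(spec.mean, spec.sd)
            cov[spec.name] = np.exp(r_cov.normal(mu, sig, n))
    cov_df = pd.DataFrame(cov)

    def transformed(name: str) -> np.ndarray:
        spec = next(c for c in config.covariates if c.name == name)
        x = cov_df[name].to_numpy()
        return np.log(x) if spec.selection_on_log else x

    # selection: W = 1{ const + beta'z + e > 0 }, e ~ N(0,1)
    index = np.full(n, config.selection.get("const", 0.0))
    for name, beta in config.selection.items():
        if name == "const":
            continue
        index += beta * transformed(name)
    treated = (index + r_select.standard_normal(n) > 0).astype(int)
    share = treated.mean()
    if share in (0.0, 1.0):
        raise DegenerateSelectionError(float(share))

    village = r_village.integers(0, config.n_villages, n)

    # outcomes per Eq-style mean + village intercept + noise
    wave = np.tile([0, 1], n)
    hh = np.repeat(np.arange(n), 2)
    W = treated[hh]
    t = wave
    out_cols = {}
    for name, spec in config.outcomes.items():
        mean = (
            spec.baseline
            + spec.time_effect * t
            + spec.effect * W * t
            + spec.treated_level * W
        )
        for cname, gamma in spec.covariate_effects.items():
            mean = mean + gamma * transformed(cname)[hh]
        u = r_veff.normal(0.0, config.village_sd, config.n_villages) if config.village_sd > 0 else np.zeros(config.n_villages)
        eps = r_out.normal(0.0, config.noise_sd, 2 * n) if config.noise_sd > 0 else 0.0
        out_cols[name] = mean + u[village[hh]] + eps

    # exam responses: 1PL item-response draws per wave
    K = len(config.exam.difficulties)
    ability = r_exam.normal(0.0, config.exam.ability_sd, n)
    ability_it = ability[hh] + config.exam.treatment_shift * W * t
    d = logit(np.asarray(config.exam.difficulties))
    p_correct = expit(d[None, :] + ability_it[:, None])
    exam = (r_exam.random((2 * n, K)) < p_correct).astype(int)

    # 24-hour recall indicators
    rb = logit(np.asarray(config.recall_base))
    p_recall = expit(rb[None, :] + config.recall_effect * (W * t)[:, None])
    recall = (r_recall.random((2 * n, N_CATEGORIES)) < p_recall).astype(int)

    # 7-day frequencies: binomial(7, p) day counts per category
    fb = logit(np.asarray(config.freq_base))
    p_freq = expit(fb[None, :] + config.freq_effect * (W * t)[:, None])
    freq = r_freq.binomial(7, p_freq)

    # month calendars
    p_low = expit(logit(config.month_low_rate) + config.month_effect * (W * t))
    months_low = (r_month.random((2 * n, N_MONTHS)) < p_low[:, None]).astype(int)
    p_rel = expit(logit(config.month_relief_rate) + config.month_effect * (W * t))
    months_rel = (r_month.random((2 * n, N_MONTHS)) < p_rel[:, None]).astype(int)

    sold = (r_misc.random(2 * n) < config.sold_asset_rate).astype(int)
    strategies = r_misc.poisson(config.strategies_rate, 2 * n)

    data = {
        "household_id": hh,
        "village_id": village[hh],
        "wave": wave,
        "treated": W,
    }
    for name in cov_df.columns:
        data[name] = cov_df[name].to_numpy()[hh]
    for q in range(K):
        data[f"exam_q{q + 1:02d}"] = exam[:, q]
    for g in range(N_CATEGORIES):
        data[f"recall_g{g + 1:02d}"] = recall[:, g]
    for g in range(N_CATEGORIES):
        data[f"freq_f{g + 1:02d}"] = freq[:, g]
    for m in range(N_MONTHS):
        data[f"month_low_{m + 1:02d}"] = months_low[:, m]
    for m in range(N_MONTHS):
        data[f"month_relief_{m + 1:02d}"] = months_rel[:, m]
    data["sold_asset"] = sold
    data["strategies_count"] = strategies
    for name, vals in out_cols.items():
        data[name] = vals

    panel = PanelDataset(
        df=pd.DataFrame(data),
        covariate_kinds={c.name: c.kind for c in config.covariates},
        outcome_names=list(config.outcomes),
        n_exam_items=K,
    )
    panel.validate()
    return panel


def write_panel(panel: PanelDataset, path: str | Path) -> Path:
    """Write the panel CSV plus a sidecar metadata file (``<path>.meta.json``)."""
    panel.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g guarantees binary round-trip for float64 columns
    panel.df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "covariate_kinds": panel.covariate_kinds,
        "outcome_names": panel.outcome_names,
        "n_exam_items": panel.n_exam_items,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))
    return path


def read_panel(path: str | Path) -> PanelDataset:
    """Read a panel CSV written by :func:`write_panel` (or hand-built).

    Without a metadata sidecar, covariates are taken to be the columns
    between ``treated`` and the first instrument column, with kind inferred
    (binary iff values are a subset of {0,1}).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"panel file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PanelDataset.REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"panel missing required columns: {missing}")

    meta_path = Path(str(path) + ".meta.json")
    instrument_prefixes = ("exam_q", "recall_g", "freq_f", "month_low_", "month_relief_")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        covariate_kinds = dict(meta["covariate_kinds"])
        outcome_names = list(meta["outcome_names"])
        n_exam_items = int(meta["n_exam_items"])
    else:
        cols = list(df.columns)
        start = cols.index("treated") + 1
        cov_cols = []
        for c in cols[start:]:
            if c.startswith(instrument_prefixes):
                break
            cov_cols.append(c)
        covariate_kinds = {
            c: ("binary" if set(np.unique(df[c])) <= {0, 1} else "continuous")
            for c in cov_cols
        }
        tail = cols.index("strategies_count") + 1 if "strategies_count" in cols else len(cols)
        outcome_names = cols[tail:]
        n_exam_items = sum(c.startswith("exam_q") for c in cols)

    for c in covariate_kinds:
        if c in df.columns:
            df[c] = df[c].astype(float)
    panel = PanelDataset(
        df=df,
        covariate_kinds=covariate_kinds,
        outcome_names=outcome_names,
        n_exam_items=n_exam_items,
    )
    panel.validate()
    return panel
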
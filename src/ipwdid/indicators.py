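"""Composite outcome construction from raw survey instrument responses.

Builds knowledge-exam indices (inverse-difficulty weighted), four dietary
diversity counts, the food consumption score (FCS), a 7-day vitamin-A
consumption frequency, and the month-calendar food-security indicators.
All constructors are vectorised over households: inputs are pandas
DataFrames whose columns are the 12 survey food categories (or exam items),
one row per household-wave observation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError

__all__ = [
    "FoodGroupMap",
    "KnowledgeWeights",
    "Standardized",
    "default_food_group_map",
    "fit_knowledge_weights",
    "knowledge_score",
    "standardize",
    "diversity_score",
    "hdds",
    "cdds",
    "fgds",
    "vita_diversity",
    "fcs",
    "vita_freq",
    "food_security",
    "build_indicators",
]

#: diversity scheme name -> (number of groups, i.e. upper bound of the count)
SCHEME_BOUNDS = {"hdds": 8, "cdds": 8, "fgds": 10, "vitamin_a": 6}


@dataclass(frozen=True)
class FoodGroupMap:
    """Mapping from the 12 survey food categories to scoring-scheme groups.

    Attributes
    ----------
    categories
        The 12 survey categories, in instrument column order.
    schemes
        ``scheme -> group -> list of member categories``.  Schemes: ``hdds``
        (8 household groups), ``cdds`` (8 child groups, organ meat separate
        and vitamin-A produce split out), ``fgds`` (10 groups),
        ``vitamin_a`` (6 groups), ``fcs`` (7 frequency groups).
    fcs_weights
        Per-FCS-group weight applied after capping group frequency at 7.
    vitamin_a_items
        Categories counting as vitamin-A sources in the 7-day frequency
        indicator.
    """

    categories: tuple[str, ...]
    schemes: Mapping[str, Mapping[str, tuple[str, ...]]]
    fcs_weights: Mapping[str, float]
    vitamin_a_items: tuple[str, ...]
    version: int = 1

    def __post_init__(self):
        cats = set(self.categories)
        if len(cats) != len(self.categories):
            raise ValidationError("duplicate survey categories in food group map")
        for scheme, groups in self.schemes.items():
            if scheme in SCHEME_BOUNDS and len(groups) != SCHEME_BOUNDS[scheme]:
                raise ValidationError(
                    f"scheme {scheme!r} must define {SCHEME_BOUNDS[scheme]} groups, "
                    f"got {len(groups)}"
                )
            for group, members in groups.items():
                unknown = set(members) - cats
                if unknown:
                    raise ValidationError(
                        f"scheme {scheme!r} group {group!r} references unknown "
                        f"categories {sorted(unknown)}"
                    )
        if set(self.fcs_weights) != set(self.schemes["fcs"]):
            raise ValidationError("fcs_weights keys must match the fcs scheme groups")
        if any(w <= 0 for w in self.fcs_weights.values()):
            raise ValidationError("all FCS group weights must be > 0")
        unknown = set(self.vitamin_a_items) - cats
        if unknown:
            raise ValidationError(f"unknown vitamin-A items {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path_or_stream) -> "FoodGroupMap":
        if hasattr(path_or_stream, "read"):
            raw = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                raw = yaml.safe_load(fh)
        return cls(
            categories=tuple(raw["categories"]),
            schemes={
                s: {g: tuple(m) for g, m in groups.items()}
                for s, groups in raw["schemes"].items()
            },
            fcs_weights=dict(raw["fcs_weights"]),
            vitamin_a_items=tuple(raw["vitamin_a_items"]),
            version=int(raw.get("version", 1)),
        )


def default_food_group_map() -> FoodGroupMap:
    """The food-group map shipped with the package."""
    ref = resources.files("ipwdid.data").joinpath("food_groups.yaml")
    with ref.open() as fh:
        return FoodGroupMap.from_yaml(fh)


# ---------------------------------------------------------------------------
# knowledge indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KnowledgeWeights:
    """Per-item inverse-difficulty weights fitted on a reference sample."""

    p_correct: pd.Series
    weights: pd.Series = field(default=None)  # type: ignore[assignment]
    excluded: tuple[str, ...] = ()
    reference: str = "pooled baseline"

    def __post_init__(self):
        if self.weights is None:
            object.__setattr__(self, "weights", 1.0 / self.p_correct)
        if (self.p_correct <= 0).any() or (self.p_correct > 1).any():
            raise ValidationError("item probabilities must lie in (0, 1]")

    @property
    def items(self) -> pd.Index:
        return self.weights.index


def _check_binary(df: pd.DataFrame, what: str) -> None:
    vals = df.to_numpy()
    if not np.isin(vals[~np.isnan(vals.astype(float))], (0, 1)).all():
        raise ValidationError(f"{what} must be binary 0/1 indicators")


def fit_knowledge_weights(
    responses: pd.DataFrame,
    reference: pd.Series | np.ndarray | None = None,
    reference_label: str = "pooled baseline",
) -> KnowledgeWeights:
    """Fit per-item weights as the inverse share answering correctly.

    Parameters
    ----------
    responses
        Binary item-response matrix, one column per exam item.
    reference
        Boolean row selector giving the reference sample; all rows by default.

    Items never answered correctly in the reference sample carry an undefined
    weight; they are excluded with a warning naming each item.
    """
    _check_binary(responses, "exam responses")
    ref = responses if reference is None else responses.loc[np.asarray(reference, bool)]
    if len(ref) == 0:
        raise ValidationError("reference sample for knowledge weights is empty")
    p = ref.mean(axis=0)
    dead = p.index[p <= 0].tolist()
    if dead:
        warnings.warn(
            f"excluding items never answered correctly in reference sample: {dead}",
            UserWarning,
            stacklevel=2,
        )
        p = p.drop(dead)
    return KnowledgeWeights(p_correct=p, excluded=tuple(dead), reference=reference_label)


def knowledge_score(
    responses: pd.DataFrame,
    weights: KnowledgeWeights,
    items: Sequence[str] | None = None,
    missing: str = "incorrect",
) -> pd.Series:
    """Weighted exam score: sum of item weights over correct answers.

    ``items`` restricts to a sub-exam (e.g. production vs. nutrition items);
    it must be a subset of the weighted items.  Missing responses are scored
    as incorrect by default; ``missing="error"`` raises instead.
    """
    cols = list(weights.items) if items is None else list(items)
    extra = set(cols) - set(weights.items)
    if extra:
        raise ValidationError(f"items not covered by fitted weights: {sorted(extra)}")
    resp = responses[cols]
    if resp.isna().any().any():
        if missing == "error":
            raise ValidationError("missing exam responses present")
        resp = resp.fillna(0.0)
    _check_binary(resp, "exam responses")
    return resp.to_numpy(float) @ weights.weights[cols].to_numpy(float) + pd.Series(
        0.0, index=responses.index
    )


@dataclass(frozen=True)
class Standardized:
    """A score expressed in reference-sample standard-deviation units."""

    values: pd.Series
    ref_mean: float
    ref_sd: float


def standardize(
    scores: pd.Series, reference: pd.Series | np.ndarray | None = None
) -> Standardized:
    """Center and scale by the reference sample mean and SD.

    ``reference`` is a boolean row selector (all rows by default).  A zero
    reference SD is an explicit failure.
    """
    scores = pd.Series(scores)
    ref = scores if reference is None else scores.loc[np.asarray(reference, bool)]
    mu = float(ref.mean())
    sd = float(ref.std(ddof=0))
    if not sd > 0:
        raise ValidationError("reference sample has zero standard deviation")
    return Standardized(values=(scores - mu) / sd, ref_mean=mu, ref_sd=sd)


# ---------------------------------------------------------------------------
# dietary diversity
# ---------------------------------------------------------------------------

def _check_recall(recall: pd.DataFrame, fg_map: FoodGroupMap) -> pd.DataFrame:
    missing = set(fg_map.categories) - set(recall.columns)
    if missing:
        raise ValidationError(f"24-hour recall missing categories {sorted(missing)}")
    recall = recall[list(fg_map.categories)]
    if not np.isin(recall.to_numpy(), (0, 1)).all():
        raise ValidationError("24-hour recall indicators must be 0/1")
    return recall


def diversity_score(
    recall_24h: pd.DataFrame, fg_map: FoodGroupMap, scheme: str
) -> pd.Series:
    """Count of scheme groups with at least one consumed member category."""
    if scheme not in fg_map.schemes:
        raise ValidationError(f"unknown diversity scheme {scheme!r}")
    recall = _check_recall(recall_24h, fg_map)
    total = pd.Series(0, index=recall.index, dtype=int)
    for members in fg_map.schemes[scheme].values():
        total += recall[list(members)].any(axis=1).astype(int)
    return total


def hdds(recall_24h: pd.DataFrame, fg_map: FoodGroupMap) -> pd.Series:
    """Household dietary diversity score over 8 food groups, range [0, 8]."""
    return diversity_score(recall_24h, fg_map, "hdds")


def cdds(recall_24h: pd.DataFrame, fg_map: FoodGroupMap) -> pd.Series:
    """Child dietary diversity score over 8 groups (organ meat separate,
    vitamin-A-rich produce distinguished), range [0, 8]."""
    return diversity_score(recall_24h, fg_map, "cdds")


def fgds(recall_24h: pd.DataFrame, fg_map: FoodGroupMap) -> pd.Series:
    """10-group food-group diversity count, range [0, 10].

    Note: a household consuming nothing scores 0 even though the instrument
    presumes at least one group.
    """
    return diversity_score(recall_24h, fg_map, "fgds")


def vita_diversity(recall_24h: pd.DataFrame, fg_map: FoodGroupMap) -> pd.Series:
    """Count of vitamin-A source groups consumed, range [0, 6]."""
    return diversity_score(recall_24h, fg_map, "vitamin_a")


def _check_freq(freq_7d: pd.DataFrame, categories: Sequence[str]) -> pd.DataFrame:
    missing = set(categories) - set(freq_7d.columns)
    if missing:
        raise ValidationError(f"7-day frequencies missing categories {sorted(missing)}")
    freq = freq_7d[list(categories)]
    vals = freq.to_numpy(float)
    if (vals < 0).any():
        raise ValidationError("7-day frequencies must be non-negative")
    if (vals > 7).any():
        raise ValidationError("7-day item frequencies cannot exceed 7 days")
    return freq


def fcs(freq_7d: pd.DataFrame, fg_map: FoodGroupMap) -> pd.Series:
    """Food consumption score from 7-day food-group frequencies.

    Per group: sum member-item day counts, cap at 7, multiply by the group
    weight; the score is the sum of the weighted group values.
    """
    freq = _check_freq(freq_7d, fg_map.categories)
    total = pd.Series(0.0, index=freq.index)
    for group, members in fg_map.schemes["fcs"].items():
        group_days = freq[list(members)].sum(axis=1).clip(upper=7)
        total += fg_map.fcs_weights[group] * group_days
    return total


def vita_freq(freq_7d: pd.DataFrame, fg_map: FoodGroupMap) -> pd.Series:
    """Days in the past week with any vitamin-A-rich food, capped at 7.

    Item-level day counts are resolved to a day union as
    ``min(sum of item days, 7)``.
    """
    freq = _check_freq(freq_7d, fg_map.vitamin_a_items)
    return freq.sum(axis=1).clip(upper=7)


# ---------------------------------------------------------------------------
# food security
# ---------------------------------------------------------------------------

def food_security(
    months_low_food: pd.DataFrame,
    months_relief: pd.DataFrame,
    sold_asset: pd.Series,
    strategies_count: pd.Series,
) -> pd.DataFrame:
    """Aggregate the month calendars and coping indicators.

    Returns a frame with columns ``mihfp`` (months of inadequate food
    provisioning, 0-12), ``relief_months`` (0-12), ``sold_asset`` (0/1) and
    ``food_insecurity_score`` (non-negative strategy count).
    """
    for name, months in (("months_low_food", months_low_food), ("months_relief", months_relief)):
        if months.shape[1] != 12:
            raise ValidationError(
                f"{name} must have 12 monthly flags, got {months.shape[1]}"
            )
        if not np.isin(months.to_numpy(), (0, 1)).all():
            raise ValidationError(f"{name} flags must be 0/1")
    if not np.isin(sold_asset.to_numpy(), (0, 1)).all():
        raise ValidationError("sold_asset must be 0/1")
    if (strategies_count.to_numpy() < 0).any():
        raise ValidationError("strategies_count must be non-negative")
    return pd.DataFrame(
        {
            "mihfp": months_low_food.sum(axis=1).astype(int),
            "relief_months": months_relief.sum(axis=1).astype(int),
            "sold_asset": sold_asset.astype(int),
            "food_insecurity_score": strategies_count,
        }
    )


# ---------------------------------------------------------------------------
# full indicator table
# ---------------------------------------------------------------------------

def build_indicators(
    panel,
    fg_map: FoodGroupMap | None = None,
    n_production_items: int | None = None,
) -> pd.DataFrame:
    """Compute every indicator for a panel, keyed by household_id and wave.

    Knowledge weights are fitted on the pooled baseline sample and applied
    to both waves so scores are comparable over time.  The exam's first
    ``n_production_items`` items form the production sub-score and the rest
    the vitamin-A sub-score (default: an even split).
    """
    from .synthdata import PanelDataset  # local import to avoid a cycle

    if isinstance(panel, PanelDataset):
        df = panel.df
    else:
        df = panel
    fg_map = fg_map or default_food_group_map()

    exam_cols = [c for c in df.columns if c.startswith("exam_q")]
    recall_cols = [c for c in df.columns if c.startswith("recall_g")]
    freq_cols = [c for c in df.columns if c.startswith("freq_f")]
    low_cols = [c for c in df.columns if c.startswith("month_low_")]
    relief_cols = [c for c in df.columns if c.startswith("month_relief_")]
    if len(recall_cols) != len(fg_map.categories):
        raise ValidationError(
            f"expected {len(fg_map.categories)} recall columns, got {len(recall_cols)}"
        )

    exam = df[exam_cols]
    weights = fit_knowledge_weights(exam, reference=(df["wave"] == 0).to_numpy())
    usable = [c for c in exam_cols if c in weights.items]
    k = n_production_items if n_production_items is not None else len(exam_cols) // 2
    prod_items = [c for c in exam_cols[:k] if c in weights.items]
    vita_items = [c for c in exam_cols[k:] if c in weights.items]

    recall = df[recall_cols].copy()
    recall.columns = list(fg_map.categories)
    freq = df[freq_cols].copy()
    freq.columns = list(fg_map.categories)

    out = pd.DataFrame(
        {
            "household_id": df["household_id"],
            "wave": df["wave"],
            "knowledge_production": knowledge_score(exam, weights, prod_items),
            "knowledge_vitaminA": knowledge_score(exam, weights, vita_items),
            "knowledge_combined": knowledge_score(exam, weights, usable),
            "hdds": hdds(recall, fg_map),
            "cdds": cdds(recall, fg_map),
            "fgds": fgds(recall, fg_map),
            "vita_diversity": vita_diversity(recall, fg_map),
            "fcs": fcs(freq, fg_map),
            "vita_freq_days": vita_freq(freq, fg_map),
        }
    )
    fs = food_security(
        df[low_cols], df[relief_cols], df["sold_asset"], df["strategies_count"]
    )
    out = pd.concat([out, fs], axis=1)

    baseline = (df["wave"] == 0).to_numpy()
    for col in ("knowledge_production", "knowledge_vitaminA", "knowledge_combined"):
        out[f"{col}_std"] = standardize(out[col], reference=baseline).values
    return out
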
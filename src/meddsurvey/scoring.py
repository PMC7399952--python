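"""Modified 18-point literature-based Mediterranean-diet (MedD) adherence score.

Nine food components are each scored 0, 1 or 2; the total runs 0-18 with
higher totals meaning closer adherence to a Mediterranean pattern.

Four components use fixed printed rules:

* fruit (cup equivalents/day):      0 = <1,  1 = >=1,  2 = >=2
* vegetables (cup equivalents/day): 0 = <0.5, 1 = >=0.5, 2 = >=1
* olive oil (g/day):                0 = <14, 1 = >=14, 2 = >=28
* alcohol (g ethanol/day): unimodal — 1 for <12 g, 2 for 12-24 g, 0 for >24 g
  (moderate intake scores highest; heavy intake scores 0, abstention 1).

The remaining five (legumes, cereals/whole grains, fish, meat, dairy) are
graded against configurable gram cutoffs from the literature-based index:
increasing components step 0->1 at the lower cutoff and 1->2 at the upper;
meat is scored in the decreasing direction (less red/cured/organ meat scores
higher). Thresholds are inclusive upward, mirrored for decreasing.

Adherence tertiles are equal-size by construction: participants are ranked by
total score with a deterministic tie-break and cut into three groups whose
sizes differ by at most one (remainder to the lower tertiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

TERTILE_LABELS = ["lowest", "middle", "highest"]


@dataclass(frozen=True)
class GradedCutoffs:
    """Gram cutoffs and direction for one graded component."""

    lower: float
    upper: float
    direction: str = "increasing"  # or "decreasing"

    def __post_init__(self):
        if self.direction not in ("increasing", "decreasing"):
            raise ConfigurationError(f"direction must be increasing/decreasing, got {self.direction}")
        if not (0 < self.lower < self.upper):
            raise ConfigurationError(
                f"cutoffs must satisfy 0 < lower < upper, got ({self.lower}, {self.upper})"
            )


@dataclass(frozen=True)
class ScoreCutoffs:
    """Cutoff configuration for the five graded components (g/day).

    Defaults derive from the literature-based index's serving sizes converted
    to grams per day: legumes 70 g servings at 1 and 2 per week; cereals
    130 g servings (so a score of 1 needs about 4.5 oz of whole grains) at 1
    and 1.5 per day; fish 100 g servings at 1 and 2.5 per week; meat 80 g
    servings, decreasing, at 1 and 1.5 per day; dairy 200 g servings at 1 and
    2 per day. The fixed fruit/vegetable/olive-oil/alcohol rules are not
    configurable: they are printed rules.
    """

    legumes: GradedCutoffs = field(default_factory=lambda: GradedCutoffs(10.0, 20.0))
    cereals: GradedCutoffs = field(default_factory=lambda: GradedCutoffs(130.0, 195.0))
    fish: GradedCutoffs = field(default_factory=lambda: GradedCutoffs(14.0, 36.0))
    meat: GradedCutoffs = field(default_factory=lambda: GradedCutoffs(80.0, 120.0, "decreasing"))
    dairy: GradedCutoffs = field(default_factory=lambda: GradedCutoffs(200.0, 400.0))

    @classmethod
    def from_dict(cls, cfg: dict) -> "ScoreCutoffs":
        kwargs = {}
        for name, block in (cfg or {}).items():
            if name not in ("legumes", "cereals", "fish", "meat", "dairy"):
                raise ConfigurationError(f"unknown graded component in cutoffs: {name}")
            kwargs[name] = GradedCutoffs(
                float(block["lower"]), float(block["upper"]), block.get("direction", "increasing")
            )
        return cls(**kwargs)


def _check_nonneg(value: float, what: str) -> float:
    v = float(value)
    if v < 0 or np.isnan(v):
        raise ValidationError(f"{what} must be a nonnegative amount, got {value}")
    return v


def score_fruit(ce: float) -> int:
    """Fruit: 0 = <1 CE, 1 = >=1 CE, 2 = >=2 CE per day."""
    ce = _check_nonneg(ce, "fruit CE")
    return 2 if ce >= 2 else (1 if ce >= 1 else 0)


def score_vegetables(ce: float) -> int:
    """Vegetables: 0 = <0.5 CE, 1 = >=0.5 CE, 2 = >=1 CE per day."""
    ce = _check_nonneg(ce, "vegetable CE")
    return 2 if ce >= 1 else (1 if ce >= 0.5 else 0)


def score_olive_oil(g: float) -> int:
    """Olive oil: 0 = <14 g, 1 = >=14 g, 2 = >=28 g per day (0/1/2 tablespoons)."""
    g = _check_nonneg(g, "olive oil grams")
    return 2 if g >= 28 else (1 if g >= 14 else 0)


def score_alcohol(g: float) -> int:
    """Alcohol: 1 for <12 g, 2 for 12-24 g, 0 for >24 g ethanol per day.

    The moderate band is the closed interval [12, 24]; exactly 12 g scores 2.
    """
    g = _check_nonneg(g, "alcohol grams")
    if g > 24:
        return 0
    if g >= 12:
        return 2
    return 1


def score_graded_component(g: float, cutoffs: GradedCutoffs) -> int:
    """Score a graded component against its gram cutoffs.

    Increasing: 0 below lower, 1 at/above lower, 2 at/above upper.
    Decreasing (meat): 2 below lower, 1 at/above lower, 0 at/above upper.
    """
    g = _check_nonneg(g, "graded component grams")
    if g >= cutoffs.upper:
        s = 2
    elif g >= cutoffs.lower:
        s = 1
    else:
        s = 0
    return s if cutoffs.direction == "increasing" else 2 - s


COMPONENT_SCORERS = {
    "fruit": ("fruit_ce", score_fruit),
    "vegetables": ("vegetables_ce", score_vegetables),
    "legumes": ("legumes_g", None),
    "cereals": ("cereals_wholegrain_g", None),
    "fish": ("fish_g", None),
    "meat": ("meat_g", None),
    "dairy": ("dairy_g", None),
    "alcohol": ("alcohol_g", score_alcohol),
    "olive_oil": ("olive_oil_g", score_olive_oil),
}

COMPONENT_NAMES = list(COMPONENT_SCORERS)


def score_component(name: str, amount: float, cutoffs: ScoreCutoffs | None = None) -> int:
    """Score a single named component at a given daily amount."""
    cutoffs = cutoffs or ScoreCutoffs()
    if name not in COMPONENT_SCORERS:
        raise ConfigurationError(f"unknown component: {name}")
    _, fn = COMPONENT_SCORERS[name]
    if fn is not None:
        return fn(amount)
    return score_graded_component(amount, getattr(cutoffs, name))


def total_score(component_scores: dict[str, int]) -> int:
    """Sum the nine component scores into the 0-18 total."""
    missing = [c for c in COMPONENT_NAMES if c not in component_scores]
    if missing:
        raise ValidationError(f"missing component scores: {', '.join(missing)}")
    bad = {c: s for c, s in component_scores.items() if c in COMPONENT_NAMES and s not in (0, 1, 2)}
    if bad:
        raise ValidationError(f"component scores must be 0/1/2, got {bad}")
    return int(sum(component_scores[c] for c in COMPONENT_NAMES))


def score_components(components: pd.DataFrame, cutoffs: ScoreCutoffs | None = None) -> pd.DataFrame:
    """Score a component-intake table: one row per participant.

    Returns columns ``SCORE_<COMPONENT>`` for the nine components plus
    ``SCORE_TOTAL``; ``SEQN`` is carried through when present.
    """
    cutoffs = cutoffs or ScoreCutoffs()
    out = pd.DataFrame(index=components.index)
    if "SEQN" in components.columns:
        out["SEQN"] = components["SEQN"]
    for name, (col, _) in COMPONENT_SCORERS.items():
        out[f"SCORE_{name.upper()}"] = score_component_array(
            name, components[col].to_numpy(dtype=float), cutoffs
        )
    out["SCORE_TOTAL"] = out[[f"SCORE_{n.upper()}" for n in COMPONENT_NAMES]].sum(axis=1)
    return out


def score_component_array(name: str, values: np.ndarray, cutoffs: ScoreCutoffs | None = None):
    """Vectorized component scoring (same rules as the scalar scorers)."""
    cutoffs = cutoffs or ScoreCutoffs()
    v = np.asarray(values, dtype=float)
    if np.any((v < 0) | np.isnan(v)):
        bad = int(np.where((v < 0) | np.isnan(v))[0][0])
        raise ValidationError(f"{name} amounts must be nonnegative; offending index {bad}")
    if name == "fruit":
        return np.select([v >= 2, v >= 1], [2, 1], 0)
    if name == "vegetables":
        return np.select([v >= 1, v >= 0.5], [2, 1], 0)
    if name == "olive_oil":
        return np.select([v >= 28, v >= 14], [2, 1], 0)
    if name == "alcohol":
        return np.select([v > 24, v >= 12], [0, 2], 1)
    if name not in COMPONENT_SCORERS:
        raise ConfigurationError(f"unknown component: {name}")
    c = getattr(cutoffs, name)
    s = np.select([v >= c.upper, v >= c.lower], [2, 1], 0)
    return s if c.direction == "increasing" else 2 - s


def tertile_sizes(n: int) -> tuple[int, int, int]:
    """Equal-size tertile group sizes: sizes differ by <=1, remainder to the
    lower tertiles (n=3068 -> 1023/1023/1022)."""
    q, r = divmod(n, 3)
    return tuple(q + (1 if i < r else 0) for i in range(3))


def assign_tertiles(scores: pd.Series) -> pd.Series:
    """Partition participants into lowest/middle/highest adherence tertiles.

    Participants are stably sorted by (score, participant id) and cut into
    three contiguous groups of near-equal size. Ties at a cut point are split
    deterministically by the sort, so reruns on the same input agree exactly.

    Parameters
    ----------
    scores : Series of per-participant total scores, indexed by participant id.

    Returns
    -------
    Series of labels 'lowest'/'middle'/'highest' (ordered categorical),
    aligned to the input index.
    """
    n = len(scores)
    if n < 3:
        raise ValidationError(f"need at least 3 participants for tertiles, got {n}")
    if scores.isna().any():
        raise ValidationError("scores contain missing values")
    # stable sort by score, then participant id (ranked to allow any id dtype)
    id_rank = pd.Series(scores.index).rank(method="first").to_numpy()
    idx = np.lexsort((id_rank, scores.to_numpy()))
    sizes = tertile_sizes(n)
    labels = np.empty(n, dtype=object)
    start = 0
    for size, lab in zip(sizes, TERTILE_LABELS):
        labels[idx[start : start + size]] = lab
        start += size
    return pd.Series(
        pd.Categorical(labels, categories=TERTILE_LABELS, ordered=True),
        index=scores.index,
        name="TERTILE",
    )
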
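"""Dietary-recall ingestion: reading recall tables, energy-outlier screening,
two-day averaging, and mapping FPED food groups onto the nine Mediterranean-diet
score components.

The unit of input is one 24-h recall day per row, identified by ``SEQN``
(participant) and ``DAY`` (1 or 2), with FPED food-group amounts in grams or,
for fruit and vegetable groups, cup equivalents (CE). Two completed recall
days are required for a participant to enter the analysis set; the two days
are combined by the arithmetic mean, amount by amount.

Energy plausibility is screened with the robust modified z-score
``0.6745 * (x - median) / MAD`` and the conventional |z| >= 3.5 cutoff.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DegenerateScaleError, SchemaError, ValidationError

#: Exact column contract for recall-level CSV input, one row per participant-day.
RECALL_COLUMNS = [
    "SEQN",
    "DAY",
    "FPED_CITMLB_CE",
    "FPED_OTHRFRUIT_CE",
    "FPED_DARKGREEN_CE",
    "FPED_TOMATO_CE",
    "FPED_REDORANGE_CE",
    "FPED_OTHSTARCHY_CE",
    "FPED_LEGUMES_G",
    "FPED_WHOLEGRAIN_G",
    "FPED_FISHLO3_G",
    "FPED_FISHHI3_G",
    "FPED_REDMEAT_G",
    "FPED_CUREDMEAT_G",
    "FPED_ORGANMEAT_G",
    "FPED_DAIRY_G",
    "ALC_G",
    "OLIVEOIL_G",
    "ENERGY_KCAL",
]

#: Amount columns (everything except the identifiers).
AMOUNT_COLUMNS = RECALL_COLUMNS[2:]

#: The nine score components, in scoring order.
COMPONENT_COLUMNS = [
    "fruit_ce",
    "vegetables_ce",
    "legumes_g",
    "cereals_wholegrain_g",
    "fish_g",
    "meat_g",
    "dairy_g",
    "alcohol_g",
    "olive_oil_g",
]

#: FPED constituents of each component. Vegetables sum exactly the four listed
#: FPED groups; cereals is whole grains only; dairy is total dairy.
FPED_TO_COMPONENT = {
    "fruit_ce": ["FPED_CITMLB_CE", "FPED_OTHRFRUIT_CE"],
    "vegetables_ce": [
        "FPED_DARKGREEN_CE",
        "FPED_TOMATO_CE",
        "FPED_REDORANGE_CE",
        "FPED_OTHSTARCHY_CE",
    ],
    "legumes_g": ["FPED_LEGUMES_G"],
    "cereals_wholegrain_g": ["FPED_WHOLEGRAIN_G"],
    "fish_g": ["FPED_FISHLO3_G", "FPED_FISHHI3_G"],
    "meat_g": ["FPED_REDMEAT_G", "FPED_CUREDMEAT_G", "FPED_ORGANMEAT_G"],
    "dairy_g": ["FPED_DAIRY_G"],
    "alcohol_g": ["ALC_G"],
    "olive_oil_g": ["OLIVEOIL_G"],
}

#: Grams of ethanol per standard drink equivalent, used when alcohol arrives
#: as drink equivalents instead of grams.
GRAMS_PER_DRINK = 14.0


def read_recall_table(
    path, *, alcohol_drinks_column: str | None = None, grams_per_drink: float = GRAMS_PER_DRINK
) -> pd.DataFrame:
    """Read a recall-day CSV and validate it against the column contract.

    Parameters
    ----------
    path
        CSV file with one row per participant-day. Empty cells are missing.
    alcohol_drinks_column
        If given, the file carries alcohol as drink equivalents in this column
        instead of an ``ALC_G`` grams column; it is converted with
        ``grams_per_drink`` (default 14 g ethanol per drink).

    Returns
    -------
    DataFrame with the contract columns; unknown columns are preserved but
    ignored downstream.
    """
    df = pd.read_csv(path)
    if alcohol_drinks_column is not None:
        if alcohol_drinks_column not in df.columns:
            raise SchemaError(f"missing mandatory column: {alcohol_drinks_column}")
        df["ALC_G"] = df[alcohol_drinks_column] * float(grams_per_drink)
    return validate_recall_table(df)


def validate_recall_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the recall-day column contract and amount invariants."""
    for col in RECALL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col}")
    bad_day = df["DAY"].dropna()
    if not bad_day.isin([1, 2]).all():
        rows = df.index[~df["DAY"].isin([1, 2]) & df["DAY"].notna()].tolist()
        raise ValidationError(f"DAY must be 1 or 2; offending rows: {rows[:5]}")
    for col in AMOUNT_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        neg = vals < 0
        if neg.any():
            row = int(df.index[neg][0])
            raise ValidationError(f"negative amount in column {col} at row {row}")
        df[col] = vals
    return df


def average_recalls(day1: pd.Series, day2: pd.Series) -> pd.Series:
    """Average one participant's two recall days, amount by amount.

    Both rows must belong to the same participant and carry day indices 1
    and 2. The result keeps ``SEQN`` and drops ``DAY``.
    """
    if day1["SEQN"] != day2["SEQN"]:
        raise ValidationError(
            f"cannot average recalls of different participants: {day1['SEQN']} vs {day2['SEQN']}"
        )
    if {int(day1["DAY"]), int(day2["DAY"])} != {1, 2}:
        raise ValidationError("expected one recall for day 1 and one for day 2")
    out = pd.Series(index=["SEQN"] + AMOUNT_COLUMNS, dtype=object)
    out["SEQN"] = day1["SEQN"]
    for col in AMOUNT_COLUMNS:
        out[col] = (float(day1[col]) + float(day2[col])) / 2.0
    return out


def average_recall_table(recalls: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Average two recall days per participant across a recall table.

    Participants without both days (or with missing amounts on either day)
    are excluded — completing two 24-h recalls is an inclusion requirement —
    and returned in the exclusion list.

    Returns
    -------
    (intake, excluded)
        ``intake`` has one row per retained participant with day-averaged
        amounts; ``excluded`` lists the SEQNs dropped for an incomplete pair.
    """
    recalls = recalls.copy()
    counts = recalls.groupby("SEQN")["DAY"].agg(lambda d: set(d.dropna().astype(int)))
    complete = counts[counts.apply(lambda s: s == {1, 2})].index
    excluded = sorted(set(recalls["SEQN"]) - set(complete))
    kept = recalls[recalls["SEQN"].isin(complete)]
    intake = kept.groupby("SEQN", as_index=False)[AMOUNT_COLUMNS].mean()
    # a missing amount on either day leaves NaN in the mean -> exclude too
    incomplete_amounts = intake[AMOUNT_COLUMNS].isna().any(axis=1)
    excluded += sorted(intake.loc[incomplete_amounts, "SEQN"])
    intake = intake[~incomplete_amounts].reset_index(drop=True)
    return intake, excluded


def modified_zscore(values: Iterable[float]) -> np.ndarray:
    """Robust modified z-scores, 0.6745 * (x - median) / MAD.

    MAD is the median absolute deviation from the median. Requires at least
    two values and a nonzero MAD.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValidationError("modified_zscore requires at least 2 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise DegenerateScaleError("MAD is zero; modified z-scores undefined")
    return 0.6745 * (x - med) / mad


def screen_energy_outliers(
    records: pd.DataFrame, cutoff: float = 3.5, energy_column: str = "ENERGY_KCAL"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records into (kept, flagged) by the modified-z energy screen.

    ``flagged`` contains records with |modified z of energy| >= cutoff.
    Order is preserved and kept + flagged is exactly the input.
    """
    energy = records[energy_column].to_numpy(dtype=float)
    if np.isnan(energy).any():
        raise ValidationError(f"{energy_column} missing for some records")
    z = modified_zscore(energy)
    mask = np.abs(z) >= cutoff
    return records[~mask], records[mask]


def map_fped_to_components(intake: pd.DataFrame) -> pd.DataFrame:
    """Collapse FPED group amounts into the nine MedD score components.

    Each component is the sum of its FPED constituents: fruit = citrus/melons/
    berries + other fruit (CE); vegetables = dark green + tomatoes +
    red/orange + other starchy (CE); meat = red + cured + organ; fish = low +
    high omega-3 seafood; cereals = whole grains; dairy = total dairy;
    alcohol (g ethanol) and olive oil (g) pass through.
    """
    out = pd.DataFrame(index=intake.index)
    if "SEQN" in intake.columns:
        out["SEQN"] = intake["SEQN"]
    for component, parts in FPED_TO_COMPONENT.items():
        out[component] = intake[list(parts)].sum(axis=1, skipna=False)
    neg = out[COMPONENT_COLUMNS].lt(0).any(axis=1)
    if neg.any():
        raise ValidationError(f"negative component amount at row {int(out.index[neg][0])}")
    return out
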
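"""Education-stratified cognitive standardization.

Raw scores from the CERAD word-list test (three immediate learning trials and
a delayed recall, each 0-10 words), the Animal Fluency Test (AFT, animals
named in one minute) and the Digit Symbol Substitution Test (DSST, 0-133
correct pairs) are converted to z-scores within five education strata
(<9th grade, 9-11th grade, high school/GED, some college/AA, college+),
because education dominates raw cognitive performance. A global composite is
the mean of the four test z-scores, computed only when all four are present.
A standardized score below -1 (strictly) flags "low cognitive performance"
on that measure.

Standardization is an unweighted cohort transformation with the sample-SD
(n-1) convention; survey weights enter later, at estimation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateStratumError, ValidationError

EDUCATION_LEVELS = [
    "<9th Grade",
    "9-11th Grade",
    "High School/GED",
    "Some College/AA Degree",
    "College Graduate or Above",
]

#: Raw-score column -> z-score column.
TEST_COLUMNS = {
    "CERAD_IMM": "Z_CERAD_IMM",
    "DSST": "Z_DSST",
    "AFT": "Z_AFT",
    "CERAD_DR": "Z_CERAD_DR",
}

Z_COLUMNS = list(TEST_COLUMNS.values())
LOW_COLUMNS = ["LOW_CERAD_IMM", "LOW_DSST", "LOW_AFT", "LOW_CERAD_DR", "LOW_GLOBAL"]

COGNITIVE_MEASURES = {
    "CERAD Immediate Learning": ("Z_CERAD_IMM", "LOW_CERAD_IMM"),
    "Digit Symbol Substitution Test": ("Z_DSST", "LOW_DSST"),
    "Animal Fluency Test": ("Z_AFT", "LOW_AFT"),
    "CERAD Delayed Recall": ("Z_CERAD_DR", "LOW_CERAD_DR"),
    "Global Cognition": ("Z_GLOBAL", "LOW_GLOBAL"),
}


def cerad_immediate(trial1, trial2, trial3):
    """CERAD immediate learning: mean words recalled over the three trials.

    Accepts scalars or aligned Series; any missing trial yields a missing
    result for that participant; out-of-range word counts raise.
    """
    t = pd.concat(
        [pd.Series(np.atleast_1d(x), dtype=float) for x in (trial1, trial2, trial3)], axis=1
    )
    bad = ((t < 0) | (t > 10)).any(axis=1)
    if bad.any():
        raise ValidationError(f"CERAD trial word counts must be 0-10; row {int(t.index[bad][0])}")
    out = t.mean(axis=1, skipna=False)
    return float(out.iloc[0]) if np.isscalar(trial1) else out


def education_zscores(
    scores: pd.Series, education: pd.Series, tol: float = 0.0
) -> pd.Series:
    """Center and scale scores to mean 0, SD 1 within each education stratum.

    Missing scores stay missing and do not contribute to stratum moments.
    Sample SD (n-1 denominator), unweighted. A stratum with fewer than two
    non-missing values, or zero variance, is degenerate and raises.
    """
    scores = pd.Series(scores, dtype=float)
    z = pd.Series(np.nan, index=scores.index, dtype=float)
    for level, grp in scores.groupby(education, observed=True):
        vals = grp.dropna()
        if len(vals) < 2:
            raise DegenerateStratumError(
                f"education stratum {level!r} has {len(vals)} non-missing values (<2)"
            )
        sd = vals.std(ddof=1)
        if sd <= tol:
            raise DegenerateStratumError(f"education stratum {level!r} has zero variance")
        z.loc[grp.index] = (grp - vals.mean()) / sd
    return z


def global_cognition(z: pd.DataFrame) -> pd.Series:
    """Global composite: mean of the four test z-scores, complete case.

    Any missing test z leaves the global measure missing for that
    participant (the composite sample is the intersection of the four tests).
    """
    missing = [c for c in Z_COLUMNS if c not in z.columns]
    if missing:
        raise ValidationError(f"missing z-score columns: {', '.join(missing)}")
    return z[Z_COLUMNS].mean(axis=1, skipna=False)


def low_flag(z):
    """Low cognitive performance indicator: z < -1, strictly (z = -1 is not low).

    Missing z stays missing (returned as NaN rather than False).
    """
    if np.isscalar(z):
        zf = float(z)
        return np.nan if np.isnan(zf) else bool(zf < -1)
    z = pd.Series(z, dtype=float)
    out = (z < -1).astype(float)
    out[z.isna()] = np.nan
    return out


def standardize_cognition(df: pd.DataFrame, education_column: str = "EDU_LEVEL") -> pd.DataFrame:
    """Full cognitive standardization for a participant table.

    Expects raw columns ``CERAD_T1..T3, CERAD_DR, AFT, DSST`` and the
    education column; returns the input plus ``CERAD_IMM``, the four
    ``Z_*`` columns, ``Z_GLOBAL`` and the five ``LOW_*`` flags (floats with
    NaN for participants missing that measure).
    """
    out = df.copy()
    out["CERAD_IMM"] = cerad_immediate(df["CERAD_T1"], df["CERAD_T2"], df["CERAD_T3"])
    for raw, zcol in TEST_COLUMNS.items():
        out[zcol] = education_zscores(out[raw], out[education_column])
    out["Z_GLOBAL"] = global_cognition(out)
    for zcol, lowcol in zip(Z_COLUMNS + ["Z_GLOBAL"], LOW_COLUMNS):
        z = out[zcol]
        low = (z < -1).astype(float)
        low[z.isna()] = np.nan
        out[lowcol] = low
    return out
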
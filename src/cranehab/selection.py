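"""Habitat use and preference: use percentages and Ivlev's electivity index.

Use (``a``) is the percentage of flocks observed in a habitat among flocks in
available habitats; availability (``b``) is the habitat's share of the total
available area. Ivlev's electivity ``s = (a - b) / (a + b)`` runs from -1
(never used) through 0 (use proportional to availability) to +1 (exclusively
used); its sign separates preference from avoidance.

Flocks recorded in habitats outside the available set (e.g. woodland) are
excluded from the use denominator and reported separately.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .survey import AvailabilitySet, FlockObservation, InputError


def ivlev(a: float, b: float) -> float:
    """Ivlev's electivity index ``s = (a - b) / (a + b)``.

    Parameters are percentages (use ``a`` and availability ``b``) but the
    index only depends on their ratio. ``a = 0`` gives the never-used bound
    -1; ``a > b`` gives a positive index (preference).
    """
    if a < 0:
        raise InputError(f"use percentage a must be >= 0, got {a}")
    if b < 0:
        raise InputError(f"availability percentage b must be >= 0, got {b}")
    if a + b == 0:
        raise InputError("ivlev undefined for a + b = 0")
    return (a - b) / (a + b)


def use_table(
    flocks: Iterable[FlockObservation], avail: AvailabilitySet
) -> tuple[pd.DataFrame, int]:
    """Flock counts and use percentages per available habitat class.

    Returns a frame indexed by class with columns ``n_flocks`` and
    ``use_pct`` plus the number of flocks excluded because they were recorded
    in a non-available habitat. Raises if no flock falls in an available
    class.
    """
    flocks = list(flocks)
    for f in flocks:
        if f.habitat == "unassigned":
            raise InputError(f"flock {f.flock_id!r} has no assigned habitat")
    included = [f for f in flocks if f.habitat in avail.classes]
    n_excluded = len(flocks) - len(included)
    if not included:
        raise InputError("no flocks in available habitat classes; use table undefined")
    counts = {c: sum(1 for f in included if f.habitat == c) for c in avail.classes}
    n = len(included)
    df = pd.DataFrame(
        {
            "n_flocks": pd.Series(counts),
            "use_pct": pd.Series({c: 100.0 * k / n for c, k in counts.items()}),
        }
    )
    df.index.name = "habitat"
    return df, n_excluded


def pooled_electivity(
    flocks: Iterable[FlockObservation], avail: AvailabilitySet
) -> pd.Series:
    """Pooled (all surveys together) electivity per available class."""
    use, _ = use_table(flocks, avail)
    pcts = avail.percentages()
    return pd.Series(
        {c: ivlev(use.loc[c, "use_pct"], pcts[c]) for c in avail.classes}, name="s_pooled"
    )


def per_survey_electivity(
    flocks: Iterable[FlockObservation],
    avail: AvailabilitySet,
    surveys: Sequence[int] | None = None,
    zero_use: str = "include",
) -> pd.DataFrame:
    """Electivity per survey with across-survey mean and sample SD.

    For each survey, use ``a`` is computed from that survey's flocks only;
    availability ``b`` is the constant landscape value. Surveys with no
    included flocks are omitted with a warning.

    ``zero_use`` controls habitats with zero flocks in an otherwise non-empty
    survey: ``"include"`` (default) scores them at the bound s = -1;
    ``"omit"`` drops those surveys from that habitat's mean/SD.
    """
    if zero_use not in ("include", "omit"):
        raise InputError(f"zero_use must be 'include' or 'omit', got {zero_use!r}")
    flocks = list(flocks)
    if surveys is None:
        surveys = sorted({f.survey_id for f in flocks})
    pcts = avail.percentages()
    per_survey: dict[str, list[float]] = {c: [] for c in avail.classes}
    for sid in surveys:
        sf = [f for f in flocks if f.survey_id == sid]
        sf_inc = [f for f in sf if f.habitat in avail.classes]
        if not sf_inc:
            warnings.warn(f"survey {sid}: no flocks in available habitats; omitted")
            continue
        n = len(sf_inc)
        for c in avail.classes:
            a = 100.0 * sum(1 for f in sf_inc if f.habitat == c) / n
            if a == 0.0 and zero_use == "omit":
                continue
            per_survey[c].append(ivlev(a, pcts[c]))
    rows = {}
    for c in avail.classes:
        vals = np.asarray(per_survey[c], dtype=float)
        rows[c] = {
            "n_surveys": len(vals),
            "s_mean": float(vals.mean()) if len(vals) else np.nan,
            "s_sd": float(vals.std(ddof=1)) if len(vals) > 1 else (0.0 if len(vals) else np.nan),
            "s_values": list(vals),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "habitat"
    return df


def seasonal_electivity(
    flocks: Iterable[FlockObservation], avail: AvailabilitySet
) -> pd.DataFrame:
    """Pooled electivity per calendar month (long format).

    One value per (month, class): flocks of all the month's surveys pooled,
    because surveys per month are unequal. Months without included flocks
    yield no rows.
    """
    flocks = [f for f in flocks if f.habitat in avail.classes]
    pcts = avail.percentages()
    months = sorted({(f.date.year, f.date.month) for f in flocks})
    records = []
    for year, month in months:
        mf = [f for f in flocks if f.date.year == year and f.date.month == month]
        n = len(mf)
        for c in avail.classes:
            a = 100.0 * sum(1 for f in mf if f.habitat == c) / n
            records.append(
                {
                    "year": year,
                    "month": month,
                    "habitat": c,
                    "n_flocks": n,
                    "use_pct": a,
                    "s": ivlev(a, pcts[c]),
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["year", "month", "habitat", "n_flocks", "use_pct", "s"]
    )


def electivity_table(
    flocks: Iterable[FlockObservation],
    avail: AvailabilitySet,
    surveys: Sequence[int] | None = None,
    zero_use: str = "include",
) -> tuple[pd.DataFrame, int]:
    """Full per-class selection summary (one species at a time).

    Columns: flock count, use %, availability %, pooled s, per-survey mean s
    and sample SD. Returns the table and the excluded-flock count.
    """
    flocks = list(flocks)
    use, n_excluded = use_table(flocks, avail)
    pooled = pooled_electivity(flocks, avail)
    per_survey = per_survey_electivity(flocks, avail, surveys, zero_use)
    pcts = avail.percentages()
    df = pd.DataFrame(
        {
            "n_flocks": use["n_flocks"],
            "use_pct": use["use_pct"],
            "avail_pct": pd.Series(pcts),
            "s_pooled": pooled,
            "s_mean": per_survey["s_mean"],
            "s_sd": per_survey["s_sd"],
        }
    )
    df.index.name = "habitat"
    return df, n_excluded
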
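"""Distance-to-roost statistics and the between-species comparison.

Wintering cranes leave a communal roost each morning; how far each flock
forages from it is a one-number summary of spatial strategy. Because the same
transect was walked in repeated surveys, flock distances within a survey are
not independent. The species comparison therefore (a) permutes species labels
only within each survey stratum, preserving survey structure under the null,
and (b) fits a companion fixed-effects least-squares model
``distance ~ species + survey`` whose species F statistic is reported
alongside. The permutation p-value is the headline number.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .survey import FlockObservation, InputError, RoostSite


def distance_to_roost(x: float, y: float, roost: RoostSite) -> float:
    """Euclidean distance from a planar point (meters) to the roost, in km."""
    if not (math.isfinite(x) and math.isfinite(y)):
        raise InputError("distance_to_roost: non-finite coordinates")
    return math.hypot(x - roost.x, y - roost.y) / 1000.0


def roost_distances(
    flocks: Iterable[FlockObservation], roost: RoostSite
) -> pd.DataFrame:
    """Per-flock roost distances: flock_id, species, survey_id, distance_km."""
    records = [
        {
            "flock_id": f.flock_id,
            "species": f.species,
            "survey_id": f.survey_id,
            "distance_km": distance_to_roost(f.x, f.y, roost),
        }
        for f in flocks
    ]
    return pd.DataFrame.from_records(
        records, columns=["flock_id", "species", "survey_id", "distance_km"]
    )


def summarize_distances(records: pd.DataFrame) -> pd.DataFrame:
    """Per-species n, mean, sample SD and SE of distance_km.

    Both SD and SE are reported; for a single record the SD is undefined and
    flagged as 0 with a warning.
    """
    rows = {}
    for species, grp in records.groupby("species"):
        d = grp["distance_km"].to_numpy(dtype=float)
        n = len(d)
        if n == 1:
            warnings.warn(f"species {species!r}: single record, SD undefined (reported as 0)")
            sd = 0.0
        else:
            sd = float(d.std(ddof=1))
        rows[species] = {
            "n": n,
            "mean_km": float(d.mean()),
            "sd_km": sd,
            "se_km": sd / math.sqrt(n) if n > 0 else float("nan"),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "species"
    return df


def stratified_permutation_test(
    values: np.ndarray,
    labels: np.ndarray,
    strata: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-group mean-difference test permuting labels within strata.

    The statistic is ``mean(values | group1) - mean(values | group0)`` with
    groups in sorted label order, so exchanging the two label names negates
    the observed difference without touching the p-value. Labels are shuffled
    independently within each stratum, so per-stratum group counts (and hence
    overall group sizes) are preserved. Two-sided p-value with the add-one
    correction: ``p = (1 + #{|t*| >= |t|}) / (1 + n_perm)``, which can never
    be exactly zero.
    """
    if rng is None:
        rng = np.random.default_rng()
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    strata = np.asarray(strata)
    groups = sorted(pd.unique(labels))
    if len(groups) != 2:
        raise InputError(f"need exactly 2 label groups, got {groups}")
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} is very small; p-value resolution is coarse")
    z = (labels == groups[1]).astype(float)
    n1 = z.sum()
    n0 = len(z) - n1
    if n1 == 0 or n0 == 0:
        raise InputError("one label group is empty")
    total = values.sum()

    def stat_from_s1(s1: np.ndarray | float) -> np.ndarray | float:
        return s1 / n1 - (total - s1) / n0

    obs = float(stat_from_s1(float(values @ z)))
    # within-stratum shuffles: per stratum, n_perm independent permutations of
    # its label vector; the group-1 value sum is all the statistic needs
    s1 = np.zeros(n_perm)
    for s in pd.unique(strata):
        idx = np.nonzero(strata == s)[0]
        zs = np.tile(z[idx], (n_perm, 1))
        zs = rng.permuted(zs, axis=1)
        s1 += zs @ values[idx]
    perm_stats = stat_from_s1(s1)
    p = (1.0 + np.sum(np.abs(perm_stats) >= abs(obs) - 1e-12)) / (1.0 + n_perm)
    return obs, float(p)


def least_squares_comparison(records: pd.DataFrame) -> dict[str, float]:
    """Fixed-effects least-squares fit of distance on species + survey.

    Survey enters as a fixed blocking factor. Returns the species F statistic
    and p from the additive model, and the interaction F from the model with
    a species x survey interaction.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = records.copy()
    df["survey_id"] = df["survey_id"].astype("category")
    add = smf.ols("distance_km ~ C(species) + C(survey_id)", data=df).fit()
    a_add = anova_lm(add, typ=2)
    inter = smf.ols("distance_km ~ C(species) * C(survey_id)", data=df).fit()
    a_int = anova_lm(inter, typ=2)
    return {
        "f_species": float(a_add.loc["C(species)", "F"]),
        "p_species_f": float(a_add.loc["C(species)", "PR(>F)"]),
        "f_interaction": float(a_int.loc["C(species):C(survey_id)", "F"]),
        "p_interaction_f": float(a_int.loc["C(species):C(survey_id)", "PR(>F)"]),
    }


def species_comparison(
    records: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> dict[str, object]:
    """Compare mean roost distance between the two species.

    ``records`` is the output of :func:`roost_distances` (both species
    present). Returns the per-species means, observed difference, stratified
    permutation p-value (the headline), and the companion least-squares F
    statistics. ``seed`` is required for a reproducible permutation stream
    and is echoed in the result.
    """
    species = list(pd.unique(records["species"]))
    if len(species) != 2:
        raise InputError(f"need exactly 2 species, got {species}")
    shared = None
    for sp in species:
        surveys = set(records.loc[records["species"] == sp, "survey_id"])
        shared = surveys if shared is None else shared & surveys
    if len(shared) < 2:
        raise InputError("species must co-occur in at least 2 surveys")
    rng = np.random.default_rng(seed)
    obs, p = stratified_permutation_test(
        records["distance_km"].to_numpy(),
        records["species"].to_numpy(),
        records["survey_id"].to_numpy(),
        n_perm=n_perm,
        rng=rng,
    )
    summary = summarize_distances(records)
    ls = least_squares_comparison(records)
    return {
        "species": species,
        "mean_km": {sp: float(summary.loc[sp, "mean_km"]) for sp in species},
        "delta_km": obs,
        "p_permutation": p,
        "n_perm": n_perm,
        "seed": seed,
        **ls,
    }
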
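from datetime import date

import numpy as np
import pytest
from shapely.geometry import box

from cranehab.survey import AvailabilitySet, FlockObservation, HabitatMap, RoostSite


@pytest.fixture()
def small_map() -> HabitatMap:
    """Three adjacent rectangles: farmland | grassland sharing an edge at
    x = 100, marshland detached above."""
    return HabitatMap(
        [
            (box(0, 0, 100, 100), "farmland"),
            (box(100, 0, 200, 100), "grassland"),
            (box(20, 150, 60, 190), "marshland"),
        ]
    )


@pytest.fixture()
def paper_avail() -> AvailabilitySet:
    """The printed per-class available areas (hectares)."""
    return AvailabilitySet({"farmland": 2216.7, "marshland": 38.3, "grassland": 760.4})


@pytest.fixture()
def roost() -> RoostSite:
    return RoostSite(0.0, 0.0)


def make_flock(
    i: int = 0,
    survey_id: int = 1,
    month: int = 12,
    species: str = "BNC",
    x: float = 0.0,
    y: float = 0.0,
    count: int = 3,
    habitat: str = "unassigned",
    year: int = 2010,
) -> FlockObservation:
    return FlockObservation(
        flock_id=f"F{i}",
        survey_id=survey_id,
        date=date(year, month, 15),
        species=species,
        x=x,
        y=y,
        count=count,
        habitat=habitat,
    )


def flocks_with_habitat_counts(
    counts: dict[str, int], species: str = "BNC", survey_id: int = 1, start: int = 0
) -> list[FlockObservation]:
    """Flocks carrying pre-assigned habitats with the given per-class counts."""
    out = []
    i = start
    for habitat, n in counts.items():
        for _ in range(n):
            out.append(make_flock(i, survey_id=survey_id, species=species, habitat=habitat))
            i += 1
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
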
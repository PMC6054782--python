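import dataclasses
from datetime import date

import numpy as np
import pytest

from cranehab.survey import AvailabilitySet, InputError, availability_percentages
from cranehab.synth import (
    Patch,
    SpeciesParams,
    SyntheticScenario,
    expected_mean_distance,
    generate_flocks,
    generate_landscape,
    paper_mirror_scenario,
    scenario_from_dict,
    true_expected_use,
)


def uniform_species(lambda_km=1e6, flocks_per_survey=20):
    return SpeciesParams(
        weights={"farmland": 1.0, "marshland": 1.0, "grassland": 1.0},
        lambda_km=lambda_km,
        flocks_per_survey=flocks_per_survey,
    )


class TestLandscape:
    def test_default_availability_matches_study_proportions(self):
        habitat_map = generate_landscape(paper_mirror_scenario())
        pct = availability_percentages(habitat_map)
        assert pct == {"farmland": 73.5, "marshland": 1.3, "grassland": 25.2}
        avail = AvailabilitySet.from_map(habitat_map)
        assert avail.total_ha == pytest.approx(3015.4, abs=0.01)

    def test_single_patch_is_all_of_one_class(self):
        sc = paper_mirror_scenario().replace(
            patches=(Patch(0, 0, 1000, 1000, "farmland"),)
        )
        pct = availability_percentages(generate_landscape(sc))
        assert pct == {"farmland": 100.0}

    def test_empty_patch_list_rejected(self):
        with pytest.raises(InputError):
            generate_landscape(paper_mirror_scenario().replace(patches=()))

    def test_overlapping_patches_rejected(self):
        sc = paper_mirror_scenario().replace(
            patches=(
                Patch(0, 0, 1000, 1000, "farmland"),
                Patch(500, 0, 1500, 1000, "grassland"),
            )
        )
        with pytest.raises(InputError, match="overlap"):
            generate_landscape(sc)


class TestGenerateFlocks:
    def test_same_seed_same_flocks(self):
        sc = paper_mirror_scenario(seed=11)
        a = generate_flocks(sc)
        b = generate_flocks(sc)
        assert a == b

    def test_different_seed_different_locations(self):
        a = generate_flocks(paper_mirror_scenario(seed=1))
        b = generate_flocks(paper_mirror_scenario(seed=2))
        assert any(f1.x != f2.x for f1, f2 in zip(a, b))

    def test_survey_design_is_respected(self):
        sc = paper_mirror_scenario(seed=0)
        flocks = generate_flocks(sc)
        months = {sid: d.month for sid, d in sc.surveys}
        per_survey = {sid: 0 for sid, _ in sc.surveys}
        for f in flocks:
            assert f.date.month == months[f.survey_id]
            if f.species == "BNC":
                per_survey[f.survey_id] += 1
        assert set(per_survey.values()) == {sc.species["BNC"].flocks_per_survey}
        assert sorted({m for m in months.values()}) == [1, 2, 3, 11, 12]

    def test_counts_positive_and_bounded(self):
        flocks = generate_flocks(paper_mirror_scenario(seed=5))
        assert all(1 <= f.count <= 60 for f in flocks)

    def test_zero_weights_rejected(self):
        with pytest.raises(InputError):
            SyntheticScenario(
                patches=paper_mirror_scenario().patches,
                roost=paper_mirror_scenario().roost,
                species={
                    "BNC": SpeciesParams(
                        weights={"farmland": 0.0}, lambda_km=1.0, flocks_per_survey=5
                    )
                },
            )

    def test_uniform_weights_recover_availability(self):
        # w uniform, lambda -> infinity: use fractions converge to the
        # availability fractions (within 3 pp at ~2,000 flocks)
        sc = paper_mirror_scenario(seed=17).replace(
            species={"BNC": uniform_species(flocks_per_survey=170)}
        )
        flocks = generate_flocks(sc)
        assert len(flocks) == 2040
        habitat_map = generate_landscape(sc)
        classes = habitat_map.assign_many(
            np.array([f.x for f in flocks]), np.array([f.y for f in flocks])
        )
        for cls, expected in (("farmland", 0.735), ("marshland", 0.013), ("grassland", 0.252)):
            frac = (classes == cls).mean()
            assert frac == pytest.approx(expected, abs=0.03)

    def test_exclusive_weight_gives_exclusive_use(self):
        sc = paper_mirror_scenario(seed=3).replace(
            species={
                "BNC": SpeciesParams(
                    weights={"farmland": 1.0, "marshland": 0.0, "grassland": 0.0},
                    lambda_km=2.0,
                    flocks_per_survey=10,
                )
            }
        )
        flocks = generate_flocks(sc)
        habitat_map = generate_landscape(sc)
        classes = habitat_map.assign_many(
            np.array([f.x for f in flocks]), np.array([f.y for f in flocks])
        )
        assert set(classes) == {"farmland"}

    def test_smaller_lambda_means_shorter_distances(self):
        sc = paper_mirror_scenario(seed=23)
        sc.species["BNC"] = dataclasses.replace(
            sc.species["BNC"], lambda_km=1.0, flocks_per_survey=42, monthly_weights={}
        )
        sc.species["CC"] = dataclasses.replace(
            sc.species["CC"], lambda_km=8.0, flocks_per_survey=42
        )
        flocks = generate_flocks(sc)
        roost = sc.roost
        d = {
            sp: np.mean(
                [np.hypot(f.x - roost.x, f.y - roost.y) for f in flocks if f.species == sp]
            )
            for sp in ("BNC", "CC")
        }
        assert d["BNC"] < d["CC"]


class TestGroundTruth:
    def test_infinite_lambda_limit_is_area_weighted(self):
        sc = paper_mirror_scenario().replace(species={"BNC": uniform_species()})
        mu = true_expected_use(sc, "BNC", month=11, step=50.0)
        total = 2216.7 + 38.3 + 760.4
        assert mu["farmland"] == pytest.approx(2216.7 / total, abs=1e-4)
        assert mu["marshland"] == pytest.approx(38.3 / total, abs=1e-4)
        assert mu["grassland"] == pytest.approx(760.4 / total, abs=1e-4)

    def test_single_class_is_certain(self):
        sc = paper_mirror_scenario().replace(
            patches=(Patch(0, 0, 1000, 1000, "farmland"),),
            roost=paper_mirror_scenario().roost.__class__(500.0, 500.0),
            species={
                "BNC": SpeciesParams(
                    weights={"farmland": 1.0}, lambda_km=1.0, flocks_per_survey=5
                )
            },
        )
        assert true_expected_use(sc, "BNC", month=11)["farmland"] == 1.0

    def test_quadrature_agrees_with_monte_carlo(self):
        # two-oracle cross-check on the default roost-bound species
        sc = paper_mirror_scenario(seed=29)
        sc.species["BNC"] = dataclasses.replace(
            sc.species["BNC"], flocks_per_survey=1
        )
        mu = true_expected_use(sc, "BNC", month=11, step=10.0)
        from cranehab.synth import _sample_locations

        rng = np.random.default_rng(29)
        locs = _sample_locations(
            sc, sc.species["BNC"].weights_for_month(11), sc.species["BNC"].lambda_km,
            100_000, rng,
        )
        habitat_map = generate_landscape(sc)
        classes = habitat_map.assign_many(locs[:, 0], locs[:, 1])
        for cls, p in mu.items():
            assert (classes == cls).mean() == pytest.approx(p, abs=0.005)

    def test_expected_distance_orders_with_lambda(self):
        sc = paper_mirror_scenario()
        near = dataclasses.replace(sc.species["BNC"], lambda_km=1.0, monthly_weights={})
        far = dataclasses.replace(sc.species["BNC"], lambda_km=6.0, monthly_weights={})
        sc2 = sc.replace(species={"near": near, "far": far})
        assert expected_mean_distance(sc2, "near", step=50.0) < expected_mean_distance(
            sc2, "far", step=50.0
        )

    def test_default_scenario_emulates_study_distances(self):
        sc = paper_mirror_scenario()
        assert expected_mean_distance(sc, "BNC", step=25.0) == pytest.approx(1.89, abs=0.05)
        assert expected_mean_distance(sc, "CC", step=25.0) == pytest.approx(4.38, abs=0.05)

    def test_ud_area_grows_with_lambda(self):
        # weaker roost attraction spreads flocks: the 90% isopleth area
        # cannot shrink on average (Monte-Carlo trend over replicates)
        from cranehab.locoh import isopleths

        areas = {1.0: [], 4.0: []}
        for lam, store in areas.items():
            for seed in range(10):
                sc = paper_mirror_scenario(seed=seed)
                sc.species = {
                    "BNC": SpeciesParams(
                        weights={"farmland": 1.0, "marshland": 0.2, "grassland": 0.2},
                        lambda_km=lam,
                        flocks_per_survey=12,
                    )
                }
                flocks = generate_flocks(sc)
                pts = np.array([[f.x, f.y] for f in flocks])
                store.append(isopleths(pts, r=500).area_ha[0.9])
        assert np.mean(areas[1.0]) < np.mean(areas[4.0])


class TestScenarioConfig:
    def test_round_trip_from_dict(self):
        cfg = {
            "seed": 7,
            "patches": [
                {"xmin": 0, "ymin": 0, "xmax": 1000, "ymax": 1000, "habitat": "farmland"},
                {"xmin": 1000, "ymin": 0, "xmax": 1200, "ymax": 1000, "habitat": "marshland"},
            ],
            "roost": {"x": 500, "y": 500},
            "species": {
                "BNC": {
                    "weights": {"farmland": 1, "marshland": 2},
                    "lambda_km": 1.5,
                    "flocks_per_survey": 8,
                    "monthly_weights": {"2": {"marshland": 5.0}},
                }
            },
            "surveys": [{"id": 1, "date": "2010-11-15"}, {"id": 2, "date": "2011-02-10"}],
        }
        sc = scenario_from_dict(cfg)
        assert sc.seed == 7
        assert len(sc.patches) == 2
        assert sc.roost.x == 500
        assert sc.species["BNC"].monthly_weights[2]["marshland"] == 5.0
        assert sc.surveys[1] == (2, date(2011, 2, 10))

    def test_defaults_fill_missing_sections(self):
        sc = scenario_from_dict({"seed": 3})
        assert sc.seed == 3
        assert {p.habitat for p in sc.patches} >= {"farmland", "marshland", "grassland"}
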
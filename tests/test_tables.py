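"""Response-table assembly, standardization, and descriptive comparisons."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from farmvisits.detection import aggregate_visit_days, coverage_and_eligibility
from farmvisits.periods import Semester, semester_of, semester_range
from farmvisits.tables import (
    back_transform,
    build_farm_table,
    build_vulture_tables,
    descriptive_comparisons,
    standardize,
)


class TestSemester:
    def test_breeding_flag(self):
        assert Semester(2014, 1).breeding == 1
        assert Semester(2014, 2).breeding == 0

    def test_calendar_lengths(self):
        assert Semester(2014, 1).n_days == 181  # non-leap first half
        assert Semester(2016, 1).n_days == 182  # leap year
        assert Semester(2014, 2).n_days == 184

    def test_labels_and_ranges(self):
        sems = semester_range(Semester(2013, 2), 3)
        assert [s.label for s in sems] == ["2013-S2", "2014-S1", "2014-S2"]
        assert semester_of(dt.date(2014, 6, 30)).label == "2014-S1"
        assert semester_of(dt.date(2014, 7, 1)).label == "2014-S2"


@pytest.fixture(scope="module")
def pipeline_pieces(small_dataset):
    ds = small_dataset
    fixes = ds.fixes.copy()
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"], utc=True)
    semesters = ds.config.semesters
    vd = aggregate_visit_days(fixes, ds.farm_areas, ds.dem)
    cov = coverage_and_eligibility(fixes, semesters)
    return ds, fixes, vd, cov, semesters


class TestBuildFarmTable:
    def test_row_structure_and_denominators(self, pipeline_pieces):
        ds, fixes, vd, cov, semesters = pipeline_pieces
        table = build_farm_table(vd, cov, ds.farm_areas, ds.landscape, semesters)
        assert (table["numerator"] <= table["denominator"]).all()
        assert (table["denominator"] >= 1).all()
        # denominator is per semester: all rows of a semester share it
        assert (table.groupby("semester")["denominator"].nunique() == 1).all()
        # numerator counts distinct birds, never more than eligible birds
        elig = cov[cov["eligible"]].groupby("semester")["bird_id"].nunique()
        for sem, grp in table.groupby("semester"):
            assert grp["denominator"].iloc[0] == elig[sem]

    def test_distinct_bird_counting(self, pipeline_pieces):
        ds, fixes, vd, cov, semesters = pipeline_pieces
        table = build_farm_table(vd, cov, ds.farm_areas, ds.landscape, semesters)
        sem = semesters[0].label
        eligible = set(cov[(cov["semester"] == sem) & cov["eligible"]]["bird_id"])
        vd2 = vd.copy()
        vd2["semester"] = [Semester(d.year, 1 if d.month <= 6 else 2).label for d in vd2["date"]]
        sub = vd2[(vd2["semester"] == sem) & vd2["bird_id"].isin(eligible)]
        want = sub.groupby("area_id")["bird_id"].nunique()
        got = table[table["semester"] == sem].set_index("area_id")["numerator"]
        for area_id, n in want.items():
            assert got[area_id] == n

    def test_no_visits_keeps_denominators(self, pipeline_pieces):
        ds, fixes, vd, cov, semesters = pipeline_pieces
        empty = vd.iloc[:0]
        table = build_farm_table(empty, cov, ds.farm_areas, ds.landscape, semesters)
        assert (table["numerator"] == 0).all()
        assert (table["denominator"] >= 1).all()

    def test_inactive_farm_has_no_row(self, pipeline_pieces):
        ds, fixes, vd, cov, semesters = pipeline_pieces
        farms_by_id = {f.farm_id: f for f in ds.farm_objects}
        inactive = [
            f.farm_id for f in ds.farm_objects if not f.is_active(semesters[-1].label)
        ]
        if not inactive:
            pytest.skip("no inactive farm drawn in this configuration")
        table = build_farm_table(
            vd, cov, ds.farm_areas, ds.landscape, semesters, farms_by_id
        )
        dead_areas = {
            a.area_id
            for a in ds.farm_areas
            if not a.is_active(semesters[-1].label, farms_by_id)
        }
        sub = table[table["semester"] == semesters[-1].label]
        assert dead_areas.isdisjoint(set(sub["area_id"]))


@pytest.fixture(scope="module")
def vulture_tables(pipeline_pieces):
    from farmvisits.geometry import BirdContext
    from farmvisits.homerange import compute_home_range

    ds, fixes, vd, cov, semesters = pipeline_pieces
    contexts, ranges = {}, {}
    birds = ds.birds.set_index("bird_id")
    nests = [
        (r.nest_x, r.nest_y)
        for r in ds.birds.itertuples()
        if r.territorial and np.isfinite(r.nest_x)
    ]
    for rec in cov[cov["eligible"]].itertuples():
        sem = Semester.from_label(rec.semester)
        sub = fixes[
            (fixes["bird_id"] == rec.bird_id)
            & (fixes["timestamp"].dt.date >= sem.start)
            & (fixes["timestamp"].dt.date <= sem.end)
        ]
        if not len(sub):
            continue
        hr = compute_home_range(
            rec.bird_id, rec.semester, sub[["x", "y"]].to_numpy(), ds.farm_areas,
            cell_size=150,
        )
        b = birds.loc[rec.bird_id]
        ranges[(rec.bird_id, rec.semester)] = hr
        contexts[(rec.bird_id, rec.semester)] = BirdContext(
            bird_id=rec.bird_id,
            semester=rec.semester,
            territorial=bool(b["territorial"]),
            own_nest=(b["nest_x"], b["nest_y"]) if b["territorial"] else None,
            occupied_nests=nests,
            k50_polygons=hr.k50_polygons,
            area_k95_km2=hr.area_k95_km2,
            sex=b["sex"],
            age=sem.year - int(b["birth_year"]),
            success=int(b["success"][rec.semester]),
        )
    terr, nonterr = build_vulture_tables(
        vd, cov, contexts, ranges, ds.farm_areas, ds.landscape, semesters
    )
    return ds, terr, nonterr, ranges, cov


class TestBuildVultureTables:
    def test_numerator_bounded_by_tracked_days(self, vulture_tables):
        _, terr, nonterr, _, _ = vulture_tables
        for table in (terr, nonterr):
            assert (table["numerator"] <= table["denominator"]).all()
            assert (table["denominator"] >= 1).all()

    def test_rows_only_for_candidate_farms(self, vulture_tables):
        _, terr, nonterr, ranges, _ = vulture_tables
        both = pd.concat([terr, nonterr])
        for (bird, sem), grp in both.groupby(["bird_id", "semester"]):
            assert set(grp["area_id"]) <= set(ranges[(bird, sem)].candidate_areas)

    def test_territorial_rows_carry_nest_fields(self, vulture_tables):
        _, terr, nonterr, _, _ = vulture_tables
        if len(terr):
            assert "dist_nest" in terr.columns and terr["dist_nest"].notna().all()
            assert "success" in terr.columns
        if len(nonterr):
            assert "dist_nest" not in nonterr.columns or nonterr["dist_nest"].isna().all()

    def test_denominator_equals_coverage_days(self, vulture_tables):
        _, terr, nonterr, _, cov = vulture_tables
        ndays = cov.set_index(["bird_id", "semester"])["n_days"]
        both = pd.concat([terr, nonterr])
        for r in both.itertuples():
            assert r.denominator == ndays[(r.bird_id, r.semester)]


class TestStandardize:
    def test_zscore_postcondition(self, rng):
        rows = pd.DataFrame(
            {
                "dist_road": rng.uniform(0, 5000, 100),
                "goat_sheep": rng.lognormal(5, 1, 100),
                "breeding": rng.integers(0, 2, 100),
            }
        )
        scaled, scaler = standardize(rows, ("dist_road", "goat_sheep", "breeding"))
        for c in ("dist_road", "goat_sheep"):
            assert scaled[c].mean() == pytest.approx(0.0, abs=1e-10)
            assert scaled[c].std(ddof=0) == pytest.approx(1.0, abs=1e-10)
        # factors untouched
        assert set(scaled["breeding"]) <= {0, 1}

    def test_roundtrip(self, rng):
        rows = pd.DataFrame({"dist_road": rng.uniform(0, 5000, 50)})
        scaled, scaler = standardize(rows, ("dist_road",))
        back = back_transform(scaled["dist_road"], "dist_road", scaler)
        assert back == pytest.approx(rows["dist_road"].to_numpy())

    def test_constant_column_dropped(self):
        rows = pd.DataFrame({"dist_road": np.ones(10), "goat_sheep": np.arange(10.0)})
        scaled, _ = standardize(rows, ("dist_road", "goat_sheep"))
        assert "dist_road" not in scaled.columns


class TestDescriptiveComparisons:
    def make_stats(self, rng, male_shift=0.0):
        rows = []
        for i in range(40):
            terr = i % 2 == 0
            sex = "M" if i % 4 < 2 else "F"
            for breeding in (0, 1):
                visited = rng.poisson(10 + (male_shift if sex == "M" else 0))
                rows.append(
                    {
                        "bird_id": f"B{i}",
                        "semester": f"2014-S{2 - breeding}",
                        "territorial": terr,
                        "sex": sex,
                        "breeding": breeding,
                        "n_farms_hr": visited + rng.poisson(5),
                        "n_farms_visited": visited,
                        "area_k95": visited * 3 + rng.normal(0, 1),
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_groups_give_large_p(self, rng):
        out = descriptive_comparisons(self.make_stats(rng))
        sex_rows = out[(out["comparison"] == "sex") & out["p"].notna()]
        assert (sex_rows["p"] > 0.01).all()

    def test_strong_sex_difference_detected(self, rng):
        out = descriptive_comparisons(self.make_stats(rng, male_shift=15.0))
        sex_rows = out[
            (out["comparison"] == "sex") & (out["metric"] == "n_farms_visited")
        ]
        assert (sex_rows["p"] < 0.05).any()

    def test_strong_dependence_gives_high_rho(self, rng):
        out = descriptive_comparisons(self.make_stats(rng))
        rho = out.loc[out["comparison"] == "spearman", "rho"].iloc[0]
        assert rho > 0.7
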
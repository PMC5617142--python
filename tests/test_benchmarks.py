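"""Water benchmark selection/quotients and sediment guideline tiers."""

import numpy as np
import pandas as pd
import pytest

from cecscreen.benchmarks import (
    exceedance_quotients,
    sediment_quotients,
    sediment_tiers,
    select_water_benchmark,
    site_exceedance_census,
    summarize_by_river,
    tier_classify,
)
from cecscreen.model import (
    BenchmarkSet,
    ConfigurationError,
    SiteMaxMatrix,
    SiteRecord,
)
from helpers_oracle import brute_force_census


def smax_from(entries, matrix="water"):
    df = pd.DataFrame(entries).T
    df.index.name = "site_id"
    df.columns.name = "chemical_id"
    return SiteMaxMatrix(df.astype(float).fillna(0.0), matrix)


class TestBenchmarkSelection:
    def test_lowest_chronic_wins(self):
        bset = BenchmarkSet(water={"X": [(0.5, "chronic", ""), (0.3, "chronic", "")]})
        assert select_water_benchmark("X", bset) == 0.3

    def test_acute_fallback_when_no_chronic(self):
        bset = BenchmarkSet(water={"X": [(1.2, "acute", "")]})
        assert select_water_benchmark("X", bset) == 1.2

    def test_chronic_preferred_over_lower_acute(self):
        bset = BenchmarkSet(
            water={"X": [(0.9, "chronic", ""), (0.1, "acute", "")]}
        )
        assert select_water_benchmark("X", bset) == 0.9

    def test_absent_chemical_has_no_benchmark(self):
        assert select_water_benchmark("X", BenchmarkSet()) is None


class TestQuotients:
    BSET = BenchmarkSet(water={"FLU": [(0.04, "chronic", "")]})

    def test_published_maximum_over_benchmark(self):
        report = exceedance_quotients(smax_from({"S1": {"FLU": 0.671}}), self.BSET)
        assert report.quotients.loc["S1", "FLU"] == pytest.approx(16.775)
        assert report.exceeded.loc["S1", "FLU"]

    def test_quotient_exactly_one_is_flagged(self):
        report = exceedance_quotients(smax_from({"S1": {"FLU": 0.04}}), self.BSET)
        assert report.quotients.loc["S1", "FLU"] == pytest.approx(1.0)
        assert report.exceeded.loc["S1", "FLU"]

    def test_never_detected_gives_zero_unflagged(self):
        report = exceedance_quotients(smax_from({"S1": {"FLU": 0.0}}), self.BSET)
        assert report.quotients.loc["S1", "FLU"] == 0.0
        assert not report.exceeded.loc["S1", "FLU"]
        assert not report.detected.loc["S1", "FLU"]

    def test_unbenchmarked_chemical_omitted(self):
        report = exceedance_quotients(
            smax_from({"S1": {"FLU": 0.1, "ZZZ": 5.0}}), self.BSET
        )
        assert list(report.quotients.columns) == ["FLU"]

    def test_doubling_concentration_doubles_quotient(self):
        q1 = exceedance_quotients(smax_from({"S1": {"FLU": 0.1}}), self.BSET)
        q2 = exceedance_quotients(smax_from({"S1": {"FLU": 0.2}}), self.BSET)
        assert q2.quotients.loc["S1", "FLU"] == pytest.approx(
            2 * q1.quotients.loc["S1", "FLU"]
        )


class TestTierClassification:
    GUIDELINE = (423.0, 1327.0, 2230.0)  # fluoranthene TEC/MEC/PEC

    def test_published_maximum_classifies_as_pec(self):
        assert tier_classify(20800.0, self.GUIDELINE) == "PEC"

    @pytest.mark.parametrize(
        "value,tier",
        [
            (0.0, "below_TEC"),
            (423.0, "TEC"),       # boundaries are inclusive
            (1327.0, "MEC"),
            (2230.0, "PEC"),
            (500.0, "TEC"),
            (2000.0, "MEC"),
        ],
    )
    def test_tier_boundaries(self, value, tier):
        assert tier_classify(value, self.GUIDELINE) == tier

    def test_unordered_guideline_rejected(self):
        with pytest.raises(ConfigurationError):
            tier_classify(1.0, (10.0, 5.0, 20.0))

    def test_tier_monotone_in_concentration(self):
        order = {"below_TEC": 0, "TEC": 1, "MEC": 2, "PEC": 3}
        values = np.linspace(0, 3000, 97)
        tiers = [order[tier_classify(v, self.GUIDELINE)] for v in values]
        assert tiers == sorted(tiers)


SITES = {
    "S1": SiteRecord("S1", "R1"),
    "S2": SiteRecord("S2", "R1"),
    "S3": SiteRecord("S3", "R1"),
    "S4": SiteRecord("S4", "R1"),
    "S5": SiteRecord("S5", "R2"),
}


class TestRiverSummary:
    BSET = BenchmarkSet(water={"X": [(1.0, "chronic", "")]})

    def test_one_of_four_detected_sites_is_25_percent(self):
        smax = smax_from(
            {
                "S1": {"X": 2.0},
                "S2": {"X": 0.5},
                "S3": {"X": 0.5},
                "S4": {"X": 0.5},
                "S5": {"X": 0.0},
            }
        )
        report = exceedance_quotients(smax, self.BSET)
        summary = summarize_by_river(report, SITES)
        assert summary.loc["R1", "X"] == pytest.approx(25.0)

    def test_river_without_detection_marked_not_detected(self):
        smax = smax_from({"S1": {"X": 2.0}, "S5": {"X": 0.0}})
        sites = {"S1": SITES["S1"], "S5": SITES["S5"]}
        summary = summarize_by_river(
            exceedance_quotients(smax, self.BSET), sites
        )
        assert summary.loc["R2", "X"] == "--"
        assert summary.loc["R1", "X"] == pytest.approx(100.0)

    def test_sampled_denominator_option(self):
        smax = smax_from(
            {"S1": {"X": 2.0}, "S2": {"X": 0.0}, "S3": {"X": 0.0},
             "S4": {"X": 0.0}, "S5": {"X": 0.0}}
        )
        report = exceedance_quotients(smax, self.BSET)
        detected = summarize_by_river(report, SITES, "detected")
        sampled = summarize_by_river(report, SITES, "sampled")
        assert detected.loc["R1", "X"] == pytest.approx(100.0)
        assert sampled.loc["R1", "X"] == pytest.approx(25.0)

    def test_random_fixture_matches_count_oracle(self):
        rng = np.random.default_rng(13)
        entries = {
            s: {c: float(rng.choice([0.0, 0.5, 2.0])) for c in "XY"}
            for s in SITES
        }
        bset = BenchmarkSet(
            water={"X": [(1.0, "chronic", "")], "Y": [(1.0, "chronic", "")]}
        )
        report = exceedance_quotients(smax_from(entries), bset)
        summary = summarize_by_river(report, SITES)
        for river in ("R1", "R2"):
            members = [s for s in SITES if SITES[s].river == river]
            for chem in "XY":
                det = [s for s in members if entries[s][chem] > 0]
                exc = [s for s in members if entries[s][chem] >= 1.0]
                expected = "--" if not det else 100.0 * len(exc) / len(det)
                got = summary.loc[river, chem]
                if expected == "--":
                    assert got == "--"
                else:
                    assert got == pytest.approx(expected)
        assert (
            summary.loc["Basin Wide", "n_sites"]
            == summary.drop(index="Basin Wide")["n_sites"].sum()
        )


class TestCensus:
    def test_empty_report_counts_zero(self):
        bset = BenchmarkSet(water={"X": [(1.0, "chronic", "")]})
        smax = smax_from({s: {"X": 0.0} for s in SITES})
        census = site_exceedance_census(exceedance_quotients(smax, bset), SITES)
        assert census["n_sites_exceeding"] == 0
        assert census["chemicals_exceeded"] == []

    def test_every_site_flagged_is_100_percent(self):
        bset = BenchmarkSet(water={"X": [(1.0, "chronic", "")]})
        smax = smax_from({s: {"X": 2.0} for s in SITES})
        census = site_exceedance_census(exceedance_quotients(smax, bset), SITES)
        assert census["percent_sites_exceeding"] == pytest.approx(100.0)
        assert census["n_rivers_exceeding"] == 2

    def test_random_fixture_matches_brute_force(self):
        rng = np.random.default_rng(17)
        entries = {
            s: {c: float(rng.uniform(0, 2)) for c in "XYZ"} for s in SITES
        }
        bset = BenchmarkSet(
            water={c: [(1.0, "chronic", "")] for c in "XYZ"}
        )
        report = exceedance_quotients(smax_from(entries), bset)
        census = site_exceedance_census(report, SITES)
        oracle = brute_force_census(
            report.exceeded, {s: SITES[s].river for s in SITES}
        )
        for key, value in oracle.items():
            assert census[key] == value


class TestSedimentScreen:
    BSET = BenchmarkSet(sediment={"FLU": (423.0, 1327.0, 2230.0)})

    def test_tier_table_and_tec_quotients_consistent(self):
        smax = smax_from(
            {"S1": {"FLU": 20800.0}, "S2": {"FLU": 500.0}, "S3": {"FLU": 0.0}},
            matrix="sediment",
        )
        tiers = sediment_tiers(smax, self.BSET)
        assert tiers["FLU"].tolist() == ["PEC", "TEC", "below_TEC"]
        q = sediment_quotients(smax, self.BSET, "TEC")
        assert q.exceeded["FLU"].tolist() == [True, True, False]
        q_pec = sediment_quotients(smax, self.BSET, "PEC")
        assert q_pec.exceeded["FLU"].tolist() == [True, False, False]
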
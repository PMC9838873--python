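"""Unit conversion, outlier exclusion, aggregation and coverage statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gabatlas.literature import (
    LiteratureRecord,
    aggregate_region,
    build_region_literature,
    coverage_summary,
    exclude_outliers,
    parse_review_excel,
    purely_inhibitory_records,
    read_literature_csv,
    to_count,
    to_density,
    write_literature_csv,
)


def rec(value, kind="density", marker="PV", region=3, std=None, source="s1"):
    return LiteratureRecord(source, marker, region, kind, value, std)


class TestToCount:
    def test_density_times_volume(self):
        mean, std = to_count(rec(200.0, std=10.0), {3: 0.5})
        assert mean == 100.0 and std == 5.0

    def test_count_unchanged(self):
        mean, std = to_count(rec(317.0, kind="count"), {3: 0.5})
        assert mean == 317.0 and std is None

    def test_percentage_of_neurons(self):
        mean, _ = to_count(rec(10.0, kind="pct_neurons"), {3: 1.0}, neuron_counts={3: 5000})
        assert mean == 500.0

    def test_percentage_of_cells(self):
        mean, _ = to_count(rec(5.0, kind="pct_cells"), {3: 1.0}, cell_counts={3: 10000})
        assert mean == 500.0

    def test_density_with_zero_volume_rejected(self):
        with pytest.raises(ValueError, match="zero annotated volume"):
            to_count(rec(200.0), {3: 0.0})

    def test_percentage_without_reference_rejected(self):
        with pytest.raises(ValueError, match="without nNeu"):
            to_count(rec(10.0, kind="pct_neurons"), {3: 1.0})

    def test_count_density_round_trip(self):
        vols = {3: 0.37}
        r = rec(123.0, kind="count")
        dens, _ = to_density(r, vols)
        back, _ = to_count(rec(dens, kind="density"), vols)
        assert back == pytest.approx(123.0)


class TestExcludeOutliers:
    def test_high_outlier_removed(self):
        records = [rec(100, source="a"), rec(120, source="b"), rec(700, source="c")]
        kept, excluded = exclude_outliers(records, [100, 120, 700])
        assert kept == [0, 1]
        assert excluded[0][0] == 2

    def test_below_ratio_kept(self):
        kept, excluded = exclude_outliers([rec(100), rec(450)], [100, 450])
        assert kept == [0, 1] and excluded == []

    def test_single_record_kept(self):
        kept, excluded = exclude_outliers([rec(5)], [5])
        assert kept == [0] and excluded == []

    def test_low_outlier_removed(self):
        kept, excluded = exclude_outliers(
            [rec(10), rec(100), rec(120)], [10, 100, 120]
        )
        assert kept == [1, 2] and excluded[0][0] == 0

    @settings(derandomize=True, max_examples=25)
    @given(st.permutations([100.0, 120.0, 700.0, 90.0]))
    def test_order_independent(self, means):
        records = [rec(m, source=f"s{i}") for i, m in enumerate(means)]
        kept, excluded = exclude_outliers(records, list(means))
        kept_means = sorted(means[i] for i in kept)
        assert kept_means == [90.0, 100.0, 120.0]


class TestAggregateRegion:
    def test_single_record_identity(self):
        assert aggregate_region([(100.0, 20.0)]) == (100.0, 20.0)

    def test_mean_of_means_and_stds(self):
        assert aggregate_region([(100.0, 20.0), (200.0, 40.0)]) == (150.0, 30.0)

    def test_absent_std_averaged_over_available(self):
        assert aggregate_region([(100.0, 20.0), (200.0, None)]) == (150.0, 20.0)

    def test_sigma_floor_when_no_stds(self):
        eta, sigma = aggregate_region([(100.0, None)], sigma_floor_fraction=0.1)
        assert (eta, sigma) == (100.0, 10.0)

    @settings(derandomize=True, max_examples=25)
    @given(
        st.lists(st.tuples(st.floats(0.1, 1e5), st.floats(0.01, 1e4)), min_size=1, max_size=6),
        st.floats(0.1, 10),
    )
    def test_permutation_invariant_and_scale_equivariant(self, counts, c):
        eta, sigma = aggregate_region(counts)
        eta_p, sigma_p = aggregate_region(list(reversed(counts)))
        assert eta == pytest.approx(eta_p) and sigma == pytest.approx(sigma_p)
        eta_s, sigma_s = aggregate_region([(m * c, s * c) for m, s in counts])
        assert eta_s == pytest.approx(c * eta, rel=1e-9)
        assert sigma_s == pytest.approx(c * sigma, rel=1e-9)


class TestPurelyInhibitory(object):
    def test_record_equals_neuron_count(self, small_tree):
        records, flagged = purely_inhibitory_records([3], {3: 1000.0}, small_tree)
        assert len(records) == 1
        assert records[0].marker == "GAD67" and records[0].value == 1000.0
        assert flagged == {3}

    def test_empty_list(self, small_tree):
        records, flagged = purely_inhibitory_records([], {}, small_tree)
        assert records == [] and flagged == set()

    def test_unknown_region_rejected(self, small_tree):
        with pytest.raises(ValueError, match="unknown"):
            purely_inhibitory_records([99], {99: 1.0}, small_tree)


def _records_with_cvs(cv_targets, region_ids, marker="PV"):
    """Two sources per region whose sample-std CV equals the target."""
    out = []
    for cv, rid in zip(cv_targets, region_ids):
        mean = 100.0
        d = cv * mean / np.sqrt(2.0)  # std([m-d, m+d], ddof=1) = d*sqrt(2)
        out.append(rec(mean - d, region=rid, source=f"a{rid}", marker=marker))
        out.append(rec(mean + d, region=rid, source=f"b{rid}", marker=marker))
    return out


class TestCoverageSummary:
    def _hierarchy(self):
        from gabatlas.atlas import parse_hierarchy

        return parse_hierarchy(
            {"id": 1, "children": [{"id": i, "children": []} for i in range(2, 8)]}
        )

    def test_symmetric_cvs_zero_skew(self):
        h = self._hierarchy()
        records = _records_with_cvs([0.1, 0.2, 0.3], [2, 3, 4])
        vols = {r: 1.0 for r in h.ids}
        table = coverage_summary(records, h, vols)
        row = table.loc["PV"]
        assert row["median_cv"] == pytest.approx(0.2)
        assert row["cv_skewness"] == pytest.approx(0.0, abs=1e-9)
        assert row["n_regions"] == 3 and row["n_sources"] == 6

    def test_right_tailed_cvs_positive_skew(self):
        h = self._hierarchy()
        records = _records_with_cvs([0.1, 0.1, 0.7], [2, 3, 4])
        table = coverage_summary(records, h, {r: 1.0 for r in h.ids})
        row = table.loc["PV"]
        assert row["median_cv"] == pytest.approx(0.1)
        assert row["cv_skewness"] > 0

    def test_moment_skewness_formula(self):
        """The reported skewness is (1/n) * sum(((cv - mean)/std_pop)**3)."""
        h = self._hierarchy()
        cvs = [0.05, 0.12, 0.44, 0.3]
        records = _records_with_cvs(cvs, [2, 3, 4, 5])
        table = coverage_summary(records, h, {r: 1.0 for r in h.ids})
        arr = np.asarray(cvs)
        expected = np.mean(((arr - arr.mean()) / arr.std()) ** 3)
        assert table.loc["PV", "cv_skewness"] == pytest.approx(expected, rel=1e-6)

    def test_fewer_than_two_cvs_flagged(self):
        h = self._hierarchy()
        table = coverage_summary([rec(100, region=2)], h, {r: 1.0 for r in h.ids})
        assert np.isnan(table.loc["PV", "cv_skewness"])
        assert table.loc["PV", "region_fraction"] == pytest.approx(1 / 7)


class TestBuildRegionLiterature:
    def test_exclusion_and_aggregation_combined(self, small_tree):
        records = [
            rec(100, region=3, source="a", std=10),
            rec(120, region=3, source="b", std=20),
            rec(700, region=3, source="c"),
        ]
        out = build_region_literature(records, small_tree, {3: 1.0})
        lit = out[(3, "PV")]
        assert lit.eta == pytest.approx(110.0)
        assert lit.sigma == pytest.approx(15.0)
        assert lit.sources == ("a", "b") and lit.excluded[0][0] == "c"

    def test_drop_source_everywhere(self, small_tree):
        records = [rec(100, region=3, source="han"), rec(150, region=3, source="b")]
        out = build_region_literature(records, small_tree, {3: 1.0}, drop_sources=["han"])
        lit = out[(3, "PV")]
        assert lit.sources == ("b",)
        assert ("han", "source dropped globally") in lit.excluded


class TestPersistence:
    def test_csv_round_trip(self, tmp_path, small_tree):
        records = [
            rec(200.0, std=10.0, region=3, source="a"),
            rec(15.0, kind="pct_neurons", marker="GAD67", region=4, source="b"),
        ]
        path = tmp_path / "lit.csv"
        write_literature_csv(path, records)
        back = read_literature_csv(path, small_tree)
        assert [(r.source_id, r.marker, r.region_id, r.kind, r.value, r.std) for r in back] == [
            ("a", "PV", 3, "density", 200.0, 10.0),
            ("b", "GAD67", 4, "pct_neurons", 15.0, None),
        ]

    def test_review_spreadsheet_parsing(self, tmp_path, small_tree):
        df = pd.DataFrame(
            {
                "Source": ["Smith 2010", "Jones 2015", "Doe 2020"],
                "Marker": ["PV", "gad", "SST"],
                "Region": ["c2", "c2", "nope"],
                "Measurement type": ["density (cells/mm3)", "% of neurons", "cell count"],
                "Mean value": [1200.0, 25.0, 40.0],
                "SD": [100.0, None, 5.0],
            }
        )
        path = tmp_path / "review.xlsx"
        df.to_excel(path, index=False)
        records = parse_review_excel(path, small_tree)
        # the unknown-acronym row is skipped; GAD alias normalized
        assert len(records) == 2
        assert records[0].kind == "density" and records[0].region_id == 3
        assert records[1].marker == "GAD67" and records[1].kind == "pct_neurons"
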
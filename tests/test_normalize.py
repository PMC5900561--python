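"""Gene/intron filters (vs. brute-force rules), intron cluster selection,
normalization factors, and the enrichment QC statistic."""

import numpy as np
import pandas as pd
import pytest

from druid.matrix import EXON_COUNT, INTRON_COVERAGE, AbundanceMatrix, GenomePartition
from druid.normalize import (
    InsufficientSpikeInReads,
    NoFeaturesPassFilter,
    cluster_and_select_introns,
    enrichment_qc,
    filter_genes,
    filter_introns,
    intron_normalization_factors,
    normalize,
    spikein_normalization_factors,
)

TP = [1.0, 2.0, 4.0, 8.0, 12.0, 24.0]


def mat(rows: dict, kind=EXON_COUNT, tp=TP):
    return AbundanceMatrix(pd.DataFrame(rows, index=tp).T, kind=kind)


class TestFilterGenes:
    def test_boundary_row_passes_both_rules(self):
        m = mat({"g": [1, 1, 1, 1, 1, 5]})
        assert filter_genes(m).feature_ids == ["g"]

    def test_zero_time_point_drops_gene(self):
        m = mat({"g": [0, 9, 9, 9, 9, 9], "ok": [2, 2, 2, 2, 2, 9]})
        assert filter_genes(m).feature_ids == ["ok"]

    def test_never_reaching_five_drops_gene(self):
        m = mat({"g": [4, 4, 4, 4, 4, 4], "ok": [1, 1, 1, 1, 1, 5]})
        assert filter_genes(m).feature_ids == ["ok"]

    def test_empty_result_raises_naming_thresholds(self):
        with pytest.raises(NoFeaturesPassFilter, match="5"):
            filter_genes(mat({"g": [0, 0, 0, 0, 0, 0]}))

    def test_matches_brute_force_on_random_table(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 8, size=(300, 6)).astype(float)
        ids = [f"g{i}" for i in range(300)]
        m = AbundanceMatrix(pd.DataFrame(counts, index=ids, columns=TP))
        kept = set(filter_genes(m).feature_ids)
        expect = {
            ids[i]
            for i in range(300)
            if (counts[i] >= 1).all() and (counts[i] >= 5).any()
        }
        assert kept == expect


class TestFilterIntrons:
    def test_boundary_mean_exactly_half_kept(self):
        m = mat({"i": [0.5] * 6}, kind=INTRON_COVERAGE)
        assert filter_introns(m).feature_ids == ["i"]

    def test_all_zero_dropped(self):
        m = mat({"i": [0.0] * 6, "ok": [1.0] * 6}, kind=INTRON_COVERAGE)
        assert filter_introns(m).feature_ids == ["ok"]

    def test_matches_brute_force_row_means(self):
        rng = np.random.default_rng(4)
        cov = rng.exponential(0.6, size=(200, 6))
        ids = [f"i{j}" for j in range(200)]
        m = AbundanceMatrix(pd.DataFrame(cov, index=ids, columns=TP), kind=INTRON_COVERAGE)
        kept = set(filter_introns(m).feature_ids)
        assert kept == {ids[j] for j in range(200) if cov[j].mean() >= 0.5}


class TestClusterSelection:
    def test_single_decreasing_profile_selected(self):
        prof = np.array([4.0, 3.0, 2.5, 2.0, 1.5, 1.0])
        rows = {f"i{j}": prof * (1 + 0.001 * j) for j in range(8)}
        report = cluster_and_select_introns(mat(rows, kind=INTRON_COVERAGE), k=4, seed=0)
        assert set(report.selected_introns) == set(rows)

    def test_increasing_centroid_scores_worse_than_decreasing(self):
        from druid.normalize import _monotonicity_score

        t = np.array(TP)
        dec = _monotonicity_score(np.linspace(2, 0.5, 6), t)
        inc = _monotonicity_score(np.linspace(0.5, 2, 6), t)
        assert dec < inc

    def test_deterministic_and_order_invariant(self):
        rng = np.random.default_rng(5)
        rows = {f"i{j}": rng.uniform(0.5, 3, size=6) for j in range(40)}
        m1 = mat(rows, kind=INTRON_COVERAGE)
        shuffled = dict(reversed(list(rows.items())))
        m2 = mat(shuffled, kind=INTRON_COVERAGE)
        r1 = cluster_and_select_introns(m1, seed=9)
        r2 = cluster_and_select_introns(m2, seed=9)
        assert sorted(r1.selected_introns) == sorted(r2.selected_introns)
        pd.testing.assert_series_equal(r1.assignments, r2.assignments)

    def test_fewer_than_k_introns_falls_back_with_warning(self):
        rows = {"a": [3, 2, 2, 1, 1, 1], "b": [4, 3, 2, 2, 1, 1]}
        with pytest.warns(UserWarning, match="one cluster"):
            report = cluster_and_select_introns(mat(rows, kind=INTRON_COVERAGE), k=4, seed=0)
        assert set(report.selected_introns) == {"a", "b"}


class TestFactors:
    def test_intron_sum(self):
        m = AbundanceMatrix(
            pd.DataFrame({1.0: [2, 4], 2.0: [1, 1]}, index=["a", "b"]),
            kind=INTRON_COVERAGE,
        )
        fac = intron_normalization_factors(m, ["a", "b"])
        assert list(fac) == [6, 2]
        single = intron_normalization_factors(m, ["a"])
        assert list(single) == [2, 1]

    def test_zero_factor_names_time_point(self):
        m = AbundanceMatrix(
            pd.DataFrame({1.0: [1.0], 4.0: [0.0]}, index=["a"]), kind=INTRON_COVERAGE
        )
        with pytest.raises(ValueError, match="4.0"):
            intron_normalization_factors(m, ["a"])

    def test_missing_intron_id_raises(self):
        m = AbundanceMatrix(pd.DataFrame({1.0: [1.0], 2.0: [1.0]}, index=["a"]),
                            kind=INTRON_COVERAGE)
        with pytest.raises(KeyError):
            intron_normalization_factors(m, ["a", "ghost"])

    def test_factors_equal_brute_force_column_sums(self):
        rng = np.random.default_rng(6)
        cov = rng.uniform(0.5, 3.0, size=(1045, 6))
        ids = [f"i{j}" for j in range(1045)]
        m = AbundanceMatrix(pd.DataFrame(cov, index=ids, columns=TP), kind=INTRON_COVERAGE)
        fac = intron_normalization_factors(m, ids)
        np.testing.assert_allclose(fac.to_numpy(), cov.sum(axis=0))

    def test_spikein_factors_and_failures(self):
        totals = pd.DataFrame(
            {t: {"human": 8e5, "fly": 2e5} for t in TP}
        )
        part = GenomePartition(totals)
        fac = spikein_normalization_factors(part, "fly")
        assert (fac == 2e5).all()
        with pytest.raises(KeyError):
            spikein_normalization_factors(part, "worm")
        sparse = GenomePartition(totals.replace(2e5, 500.0))
        with pytest.raises(InsufficientSpikeInReads, match="insufficient"):
            spikein_normalization_factors(sparse, "fly")


class TestNormalize:
    def test_elementwise_quotient(self):
        m = AbundanceMatrix(pd.DataFrame({1.0: [10], 2.0: [20], 4.0: [30]}, index=["g"]))
        fac = pd.Series([10.0, 10.0, 10.0], index=[1.0, 2.0, 4.0])
        series = normalize(m, fac, "intron")
        assert list(series.data.loc["g"]) == [1, 2, 3]

    def test_factors_equal_to_counts_row_gives_ones(self):
        row = [3.0, 7.0, 11.0]
        m = AbundanceMatrix(pd.DataFrame({1.0: [3.0], 2.0: [7.0], 4.0: [11.0]}, index=["g"]))
        series = normalize(m, pd.Series(row, index=[1.0, 2.0, 4.0]), "intron")
        np.testing.assert_allclose(series.data.loc["g"], 1.0)

    def test_scale_invariance_per_time_point(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(1, 100, size=(20, 6)).astype(float)
        m = AbundanceMatrix(pd.DataFrame(counts, index=[f"g{i}" for i in range(20)], columns=TP))
        fac = pd.Series(rng.uniform(10, 20, 6), index=TP)
        base = normalize(m, fac, "intron")
        c = rng.uniform(0.5, 5.0, 6)
        scaled = AbundanceMatrix(m.data * c, kind=EXON_COUNT)
        same = normalize(scaled, fac * c, "intron")
        pd.testing.assert_frame_equal(base.data, same.data)

    def test_shape_mismatch_raises(self):
        m = AbundanceMatrix(pd.DataFrame({1.0: [1.0], 2.0: [1.0], 4.0: [1.0]}, index=["g"]))
        with pytest.raises(ValueError):
            normalize(m, pd.Series([1.0, 1.0], index=[1.0, 2.0]), "intron")


class TestEnrichmentQC:
    def _part(self, labeled, unlabeled):
        return GenomePartition(
            pd.DataFrame({1.0: {"lab": labeled, "unlab": unlabeled}})
        )

    def test_hundredfold(self):
        fold = enrichment_qc(self._part(1000, 100), self._part(100, 1000), "lab", "unlab")
        assert fold.iloc[0] == pytest.approx(100.0)

    def test_identical_partitions_give_unity(self):
        p = self._part(400, 600)
        assert enrichment_qc(p, p, "lab", "unlab").iloc[0] == pytest.approx(1.0)

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError):
            enrichment_qc(self._part(10, 0), self._part(10, 10), "lab", "unlab")
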
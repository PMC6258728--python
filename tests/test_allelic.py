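"""Allelic peak classification, restored peaks, escapees, rank/KS tests."""

import numpy as np
import pandas as pd
import pytest

from ximega.allelic import (classify_escapees, classify_peaks,
                            fold_change_cdf_test, restored_peaks,
                            xi_expression_density_compare)
from ximega.errors import DegenerateInputError, FormatError, JoinError
from ximega.synthetic_data import AllelicTableParams, simulate_allelic_peaks


def table(rows, genotype="wt", replicate="rep1"):
    recs = []
    for k, (xa, xi) in enumerate(rows):
        recs.append({"feature_id": f"p{k}", "chrom": "chrX",
                     "start": k * 1000, "end": k * 1000 + 500,
                     "reads_xa": xa, "reads_xi": xi,
                     "replicate": replicate, "genotype": genotype})
    return pd.DataFrame(recs)


def rule_oracle(xa, xi, min_reads=10, thr=1 / 3):
    """Direct restatement of the classification rule, kept deliberately
    separate from the vectorized implementation."""
    if xa + xi < min_reads:
        return "insufficient"
    r = xi / xa if xa > 0 else float("inf")
    if r <= thr:
        return "Xa_specific"
    if r >= 1 / thr:
        return "Xi_specific"
    return "biallelic"


EDGE_CASES = [
    (30, 0), (0, 30), (0, 0), (5, 4), (6, 4), (9, 3), (30, 10), (10, 30),
    (3, 9), (12, 4), (4, 12), (9, 1), (1, 9), (27, 9), (9, 27), (100, 33),
    (33, 100), (7, 2), (2, 7), (11, 0), (0, 11), (500, 1), (1, 500),
]


class TestClassifyPeaks:
    def test_edge_cases_match_rule_oracle(self):
        res = classify_peaks(table(EDGE_CASES))
        for (xa, xi), got in zip(EDGE_CASES, res["peak_class"]):
            assert got == rule_oracle(xa, xi), (xa, xi)

    def test_classes_partition_all_records(self):
        res = classify_peaks(table(EDGE_CASES))
        assert res["peak_class"].isin(
            ["Xa_specific", "biallelic", "Xi_specific", "insufficient"]).all()

    def test_allele_swap_symmetry(self):
        res = classify_peaks(table(EDGE_CASES))
        swapped = table([(xi, xa) for xa, xi in EDGE_CASES])
        res_swapped = classify_peaks(swapped)
        mapping = {"Xa_specific": "Xi_specific", "Xi_specific": "Xa_specific",
                   "biallelic": "biallelic", "insufficient": "insufficient"}
        for a, b in zip(res["peak_class"], res_swapped["peak_class"]):
            assert mapping[a] == b

    def test_negative_counts_rejected(self):
        t = table([(5, 5)])
        t.loc[0, "reads_xa"] = -1
        with pytest.raises(FormatError):
            classify_peaks(t)

    def test_recovers_simulated_classes(self):
        t, truth = simulate_allelic_peaks(AllelicTableParams(
            n_features=1000, mean_reads=50, xa_skew=0.95,
            escape_fraction=0.05, n_replicates=1, seed=7))
        res = classify_peaks(t).set_index("feature_id")
        predicted = res["peak_class"].map(
            {"Xa_specific": "silenced", "biallelic": "escape"})
        informative = predicted.dropna()
        agree = (predicted[informative.index] ==
                 truth[informative.index]).mean()
        assert agree >= 0.95
        assert len(informative) / len(truth) >= 0.95


class TestRestoredPeaks:
    def wt_mut_pair(self):
        wt = table([(100, 0), (100, 5), (50, 50)], genotype="wt")
        mut = table([(0, 100), (100, 0), (50, 50)], genotype="mut")
        return wt, mut

    def test_full_restoration_detected(self):
        wt, mut = self.wt_mut_pair()
        per_rep, concordant = restored_peaks(wt, mut, depth_normalize=False)
        byid = per_rep.set_index("feature_id")
        assert byid.loc["p0", "restored"]
        assert concordant == ["p0"]

    def test_zero_mut_xi_not_restored(self):
        wt, mut = self.wt_mut_pair()
        per_rep, _ = restored_peaks(wt, mut, depth_normalize=False)
        assert not per_rep.set_index("feature_id").loc["p1", "restored"]

    def test_only_wt_xa_specific_considered(self):
        wt, mut = self.wt_mut_pair()
        per_rep, _ = restored_peaks(wt, mut, depth_normalize=False)
        assert "p2" not in set(per_rep["feature_id"])  # biallelic in wt

    def test_unmatched_features_raise_join_error(self):
        wt, mut = self.wt_mut_pair()
        with pytest.raises(JoinError) as err:
            restored_peaks(wt, mut.iloc[:2])
        assert "p2" in err.value.offenders

    def test_null_concordance_rate_low(self):
        """Mutant distributionally identical to wt: concordant restorations
        should be rare (<= 1% of peaks) across seeds."""
        rates = []
        for seed in range(10):
            wt, _ = simulate_allelic_peaks(AllelicTableParams(
                n_features=400, mean_reads=50, xa_skew=0.97,
                escape_fraction=0.0, n_replicates=2, seed=seed))
            mut, _ = simulate_allelic_peaks(AllelicTableParams(
                n_features=400, mean_reads=50, xa_skew=0.97,
                escape_fraction=0.0, n_replicates=2, seed=1000 + seed,
                genotype="mut"))
            _, concordant = restored_peaks(wt, mut)
            rates.append(len(concordant) / 400)
        assert np.mean(rates) <= 0.01


class TestEscapees:
    def gene_table(self):
        rows = []
        # g0: clear escapee in both; g1: silenced; g2: under read filter
        spec = {
            "g0": {"wt": [(90, 10), (85, 15)], "mut": [(80, 20), (90, 10)]},
            "g1": {"wt": [(99, 1), (98, 2)], "mut": [(99, 1), (97, 3)]},
            "g2": {"wt": [(5, 1), (4, 1)], "mut": [(3, 0), (2, 1)]},
        }
        for gene, conds in spec.items():
            for geno, reps in conds.items():
                for r, (xa, xi) in enumerate(reps, 1):
                    rows.append({"feature_id": gene, "chrom": "chrX",
                                 "start": 0, "end": 100, "reads_xa": xa,
                                 "reads_xi": xi, "replicate": f"rep{r}",
                                 "genotype": geno})
        return pd.DataFrame(rows)

    def test_boundary_fraction_is_escapee(self):
        t = table([(9, 1)] * 1, genotype="wt")
        t["reads_xa"] = 90
        t["reads_xi"] = 10
        flags = classify_escapees(t, min_allelic_reads=12,
                                  required_genotypes=["wt"])
        assert flags.loc["p0", "wt"]

    def test_read_filter_excludes_low_genes(self):
        flags = classify_escapees(self.gene_table())
        assert "g2" not in flags.index

    def test_flags_and_overlap(self):
        flags = classify_escapees(self.gene_table())
        assert flags.loc["g0"].all()
        assert not flags.loc["g1"].any()
        assert flags.attrs["overlap"] == ["g0"]

    def test_fpm_floor_filter(self):
        t = self.gene_table()
        t["fpm"] = 5.0
        t.loc[t["feature_id"] == "g0", "fpm"] = 0.5
        flags = classify_escapees(t, fpm_floor=1.0)
        assert "g0" not in flags.index

    def test_monotone_in_threshold(self):
        t, _ = simulate_allelic_peaks(AllelicTableParams(
            n_features=300, escape_fraction=0.3, seed=3))
        lo = classify_escapees(t, xi_fraction=0.05)
        hi = classify_escapees(t, xi_fraction=0.20)
        assert set(hi.index[hi.any(axis=1)]) <= set(lo.index[lo.any(axis=1)])


class TestXiExpressionCompare:
    def test_identical_tables_p_one(self):
        t = table([(90, 10), (80, 20), (70, 30), (60, 40), (50, 50), (95, 5)])
        res = xi_expression_density_compare(t, t.copy())
        assert res["p_value"] == 1.0

    def test_bonferroni_single_comparison_unchanged(self, rng):
        a = table([(int(x), int(y)) for x, y in
                   rng.integers(10, 100, size=(20, 2))])
        b = table([(int(x), int(y)) for x, y in
                   rng.integers(10, 100, size=(20, 2))])
        res = xi_expression_density_compare(a, b, n_comparisons=1)
        assert res["p_bonferroni"] == pytest.approx(res["p_value"])

    def test_shifted_simulation_power(self):
        r = np.random.default_rng(11)
        rejections, draws = 0, 50
        for _ in range(draws):
            n = 300
            fa = r.beta(2, 2 * (1 - 0.05) / 0.05, size=n)
            fb = r.beta(2, 2 * (1 - 0.25) / 0.25, size=n)
            tot = 200
            a = table([(tot - x, x) for x in r.binomial(tot, fa)])
            b = table([(tot - x, x) for x in r.binomial(tot, fb)])
            res = xi_expression_density_compare(a, b)
            rejections += res["p_bonferroni"] < 0.05
        assert rejections / draws >= 0.95

    def test_too_few_genes_raises(self):
        t = table([(10, 10), (20, 20)])
        with pytest.raises(DegenerateInputError):
            xi_expression_density_compare(t, t.copy())


class TestFoldChangeCDF:
    def test_identical_lists(self):
        x = list(np.linspace(-1, 1, 100))
        res = fold_change_cdf_test(x, list(x))
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"] == pytest.approx(1.0)

    def test_disjoint_supports(self):
        res = fold_change_cdf_test(list(np.arange(100)),
                                   list(np.arange(100) + 1000))
        assert res["statistic"] == pytest.approx(1.0)

    def test_cdf_tables_emitted(self):
        res = fold_change_cdf_test([1.0, 2.0, 3.0], [1.5, 2.5])
        cdf = res["cdf"]["autosomal"]
        assert list(cdf["cdf"]) == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_empty_list_raises(self):
        with pytest.raises(DegenerateInputError):
            fold_change_cdf_test([], [1.0])
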
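"""Composite detection, permutation null, NB regression, enrichment, timing."""

from itertools import permutations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

import aidtrack as at
from aidtrack.composite import _n_composite_samples
from aidtrack.synth import generate_panel_counts, random_panel


def _variants(rows, **extra_cols):
    df = pd.DataFrame(rows, columns=["sample", "gene", "protein_pos"])
    df["contig"] = "1"
    df["pos"] = np.arange(len(df))
    df["ref"] = "C"
    df["alt"] = "T"
    df["classification"] = "Missense_Mutation"
    for k, v in extra_cols.items():
        df[k] = v
    return df


class TestDetect:
    def test_same_gene_pair_detected(self):
        v = _variants([("S1", "A", 1), ("S1", "A", 2), ("S1", "B", 3)])
        res = at.detect_composites(v)
        assert res["summary"]["n_events"] == 1
        assert res["events"]["gene"].iloc[0] == "A"

    def test_no_pair_no_event(self):
        v = _variants([("S1", "A", 1), ("S2", "A", 2), ("S1", "B", 3)])
        assert at.detect_composites(v)["summary"]["n_events"] == 0

    def test_count_matches_groupby_oracle(self, rng):
        rows = [
            (f"S{rng.integers(0, 10)}", f"G{rng.integers(0, 15)}", int(p))
            for p in rng.integers(1, 500, size=300)
        ]
        v = _variants(rows)
        res = at.detect_composites(v)
        oracle = (v.groupby(["sample", "gene"]).size() >= 2).sum()
        assert res["summary"]["n_events"] == oracle

    def test_aid_flag_propagates_to_event(self):
        v = _variants([("S1", "A", 1), ("S1", "A", 2)], aid=[True, False])
        assert at.detect_composites(v)["events"]["aid_composite"].iloc[0]


class TestPermutation:
    def test_three_mutation_enumeration(self):
        # S1 carries (g1, g1), S2 carries (g2): over the 3 distinct
        # arrangements of the label multiset, P(n_i >= 1) = 1/3
        v = _variants([("S1", "g1", 1), ("S1", "g1", 2), ("S2", "g2", 3)])
        res = at.permutation_expected(v, n_perm=3000, seed=1)
        assert res.observed == 1
        assert res.p_value == pytest.approx(1 / 3, abs=0.03)

    def test_all_distinct_samples_p_one(self):
        v = _variants([("S1", "A", 1), ("S2", "A", 2), ("S3", "B", 3)])
        res = at.permutation_expected(v, n_perm=200, seed=0)
        assert res.observed == 0
        assert res.p_value == 1.0

    def test_matches_exhaustive_enumeration_on_small_instance(self, rng):
        rows = [
            (f"S{rng.integers(0, 3)}", f"G{rng.integers(0, 3)}", int(p))
            for p in range(7)
        ]
        v = _variants(rows)
        samples = v["sample"].to_numpy()
        genes = v["gene"].to_numpy()
        n_pos = _n_composite_samples(samples, genes)
        exact = np.mean(
            [
                _n_composite_samples(samples, np.array(perm)) >= n_pos
                for perm in permutations(genes)
            ]
        )
        res = at.permutation_expected(v, n_perm=4000, seed=3)
        assert res.p_value == pytest.approx(exact, abs=0.03)

    def test_p_value_bounds(self):
        v = _variants([("S1", "A", 1), ("S1", "A", 2)])
        res = at.permutation_expected(v, n_perm=100, seed=0)
        assert 1 / 101 <= res.p_value <= 1.0


class TestExpectedCounts:
    def test_intercept_only_recovers_rate(self):
        # all-identical covariates and counts proportional to the offset:
        # expectations must be exactly proportional to n_mutated
        n = 30
        panel = pd.DataFrame(
            {
                "cds_length": 1500, "gc": 50.0, "reptime": 40.0,
                "chromatin": "open", "assay_version": "v1", "mean_cn": 2.0,
                "n_mutated": np.repeat([50, 100, 200], 10),
            },
            index=[f"g{i}" for i in range(n)],
        )
        panel["count"] = panel["n_mutated"] // 10
        fit = at.fit_expected_counts(panel)
        ratio = fit["expected"] / panel["n_mutated"]
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-6)
        np.testing.assert_allclose(fit["expected"], panel["count"], rtol=1e-6)

    def test_too_few_genes_rejected(self):
        panel = random_panel(5, seed=0)
        panel["count"] = 1
        panel["n_mutated"] = 10
        with pytest.raises(ValueError):
            at.fit_expected_counts(panel)

    def test_known_coefficient_recovered(self):
        panel = random_panel(200, seed=5)
        counts = generate_panel_counts(panel, beta_log_cds=1.0, dispersion=0.5, seed=6)
        fit = at.fit_expected_counts(counts)
        c = fit["coefficients"].loc["log_cds_length"]
        assert c["ci_low"] <= 1.0 <= c["ci_high"]

    def test_median_imputation_reported(self):
        panel = random_panel(30, seed=1)
        panel["count"] = 1
        panel["n_mutated"] = 50
        panel.loc[panel.index[:3], "gc"] = np.nan
        fit = at.fit_expected_counts(panel)
        assert fit["imputed"] == {"gc": 3}


class TestGeneEnrichment:
    def test_observed_equal_expected_not_small_p(self):
        obs = pd.Series([5, 8], index=["a", "b"])
        res = at.gene_enrichment(obs, obs.astype(float), pd.Series([100, 100], index=obs.index))
        assert (res["p"] >= 0.5).all()

    def test_binomial_tail_oracle(self):
        obs = pd.Series([10], index=["g"])
        res = at.gene_enrichment(obs, pd.Series([1.0], index=["g"]),
                                 pd.Series([20], index=["g"]))
        expected = sum(comb(20, k) * 0.05**k * 0.95 ** (20 - k) for k in range(10, 21))
        assert res["p"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_planted_enriched_genes_flagged(self):
        panel = random_panel(200, seed=99)
        enriched = tuple(panel.index[:5])
        counts = generate_panel_counts(
            panel, enriched_genes=enriched, enrichment_fold=5.0,
            dispersion=0.0, seed=42,
        )
        fit = at.fit_expected_counts(counts)
        res = at.gene_enrichment(counts["count"], fit["expected"], counts["n_mutated"])
        flagged = set(res.index[res["significant"]])
        assert len(flagged & set(enriched)) >= 4
        assert len(flagged - set(enriched)) <= 2

    def test_bh_q_monotone_in_p(self):
        obs = pd.Series([3, 9, 1, 6], index=list("abcd"))
        res = at.gene_enrichment(obs, pd.Series(2.0, index=obs.index),
                                 pd.Series(50, index=obs.index))
        s = res.sort_values("p")
        assert (np.diff(s["q"]) >= -1e-12).all()


class TestResidueEnrichment:
    def test_concentrated_aid_composites_highly_significant(self):
        rows = [("S%d" % i, "G", 10) for i in range(30)]
        rows += [("S%d" % i, "G", 10) for i in range(30)]  # composite partners
        rows += [("T%d" % i, "G", i + 20) for i in range(60)]
        v = _variants(rows, aid=[True] * 60 + [False] * 60)
        events = at.detect_composites(v)["events"]
        res = at.residue_enrichment(v, events)
        top = res[res["residue"] == 10]
        assert top["p"].iloc[0] < 1e-6

    def test_single_residue_gene_no_contrast(self):
        v = _variants([("S1", "G", 5), ("S1", "G", 5)], aid=[True, True])
        events = at.detect_composites(v)["events"]
        res = at.residue_enrichment(v, events)
        assert (res["p"] == 1.0).all()

    def test_missing_residues_excluded_and_counted(self):
        v = _variants([("S1", "G", 1), ("S1", "G", 2), ("S2", "G", None)])
        events = at.detect_composites(v)["events"]
        res = at.residue_enrichment(v, events)
        assert res.attrs["n_excluded_no_residue"] == 1


class TestHotspotUtilization:
    def test_single_residue_curves_jump_to_one(self):
        v = _variants([("S1", "G", 1), ("S1", "G", 1), ("S2", "G", 1)],
                      aid=[True, False, False])
        events = at.detect_composites(v)["events"]
        res = at.hotspot_utilization(v, events)
        for curve in res["curves"].values():
            assert curve[0] == pytest.approx(1.0)

    def test_curves_match_cumulative_count_oracle(self, rng):
        rows = [
            (f"S{rng.integers(0, 6)}", "G", int(rng.integers(1, 5)))
            for _ in range(20)
        ]
        v = _variants(rows, aid=list(rng.random(20) < 0.5))
        events = at.detect_composites(v)["events"]
        res = at.hotspot_utilization(v, events)
        groups = res["groups"]
        key = v["gene"] + ":" + v["protein_pos"].astype(int).astype(str)
        for gname, curve in res["curves"].items():
            members = key[groups == gname]
            for k in range(len(res["ranked_residues"])):
                topk = set(res["ranked_residues"][: k + 1])
                frac = members.isin(topk).mean()
                assert curve[k] == pytest.approx(frac)

    def test_rare_residue_group_dominated_pointwise(self):
        rows = [("S%d" % i, "G", 1) for i in range(10)]
        rows += [("S%d" % i, "G", 1) for i in range(10)]  # composites at hotspot
        rows += [("T%d" % i, "G", i + 2) for i in range(10)]  # singletons spread
        v = _variants(rows, aid=[True] * 20 + [True] * 10)
        events = at.detect_composites(v)["events"]
        res = at.hotspot_utilization(v, events)
        comp, single = res["curves"]["aid_composite"], res["curves"]["aid_singleton"]
        assert (single <= comp + 1e-12).all()


class TestTiming:
    @staticmethod
    def _cohort_with_order(n_hotspot_first, n_total):
        rows, clon = [], []
        for i in range(n_total):
            s = f"S{i}"
            # residue 1 is the cohort hotspot, residue 100+i is rare
            if i < n_hotspot_first:
                rows += [(s, "G", 1), (s, "G", 100 + i)]
                clon += ["clonal", "subclonal"]
            else:
                rows += [(s, "G", 1), (s, "G", 100 + i)]
                clon += ["subclonal", "clonal"]
        return _variants(rows, clonality=clon)

    def test_all_hotspot_first_closed_form(self):
        v = self._cohort_with_order(10, 10)
        events = at.detect_composites(v)["events"]
        res = at.timing_test(events, v)
        assert res["n_orderable"] == 10
        assert res["frac_hotspot_first"] == 1.0
        assert res["p_global"] == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_balanced_order_p_one(self):
        v = self._cohort_with_order(5, 10)
        res = at.timing_test(at.detect_composites(v)["events"], v)
        assert res["p_global"] == pytest.approx(1.0)

    def test_too_few_orderable_events_skipped(self):
        v = self._cohort_with_order(2, 2)
        res = at.timing_test(at.detect_composites(v)["events"], v)
        assert res["skipped"] is True

    def test_residue_arriving_second_one_sided(self):
        v = self._cohort_with_order(10, 10)
        res = at.timing_test(at.detect_composites(v)["events"], v)
        # the hotspot residue (key G:1) came first in all 10 events
        hot = res["per_residue"]["G:1"]
        assert hot["n_second"] == 0
        assert hot["p"] == pytest.approx(1.0)
        assert binom.sf(-1, 10, 0.5) == 1.0  # sanity on the closed form
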
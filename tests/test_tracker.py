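"""c-AID tagging, the 768-channel matrix, enrichment, cosine similarity."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import aidtrack as at
from aidtrack.genome import reverse_complement
from aidtrack.tracker import channel_of
from aidtrack.variant_io import Cohort


def _cohort(rows):
    df = pd.DataFrame(rows, columns=["sample", "contig", "pos", "ref", "alt"])
    for col in ("gene", "protein_pos", "classification", "t_alt_count", "t_ref_count"):
        df[col] = pd.NA
    return Cohort(df)


class TestClassify:
    def test_c_to_t_at_wrcy_is_aid(self):
        g = at.GenomeSequence({"c": "TTAGCTTT"})  # AGCT at [2,6), C at 4
        cohort = at.classify_aid(_cohort([("S", "c", 4, "C", "T")]), g)
        assert cohort.variants["aid"].iloc[0]
        assert cohort.variants["aid_motif"].iloc[0] == "AGCT"

    def test_c_to_a_at_wrcy_is_not_aid(self):
        g = at.GenomeSequence({"c": "TTAGCTTT"})
        cohort = at.classify_aid(_cohort([("S", "c", 4, "C", "A")]), g)
        assert not cohort.variants["aid"].iloc[0]

    def test_g_on_minus_strand_wrcy(self):
        # plus-strand 4-mer GGTA with the G at its second base; reverse
        # complement TACC is in the WRCY expansion
        g = at.GenomeSequence({"c": "TGGTATT"})
        cohort = at.classify_aid(_cohort([("S", "c", 2, "G", "C")]), g)
        assert cohort.variants["aid"].iloc[0]
        assert cohort.variants["aid_motif"].iloc[0] == "TACC"
        assert reverse_complement("GGTA") == "TACC"

    def test_context_out_of_bounds_is_not_aid(self):
        g = at.GenomeSequence({"c": "ACCT"})
        cohort = at.classify_aid(_cohort([("S", "c", 1, "C", "T")]), g)
        assert not cohort.variants["aid"].iloc[0]

    def test_planted_mutations_all_recalled(self, synth_data):
        planted = (synth_data["truth"]["process"] == "aid").to_numpy()
        flags = synth_data["cohort"].variants["aid"].to_numpy()
        assert flags[planted].all()

    def test_flagged_background_sits_in_motif_context(self, synth_data, random_genome):
        v = synth_data["cohort"].variants
        bg = (synth_data["truth"]["process"] == "background").to_numpy()
        flagged = v["aid"].to_numpy() & bg
        for _, row in v[flagged].head(20).iterrows():
            p = int(row["pos"])
            if row["ref"] == "C":
                assert random_genome.sequence("1", p - 2, p + 2) in at.WRCY.motifs
            else:
                assert random_genome.sequence("1", p - 1, p + 3) in at.WRCY.rc_motifs

    def test_reverse_complement_invariance(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        g = at.GenomeSequence({"c": seq})
        n = len(seq)
        pos = rng.integers(2, n - 3, size=200)
        refs = [seq[p] for p in pos]
        alts = [
            rng.choice([b for b in "ACGT" if b != r]) for r in refs
        ]
        fwd = at.classify_aid(
            _cohort([("S", "c", int(p), r, a) for p, r, a in zip(pos, refs, alts)]), g
        )
        comp = dict(zip("ACGT", "TGCA"))
        g_rc = at.GenomeSequence({"c": reverse_complement(seq)})
        rev = at.classify_aid(
            _cohort(
                [
                    ("S", "c", n - 1 - int(p), comp[r], comp[a])
                    for p, r, a in zip(pos, refs, alts)
                ]
            ),
            g_rc,
        )
        np.testing.assert_array_equal(
            fwd.variants["aid"].to_numpy(), rev.variants["aid"].to_numpy()
        )


class TestSubstitutionMatrix:
    def test_channel_enumeration_has_768_unique_labels(self):
        labels = at.channel_labels()
        assert len(labels) == 768 == len(set(labels))

    def test_purine_channels_mirror_pyrimidine_channels(self):
        # reverse complementation maps each purine channel onto exactly one
        # pyrimidine channel (the mirrored-frame property)
        labels = set(at.channel_labels())
        comp = dict(zip("ACGT", "TGCA"))
        mapped = set()
        for lab in labels:
            ctx, alt = lab.split(">")
            ref = ctx[ctx.index("[") + 1]
            if ref in "AG":
                flat = ctx.replace("[", "").replace("]", "")
                rc = "".join(comp[b] for b in reversed(flat))
                mapped.add(f"{rc[:2]}[{rc[2]}]{rc[3]}>{comp[alt]}")
        pyr = {l for l in labels if l[l.index("[") + 1] in "CT"}
        assert mapped == pyr

    def test_single_snv_yields_single_count(self, random_genome):
        cohort = _cohort([("S", "1", 5000, random_genome.sequence("1", 5000, 5001), "A")])
        v = cohort.variants
        if v["ref"].iloc[0] == "A":
            v.loc[0, "alt"] = "T"
        mat = at.build_substitution_matrix(cohort, random_genome)
        assert mat.to_numpy().sum() == 1
        lab = mat.columns[mat.to_numpy().ravel().nonzero()[0][0]]
        ctx = random_genome.sequence("1", 4998, 5003)
        assert lab == channel_of(ctx, v["ref"].iloc[0], v["alt"].iloc[0])

    def test_row_sums_equal_classifiable_snvs(self, synth_data, random_genome):
        mat = at.build_substitution_matrix(synth_data["cohort"], random_genome)
        per_sample = synth_data["cohort"].variants.groupby("sample").size()
        expected = per_sample - 0  # no N in the synthetic genome, all classifiable
        pd.testing.assert_series_equal(
            mat.sum(axis=1)[expected.index], expected, check_names=False
        )
        assert mat.attrs["n_excluded"] == 0


class TestEnrichment:
    def test_zero_motif_mutations(self):
        g = at.GenomeSequence({"c": "TTGCGTTTGCGTTTGCGGGTT" * 40})
        cohort = at.classify_aid(_cohort([("S", "c", 3, "C", "T")]), g)
        res = at.compute_enrichment(cohort, g)
        assert res["enrichment"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_proportional_case_scores_one(self):
        # AGCT tiling: every C and every G is a motif target, so
        # Motif_ctx == C_ctx and M_motif == M_C, giving E exactly 1
        g = at.GenomeSequence({"c": "AGCT" * 300})
        cohort = at.classify_aid(
            _cohort([("S", "c", 4 * k + 2, "C", "T") for k in range(3, 10)]), g
        )
        res = at.compute_enrichment(cohort, g)
        assert res["m_motif"].iloc[0] == res["m_c"].iloc[0]
        assert res["motif_ctx"].iloc[0] == res["c_ctx"].iloc[0]
        assert res["enrichment"].iloc[0] == pytest.approx(1.0)

    def test_fisher_p_equals_hypergeometric_tail(self, synth_data, random_genome):
        res = at.compute_enrichment(synth_data["cohort"], random_genome)
        row = res.iloc[0]
        M = int(row["m_c"] + row["c_ctx"])          # population
        n = int(row["m_c"])                          # draws
        K = int(row["m_motif"] + row["motif_ctx"])   # successes in population
        k = int(row["m_motif"])
        expected = hypergeom.sf(k - 1, M, K, n)
        assert row["p"] == pytest.approx(expected, rel=1e-9)

    def test_aid_fraction_bounds_and_q_monotonicity(self, synth_data, random_genome):
        res = at.compute_enrichment(synth_data["cohort"], random_genome)
        assert res["aid_fraction"].between(0, 1).all()
        s = res.sort_values("p")
        assert (s["q"].to_numpy() >= s["p"].to_numpy() - 1e-12).all()


class TestCosine:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 0, 0], [0, 1, 1], 0.0),
            ([1, 1, 0], [1, 0, 1], 0.5),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert at.profile_cosine(a, b) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            at.profile_cosine([0, 0], [1, 1])

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            at.profile_cosine([1, -1], [1, 1])
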
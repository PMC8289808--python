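import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from itertools import product

from aidsig import (
    ReferenceSequence,
    SnvRecord,
    bh_adjust,
    compare_cohorts,
    enrichment_test,
    gene_motif_profile,
    matches_motif,
    run_gene_screen,
    simulate_gene_mutations,
    simulate_reference,
)
from aidsig.catalog import reverse_complement
from aidsig.motifs import MOTIF_CLASSES, MotifEnrichmentScreen, motif_site_positions
from oracles import bh_oracle, fisher_oracle


class TestMatchesMotif:
    def test_rc_to_t_matches(self):
        #                              1234
        genome = ReferenceSequence({"g": "AGCT"})
        assert matches_motif(SnvRecord("S1", "g", 3, "C", "T"), genome, "RC>NY")

    def test_alt_constraint_excludes_c_to_g(self):
        genome = ReferenceSequence({"g": "AGCT"})
        rec = SnvRecord("S1", "g", 3, "C", "G")
        assert not matches_motif(rec, genome, "RC>NY")
        assert matches_motif(rec, genome, "WRC>N")  # W=A, R=G, any alt

    def test_pyrimidine_preceding_base_fails(self):
        genome = ReferenceSequence({"g": "ATCCT"})
        assert not matches_motif(SnvRecord("S1", "g", 4, "C", "T"), genome, "RC>NY")

    def test_t_reference_never_matches(self):
        genome = ReferenceSequence({"g": "AGTT"})
        assert not matches_motif(SnvRecord("S1", "g", 3, "T", "C"), genome, "RC>NY")

    def test_wrc_requires_weak_base(self):
        genome_w = ReferenceSequence({"g": "TACT"})   # W=T, R=A, C
        genome_s = ReferenceSequence({"g": "GACT"})   # 5'-2 base is strong (G)
        rec = SnvRecord("S1", "g", 3, "C", "T")
        assert matches_motif(rec, genome_w, "WRC>NY")
        assert not matches_motif(rec, genome_s, "WRC>NY")
        assert matches_motif(rec, genome_s, "RC>NY")  # RC does not look that far

    def test_insufficient_flank_is_false(self):
        genome = ReferenceSequence({"g": "CCTA"})
        assert not matches_motif(SnvRecord("S1", "g", 1, "C", "T"), genome, "RC>NY")

    def test_purine_record_evaluated_on_reverse_strand(self):
        # G>A at pos 2 of 5'-AGCT-3' is C>T preceded by G on the minus strand
        genome = ReferenceSequence({"g": "AGCT"})
        assert matches_motif(SnvRecord("S1", "g", 2, "G", "A"), genome, "RC>NY")

    def test_strand_involution_on_enumerated_contexts(self):
        """A C>T record and the equivalent G>A record on the reverse
        complement genome agree for every 5-mer context and motif class."""
        for bases in product("ACGT", repeat=4):
            seq = f"{bases[0]}{bases[1]}C{bases[2]}{bases[3]}"
            fwd = ReferenceSequence({"g": seq})
            rev = ReferenceSequence({"g": reverse_complement(seq)})
            rec_fwd = SnvRecord("S1", "g", 3, "C", "T")
            rec_rev = SnvRecord("S1", "g", 3, "G", "A")
            for motif in MOTIF_CLASSES:
                assert matches_motif(rec_fwd, fwd, motif) == matches_motif(rec_rev, rev, motif)

    def test_nesting_wrcny_implies_rcny_and_wrcn(self):
        rng = np.random.default_rng(1)
        genome = simulate_reference(5000, 0.5, 2)
        for _ in range(300):
            pos = int(rng.integers(3, 4998))
            ref = genome.base("chr1", pos)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            rec = SnvRecord("S1", "chr1", pos, ref, alt)
            if matches_motif(rec, genome, "WRC>NY"):
                assert matches_motif(rec, genome, "RC>NY")
                assert matches_motif(rec, genome, "WRC>N")


class TestGeneMotifProfile:
    def test_brute_force_position_scan(self):
        seq = "ACACAC"
        # forward: C at indices 1,3,5 preceded by A (R) -> 3 sites
        # reverse: no G in the sequence -> 0 sites
        profile = gene_motif_profile("g", seq, "RC>NY")
        assert profile.motif_site_count == 3
        assert profile.motif_site_fraction == pytest.approx(0.5)

    def test_poly_t_has_no_sites(self):
        profile = gene_motif_profile("g", "T" * 50, "RC>NY")
        assert profile.motif_site_count == 0 and profile.motif_site_fraction == 0.0

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(9)
        for motif in MOTIF_CLASSES:
            for _ in range(20):
                seq = "".join(rng.choice(list("ACGT"), size=60))
                a = gene_motif_profile("g", seq, motif).motif_site_count
                b = gene_motif_profile("g", reverse_complement(seq), motif).motif_site_count
                assert a == b

    def test_counts_match_naive_window_scan(self):
        """Independent oracle: test every position against the motif
        definition spelled out over explicit windows."""
        rng = np.random.default_rng(10)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        expected = 0
        for i, b in enumerate(seq):
            if b == "C" and i >= 1 and seq[i - 1] in "AG":
                expected += 1
            if b == "G" and i + 1 < len(seq) and seq[i + 1] in "CT":
                expected += 1
        assert gene_motif_profile("g", seq, "RC>NY").motif_site_count == expected

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            gene_motif_profile("g", "", "RC>NY")


class TestEnrichmentTest:
    def test_zero_in_motif_one_sided_p_is_one(self):
        assert enrichment_test(0, 10, 30, 300, sided="greater") == pytest.approx(1.0)

    def test_matches_factorial_oracle(self):
        p = enrichment_test(8, 2, 20, 80)
        assert p == pytest.approx(fisher_oracle(8, 2, 20, 80), rel=1e-9)
        p1 = enrichment_test(8, 2, 20, 80, sided="greater")
        assert p1 == pytest.approx(fisher_oracle(8, 2, 20, 80, "greater"), rel=1e-9)

    def test_proportional_table_two_sided_p_is_one(self):
        assert enrichment_test(5, 5, 50, 50) == pytest.approx(1.0)

    def test_zero_mutations_flagged_as_p_one(self):
        assert enrichment_test(0, 0, 30, 300) == 1.0

    def test_negative_count_is_error(self):
        with pytest.raises(ValueError):
            enrichment_test(-1, 2, 3, 4)

    def test_empty_gene_is_error(self):
        with pytest.raises(ValueError, match="at least one site"):
            enrichment_test(1, 2, 0, 0)

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    def test_oracle_agreement_on_random_small_tables(self, a, b, c, d):
        if c + d == 0:
            return
        assert enrichment_test(a, b, c, d) == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)


class TestCompareCohorts:
    def test_identical_proportions_near_one(self):
        assert compare_cohorts(50, 500, 100, 1000) == pytest.approx(1.0, abs=0.05)

    def test_extreme_table_matches_oracle(self):
        assert compare_cohorts(10, 10, 0, 10) == pytest.approx(fisher_oracle(10, 0, 0, 10), rel=1e-9)

    def test_cohort_order_symmetry(self):
        assert compare_cohorts(8, 20, 3, 25) == pytest.approx(compare_cohorts(3, 25, 8, 20))

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            compare_cohorts(11, 10, 0, 10)


class TestBhAdjust:
    def test_textbook_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    def test_all_equal_p_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2, 0.2]) == pytest.approx([0.2] * 4)

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_matches_step_up_oracle_and_permutation_invariance(self, p):
        q = bh_adjust(p)
        assert q == pytest.approx(bh_oracle(p), rel=1e-12)
        assert (np.asarray(q) >= np.asarray(p) - 1e-15).all()
        perm = np.random.default_rng(0).permutation(len(p))
        q_perm = bh_adjust(list(np.asarray(p)[perm]))
        assert q_perm == pytest.approx(np.asarray(q)[perm])


@pytest.fixture(scope="module")
def genes():
    rng = np.random.default_rng(21)
    return {
        f"G{i}": "".join(rng.choice(list("ACGT"), size=800, p=[0.3, 0.2, 0.2, 0.3]))
        for i in range(6)
    }


class TestRunGeneScreen:

    def test_enriched_gene_gets_smallest_p(self, genes):
        records = []
        for gene, seq in genes.items():
            oratio = 12.0 if gene == "G0" else 1.0
            recs, _ = simulate_gene_mutations(gene, seq, 15, oratio, seed=3)
            records.extend(recs)
        df = run_gene_screen(records, genes, min_mutations=3)
        assert df.loc[df["p_value"].idxmin(), "gene"] == "G0"
        assert df.iloc[0]["gene"] == "G0"  # sorted by in-motif count desc

    def test_consequence_filter_and_min_mutations(self, genes):
        recs, _ = simulate_gene_mutations("G1", genes["G1"], 10, 1.0, seed=4)
        silent = [
            SnvRecord("S1", "G2", p, genes["G2"][p - 1], "A" if genes["G2"][p - 1] != "A" else "C",
                      gene="G2", consequence="synonymous")
            for p in (10, 20, 30, 40)
        ]
        df = run_gene_screen(recs + silent, genes, min_mutations=3)
        assert set(df["gene"]) == {"G1"}  # G2 rows are synonymous, filtered out

    def test_gene_without_sequence_warned_and_excluded(self, genes):
        recs, _ = simulate_gene_mutations("G1", genes["G1"], 5, 1.0, seed=5)
        orphan = [
            SnvRecord("S1", "NOPE", p, "C", "T", gene="NOPE", consequence="non-synonymous")
            for p in (10, 20, 30)
        ]
        with pytest.warns(UserWarning, match="NOPE"):
            df = run_gene_screen(recs + orphan, genes)
        assert "NOPE" not in set(df["gene"])

    def test_q_values_bound_p_values(self, genes):
        records = []
        for gene, seq in genes.items():
            recs, _ = simulate_gene_mutations(gene, seq, 8, 1.0, seed=6)
            records.extend(recs)
        df = run_gene_screen(records, genes)
        assert (df["q_value"] >= df["p_value"] - 1e-15).all()
        assert (df["significant"] == (df["q_value"] < 0.05)).all()

    def test_estimator_wrapper(self, genes):
        recs, _ = simulate_gene_mutations("G3", genes["G3"], 12, 10.0, seed=7)
        screen = MotifEnrichmentScreen(gene_sequences=genes, min_mutations=3).fit(recs)
        assert set(screen.results_["gene"]) == {"G3"}
        assert screen.significant_genes_ == list(
            screen.results_.loc[screen.results_["significant"], "gene"]
        )
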
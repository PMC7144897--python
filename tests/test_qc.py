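"""QC metric primitives: classifiers, pairing, UMI collapse, strand
invasion and Hurlbert rarefaction (vs independent oracles)."""

import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtscreen.qc import (
    AlignmentMate,
    AlignmentRecord,
    MoleculeRecord,
    classify_artefact,
    classify_rrna,
    detect_strand_invasion,
    dinucleotide_entropy,
    hurlbert_richness,
    is_proper_pair,
    revcomp,
    umi_collapse,
)

OLIGOS = [
    "AAGCAGTGGTATCAACGCAGAGT",
    "GTGACTGGAGTTCAGACGTGTGCTCT",
]


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


class TestArtefact:
    def test_oligo_on_oligo_product_is_flagged(self):
        dimer = (OLIGOS[1] + revcomp(OLIGOS[0]))[:32]
        assert classify_artefact(dimer, "", OLIGOS)

    def test_reverse_complement_of_oligo_is_flagged(self):
        assert classify_artefact(revcomp(OLIGOS[0]) + "ACGTACGTA", "", OLIGOS)

    def test_poly_a_low_complexity_is_flagged(self):
        assert classify_artefact("A" * 46, "T" * 21, OLIGOS)

    def test_random_genomic_reads_below_1pct_false_positives(self):
        rng = np.random.default_rng(0)
        hits = sum(
            classify_artefact(_random_seq(rng, 32), _random_seq(rng, 21), OLIGOS)
            for _ in range(1000)
        )
        assert hits / 1000 < 0.01

    def test_entropy_scale(self):
        assert dinucleotide_entropy("A" * 40) == 0.0
        assert dinucleotide_entropy("AT" * 20) == pytest.approx(1.0, abs=0.05)
        rng = np.random.default_rng(1)
        assert dinucleotide_entropy(_random_seq(rng, 46)) > 3.0


@pytest.fixture(scope="module")
def refs():
    rng = np.random.default_rng(7)
    return {"rRNA_1": _random_seq(rng, 1500), "rRNA_2": _random_seq(rng, 900)}


class TestRrna:

    def test_exact_substring_matches(self, refs):
        assert classify_rrna(refs["rRNA_1"][100:132], "", refs)

    def test_reverse_complement_matches(self, refs):
        assert classify_rrna(revcomp(refs["rRNA_2"][50:82]), "", refs)

    def test_either_mate_suffices(self, refs):
        rng = np.random.default_rng(8)
        assert classify_rrna(_random_seq(rng, 32), refs["rRNA_1"][10:31], refs)

    def test_random_read_not_flagged(self, refs):
        rng = np.random.default_rng(9)
        assert not classify_rrna(_random_seq(rng, 32), _random_seq(rng, 21), refs)

    def test_k_longer_than_read_rejected(self, refs):
        with pytest.raises(ValueError):
            classify_rrna("ACGT", "ACGT", refs, k=21)


class TestProperPair:
    def mate(self, start, end, strand, chrom="chr1"):
        return AlignmentMate(chrom, start, end, strand)

    def test_facing_pair_1kb_apart_is_proper(self):
        assert is_proper_pair(self.mate(1000, 1032, "+"), self.mate(1980, 2001, "-"))

    def test_distance_exactly_2mb_is_rejected(self):
        m1 = self.mate(0, 32, "+")
        m2 = self.mate(2_000_000 - 21 + 1, 2_000_001, "-")  # 5'-5' = 2 Mb exactly
        assert m2.five_prime - m1.five_prime == 2_000_000
        assert not is_proper_pair(m1, m2)
        just_under = self.mate(2_000_000 - 21, 2_000_000, "-")
        assert is_proper_pair(m1, just_under)

    def test_different_chromosomes_rejected(self):
        assert not is_proper_pair(
            self.mate(0, 32, "+"), self.mate(100, 121, "-", chrom="chr2")
        )

    def test_same_strand_rejected(self):
        assert not is_proper_pair(self.mate(0, 32, "+"), self.mate(100, 121, "+"))

    def test_diverging_mates_rejected(self):
        assert not is_proper_pair(self.mate(1000, 1032, "+"), self.mate(100, 121, "-"))


class TestUmiCollapse:
    def rec(self, rid, umi, pos):
        return AlignmentRecord(rid, umi, AlignmentMate("c", pos, pos + 32, "+"), None)

    def test_identical_reads_collapse_with_support(self):
        mols = umi_collapse([self.rec(str(i), "AAAA", 10) for i in range(5)])
        assert len(mols) == 1 and mols[0].support == 5

    def test_distinct_umis_stay_separate(self):
        mols = umi_collapse([self.rec("a", "AAAA", 10), self.rec("b", "CCCC", 10)])
        assert len(mols) == 2

    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.sampled_from(["AA", "CC", "GG"])),
            max_size=40,
        )
    )
    @settings(deadline=None)
    def test_molecules_never_exceed_reads(self, items):
        recs = [self.rec(str(i), umi, pos) for i, (pos, umi) in enumerate(items)]
        mols = umi_collapse(recs)
        assert len(mols) <= len(recs)
        assert sum(m.support for m in mols) == len(recs)


class TestStrandInvasion:
    TAIL = "AGAGTACGGG"

    def test_planted_tail_upstream_is_flagged(self):
        rng = np.random.default_rng(3)
        genome = {"c": _random_seq(rng, 300)[:100] + self.TAIL + _random_seq(rng, 100)}
        mol = MoleculeRecord("c", 110, "+", "AAAA", 1)
        assert detect_strand_invasion(mol, genome, self.TAIL)

    def test_minus_strand_tail_is_flagged(self):
        rng = np.random.default_rng(4)
        genome = {"c": _random_seq(rng, 100) + revcomp(self.TAIL) + _random_seq(rng, 100)}
        mol = MoleculeRecord("c", 99, "-", "AAAA", 1)
        assert detect_strand_invasion(mol, genome, self.TAIL)

    def test_two_mismatches_tolerated_three_rejected(self):
        base = "T" * 50 + self.TAIL + "T" * 50
        mol = MoleculeRecord("c", 60, "+", "A", 1)
        two = base[:50] + "CC" + self.TAIL[2:] + base[60:]
        three = base[:50] + "CCC" + self.TAIL[3:] + base[60:]
        assert detect_strand_invasion(mol, {"c": two}, self.TAIL, max_mismatch=2)
        assert not detect_strand_invasion(mol, {"c": three}, self.TAIL, max_mismatch=2)

    def test_random_upstream_not_flagged(self):
        rng = np.random.default_rng(5)
        # random 10-mers essentially never reach <=2 mismatches to the tail
        genome = {"c": _random_seq(rng, 200)}
        hits = sum(
            detect_strand_invasion(MoleculeRecord("c", p, "+", "A", 1), genome, self.TAIL)
            for p in range(20, 180)
        )
        assert hits == 0

    def test_contig_edge_returns_false(self):
        genome = {"c": self.TAIL + "ACGTACGT"}
        mol = MoleculeRecord("c", 5, "+", "A", 1)
        assert not detect_strand_invasion(mol, genome, self.TAIL)


def hurlbert_oracle(counts, n):
    """Exact rational-arithmetic rarefaction via math.comb."""
    N = sum(counts)
    return float(
        sum(1 - math.comb(N - c, n) / math.comb(N, n) for c in counts if c > 0)
    )


class TestHurlbertRichness:
    def test_single_gene_at_exact_depth(self):
        assert hurlbert_richness({"g1": 10}, 10) == pytest.approx(1.0)

    def test_full_depth_returns_observed_richness(self):
        assert hurlbert_richness({"g1": 5, "g2": 5}, 10) == pytest.approx(2.0)

    def test_skewed_pair_matches_hand_derivation(self):
        # counts {18, 2}: 2 - C(2,10)/C(20,10) - C(18,10)/C(20,10) = 1 + 29/38
        expected = hurlbert_oracle([18, 2], 10)
        assert expected == pytest.approx(1 + 29 / 38, rel=1e-12)
        assert expected == pytest.approx(1.7632, abs=1e-4)
        assert hurlbert_richness({"g1": 18, "g2": 2}, 10) == pytest.approx(expected)

    def test_undefined_below_depth(self):
        assert hurlbert_richness({"g1": 4}, 10) is None

    def test_rejects_negative_or_fractional_counts(self):
        with pytest.raises(ValueError):
            hurlbert_richness([3, -1], 2)
        with pytest.raises(ValueError):
            hurlbert_richness([2.5], 2)

    def test_matches_exact_oracle_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            k = int(rng.integers(1, 12))
            counts = rng.integers(0, 60, size=k)
            if counts.sum() < 10:
                counts[0] += 10
            got = hurlbert_richness(counts, 10)
            assert got == pytest.approx(hurlbert_oracle(list(counts), 10), rel=1e-10)

    def test_matches_monte_carlo_subsampling_within_3_sigma(self):
        rng = np.random.default_rng(12)
        counts = np.array([40, 25, 10, 5, 3, 2, 1, 1])
        labels = np.repeat(np.arange(counts.size), counts)
        draws = 100_000
        richness = np.empty(draws)
        for i in range(draws):
            richness[i] = np.unique(rng.choice(labels, size=10, replace=False)).size
        mc, se = richness.mean(), richness.std(ddof=1) / np.sqrt(draws)
        assert abs(hurlbert_richness(counts, 10) - mc) < 3 * se

    @given(st.lists(st.integers(0, 50), min_size=1, max_size=15))
    @settings(deadline=None, max_examples=60)
    def test_bounds_and_label_permutation_invariance(self, counts):
        if sum(counts) < 10:
            counts = counts + [10]
        r = hurlbert_richness(counts, 10)
        positive = [c for c in counts if c > 0]
        assert 1.0 <= r <= len(positive) + 1e-9
        assert hurlbert_richness(sorted(counts, reverse=True), 10) == pytest.approx(r)

    def test_agrees_with_vegan_rarefy(self, tmp_path):
        """Cross-check against the R vegan implementation of rarefaction."""
        counts = [17, 3, 42, 1, 9, 28]
        script = tmp_path / "rarefy.R"
        script.write_text(
            "suppressMessages(library(vegan));"
            f"cat(rarefy(c({','.join(map(str, counts))}), 10))\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        assert hurlbert_richness(counts, 10) == pytest.approx(float(out.stdout), abs=1e-6)
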
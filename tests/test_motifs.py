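import numpy as np
import pytest

from helpers import brute_force_scan, random_dna
from regulonml import motifs as mo
from regulonml.genome_io import Genome, extract_promoter

UNIFORM = np.full(4, 0.25)


def toy_pssm(rows, name="toy"):
    """PSSM from explicit log-odds rows (A,C,G,T order)."""
    return mo.PSSM(name=name, matrix=np.array(rows, dtype=float),
                   background=UNIFORM, pseudocount=0.0)


class TestBuildPssm:
    def test_site_counts_follow_stated_formula(self):
        # two 'AA' sites, vanishing pseudocount: P(A)=1, log2(1/0.25)=2
        p = mo.build_pssm(sites=["AA", "AA"], pseudocount=1e-9)
        assert p.matrix[0, 0] == pytest.approx(2.0, abs=1e-6)
        assert p.matrix[1, 0] == pytest.approx(2.0, abs=1e-6)

    def test_uniform_probabilities_give_zero_log_odds(self):
        p = mo.build_pssm(probabilities=np.full((3, 4), 0.25))
        assert np.allclose(p.matrix, 0.0)

    def test_ragged_alignment_lists_offender(self):
        with pytest.raises(ValueError, match="'ATG'"):
            mo.build_pssm(sites=["AT", "ATG"])

    def test_pseudocount_formula_from_sites(self):
        # one 'A' site, pseudocount 0.5 split by uniform background:
        # P(A) = (1 + 0.5*0.25) / (1 + 0.5) = 0.75
        p = mo.build_pssm(sites=["A"], pseudocount=0.5)
        assert p.probabilities[0, 0] == pytest.approx(0.75)

    def test_consensus_column_is_maximum(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(4), size=6)
        p = mo.build_pssm(probabilities=probs)
        assert all(
            p.matrix[i, mo.BASE_INDEX[c]] == p.matrix[i].max()
            for i, c in enumerate(p.consensus)
        )


class TestScan:
    def test_enumerated_example(self):
        # pos1 rewards A, pos2 rewards T; windows of "CATG": CA=-2, AT=2, TG=-2
        p = toy_pssm([[1, -1, -1, -1], [-1, -1, -1, 1]])
        hit = mo.scan_sequence(p, "CATG", strands="forward")
        assert hit.score == 2.0 and hit.start == 1 and hit.site_sequence == "AT"

    def test_consensus_scores_column_maxima(self):
        p = mo.build_pssm(sites=["TATAAT", "TATAAT", "TACAAT"], pseudocount=0.5)
        hit = mo.scan_sequence(p, "GGGG" + p.consensus + "GGGG")
        assert hit.score == pytest.approx(p.consensus_score)

    def test_all_n_scores_zero_at_leftmost(self):
        p = toy_pssm([[1, -1, -1, -1], [-1, -1, -1, 1]])
        hit = mo.scan_sequence(p, "NNNNN")
        assert hit.score == 0.0 and hit.start == 0

    def test_forward_preferred_on_strand_tie(self):
        # palindromic motif scores identically on both strands
        p = toy_pssm([[1, 0, 0, 0], [0, 0, 0, 1]])  # consensus AT (palindrome)
        hit = mo.scan_sequence(p, "GGATGG")
        assert hit.strand_of_hit == "forward"

    def test_reverse_strand_hit_found(self):
        p = mo.build_pssm(sites=["ACGGT"], pseudocount=0.5)
        seq = "TTTT" + "ACCGT" + "TTTT"  # revcomp(ACGGT)=ACCGT
        hit = mo.scan_sequence(p, seq)
        assert hit.strand_of_hit == "reverse" and hit.site_sequence == "ACGGT"

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(4, 16))
        n = int(rng.integers(30, 201))
        matrix = rng.normal(size=(L, 4))
        p = toy_pssm(matrix, name=f"r{seed}")
        seq = random_dna(rng, n)
        hit = mo.scan_sequence(p, seq)
        score, start, strand = brute_force_scan(matrix, seq, both_strands=True)
        assert hit.score == pytest.approx(score, abs=1e-12)
        assert (hit.start, hit.strand_of_hit) == (start, strand)

    def test_search_window_restriction(self):
        """Sequence outside the search window never changes the hit."""
        rng = np.random.default_rng(1)
        p = mo.build_pssm(probabilities=rng.dirichlet(np.ones(4), size=6))
        g1 = Genome(id="a", sequence=random_dna(rng, 400))
        prom1 = extract_promoter(g1, tss=300, strand="+", window=(150, 50))
        # replace sequence downstream of the TSS, scan only upstream
        seq2 = prom1.sequence[:150] + random_dna(rng, 50)
        prom2 = type(prom1)(tu_id=prom1.tu_id, gene_ids=prom1.gene_ids,
                            tss=prom1.tss, strand="+", sequence=seq2)
        h1 = mo.scan(p, prom1, search_window=(-150, 0))
        h2 = mo.scan(p, prom2, search_window=(-150, 0))
        assert (h1.score, h1.offset, h1.strand_of_hit) == (h2.score, h2.offset, h2.strand_of_hit)

    def test_too_short_promoter_errors(self):
        p = toy_pssm(np.zeros((10, 4)))
        with pytest.raises(ValueError, match="shorter than motif"):
            mo.scan_sequence(p, "ACGT")


class TestHamming:
    @pytest.mark.parametrize("a,b,d", [
        ("TATAAT", "TATAAT", 0),
        ("TATAAT", "TACAAT", 1),
        ("AAAA", "TTTT", 4),
    ])
    def test_counts_mismatches(self, a, b, d):
        assert mo.hamming(a, b) == d

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = random_dna(rng, 8), random_dna(rng, 8)
            assert mo.hamming(a, b) == mo.hamming(b, a)

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError, match="unequal"):
            mo.hamming("AA", "AAA")


class TestDirectRepeats:
    unit = np.tile(np.array([[0.85, 0.05, 0.05, 0.05]]), (10, 1))  # A-rich 10-mer

    def test_length_formula(self):
        p = mo.build_dr_pssm(self.unit, k=2, gap=0)
        assert p.length == 20 and p.source == "DR-2"
        p3 = mo.build_dr_pssm(self.unit, k=3, gap=2)
        assert p3.length == 34

    def test_gap_columns_contribute_zero(self):
        p = mo.build_dr_pssm(self.unit, k=2, gap=3)
        assert np.allclose(p.matrix[10:13], 0.0)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError, match="k >= 2"):
            mo.build_dr_pssm(self.unit, k=1)

    def test_three_repeats_outscore_two_under_dr3(self):
        rng = np.random.default_rng(5)
        dr3 = mo.build_dr_pssm(self.unit, k=3, gap=0)
        consensus_unit = "A" * 10
        bg = random_dna(rng, 40)
        three = bg[:5] + consensus_unit * 3 + bg[5:]
        two = bg[:5] + consensus_unit * 2 + random_dna(rng, 10) + bg[5:]
        assert mo.scan_sequence(dr3, three).score > mo.scan_sequence(dr3, two).score

    def test_cutoff_is_mean_of_confirmed_scores(self):
        p = mo.build_dr_pssm(self.unit, k=2, gap=0)
        sites = ["A" * 20, "A" * 10 + "C" * 10]
        scores = [mo.scan_sequence(p, s).score for s in sites]
        cut = mo.dr_cutoff(p, sites)
        assert cut == pytest.approx(np.mean(scores))
        assert min(scores) <= cut <= max(scores)

    def test_cutoff_empty_list_errors(self):
        p = mo.build_dr_pssm(self.unit, k=2)
        with pytest.raises(ValueError, match="at least one"):
            mo.dr_cutoff(p, [])
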
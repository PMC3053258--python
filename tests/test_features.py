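import math
from collections import Counter

import numpy as np
import pytest

from plantpin import (
    FoldResult,
    ParameterSet,
    ReadAlignment,
    ReferenceFolder,
    extract_duplex,
    normalized_mfe,
    nucleus_conserved,
    shuffle,
    signature_logodds,
    stability_pvalue,
    stability_pvalue_from_count,
    star_present,
)
from plantpin.excision import Precursor
from plantpin.features import signature_logliks
from plantpin.io_formats import revcomp
from plantpin.synthetic import SyntheticSpec, make_hairpin


class TestNormalizedMfe:
    def test_arithmetic(self):
        fr = FoldResult("A" * 250, "." * 250, -100.0)
        assert normalized_mfe(fr) == pytest.approx(-0.4)

    def test_unstructured_zero(self):
        assert normalized_mfe(FoldResult("A" * 20, "." * 20, 0.0)) == 0.0

    def test_length_invariance_for_equal_per_nt_energy(self):
        a = FoldResult("A" * 100, "." * 100, -40.0)
        b = FoldResult("A" * 300, "." * 300, -120.0)
        assert normalized_mfe(a) == pytest.approx(normalized_mfe(b))

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            normalized_mfe(FoldResult("ACGTACGTAC", "." * 10, -1.0), length=0)


class TestShuffle:
    def test_homopolymer_fixed_point(self, rng):
        assert shuffle("AAAA", "mono", rng) == "AAAA"

    def test_mono_preserves_nucleotide_histogram(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 200))
            s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
            assert Counter(shuffle(s, "mono", rng)) == Counter(s)

    def test_di_preserves_dinucleotide_table(self, rng):
        """Euler-path shuffle conserves the 16-entry dinucleotide count table."""
        for _ in range(100):
            n = int(rng.integers(20, 200))
            s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
            sh = shuffle(s, "di", rng)
            assert Counter(zip(sh, sh[1:])) == Counter(zip(s, s[1:]))
            assert sh[0] == s[0] and sh[-1] == s[-1]

    def test_di_actually_shuffles(self, rng):
        # needs a sequence whose dinucleotide graph admits >1 Euler path
        s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 120)])
        outs = {shuffle(s, "di", rng) for _ in range(20)}
        assert len(outs) > 1


class TestStabilityPvalue:
    def test_formula(self):
        assert stability_pvalue_from_count(49, 999) == pytest.approx(0.049)

    def test_floor(self):
        assert stability_pvalue_from_count(0, 999) == pytest.approx(0.001)

    def test_planted_hairpin_is_stable(self):
        spec = SyntheticSpec(seed=4, stem_length=26, loop_length=8)
        hp, _, _ = make_hairpin(spec, np.random.default_rng(4))
        p, rel = stability_pvalue(hp, n_shuffles=99, rng=np.random.default_rng(10))
        assert rel == 1
        assert p <= 0.05

    def test_independent_recount_agrees(self):
        """Recomputing every shuffle MFE separately with the same seed
        reproduces R and hence p exactly."""
        spec = SyntheticSpec(seed=8, stem_length=20, loop_length=6)
        hp, _, _ = make_hairpin(spec, np.random.default_rng(8))
        p, _ = stability_pvalue(hp, n_shuffles=99, rng=np.random.default_rng(3))
        folder = ReferenceFolder()
        rng = np.random.default_rng(3)
        native = folder.energy(hp)
        r = 0
        for _ in range(99):
            sh = shuffle(hp, "mono", rng)
            if folder.energy(sh) <= native:
                r += 1
        assert p == pytest.approx(stability_pvalue_from_count(r, 99))

    def test_pvalue_in_unit_interval_and_stable_hairpin_small(self):
        spec = SyntheticSpec(seed=5, stem_length=30)
        hp, _, _ = make_hairpin(spec, np.random.default_rng(5))
        for n in (19, 49):
            p, _ = stability_pvalue(hp, n_shuffles=n, rng=np.random.default_rng(1))
            assert 0.0 < p <= 1.0
            assert p == pytest.approx(1.0 / (n + 1))


class TestNucleusConserved:
    LIB = ["TAGCTAGCTAGCTAGCTAGCT", "GGGGCCCCAAAATTTTGGGGC"]

    def test_identity_match(self):
        assert nucleus_conserved(self.LIB[0], self.LIB) == 1

    def test_only_positions_2_to_12_compared(self):
        m = list(self.LIB[0])
        m[0] = "C"
        for i in range(12, 21):
            m[i] = "A" if self.LIB[0][i] != "A" else "G"
        assert nucleus_conserved("".join(m), self.LIB) == 1

    def test_single_mismatch_in_window_fails(self):
        m = list(self.LIB[0])
        m[4] = "A" if m[4] != "A" else "G"  # position 5 (1-based) inside 2-12
        assert nucleus_conserved("".join(m), self.LIB) == 0

    def test_library_order_invariance(self):
        assert nucleus_conserved(self.LIB[1], self.LIB[::-1]) == 1

    def test_short_mature_scores_zero(self):
        assert nucleus_conserved("ACGTACG", self.LIB) == 0

    def test_mismatch_allowance_flag(self):
        m = list(self.LIB[0])
        m[4] = "A" if m[4] != "A" else "G"
        assert nucleus_conserved("".join(m), self.LIB, max_mismatches=1) == 1


def planted_candidate(seed=21, arm="5p"):
    spec = SyntheticSpec(seed=seed)
    hp, (m0, m1), (s0, s1) = make_hairpin(spec, np.random.default_rng(seed), arm=arm)
    pre = Precursor("p", "chr1", 1000, 1000 + len(hp), "+", hp,
                    ReferenceFolder().fold(hp), m0, m1)
    duplex = extract_duplex(pre)
    assert duplex is not None
    return pre, duplex


def aln(pre, lo, hi, count=1, rid="r"):
    seq = pre.sequence[lo:hi]
    return ReadAlignment(rid, seq, count, pre.ref_id, pre.start + lo, pre.start + hi, "+", 0, 1)


class TestStarPresent:
    def test_read_on_star_interval(self):
        pre, d = planted_candidate()
        assert star_present(pre, d, [aln(pre, d.star_start, d.star_end)]) == 1

    def test_no_reads_outside_mature(self):
        pre, d = planted_candidate()
        assert star_present(pre, d, [aln(pre, d.mature_start, d.mature_end)]) == 0

    def test_two_nt_slack(self):
        pre, d = planted_candidate()
        shifted = aln(pre, d.star_start - 2, d.star_end - 2)
        assert star_present(pre, d, [shifted], slack=2) == 1


class TestSignature:
    def test_all_consistent_reads_maximal(self, monocot):
        pre, d = planted_candidate()
        reads = [aln(pre, d.mature_start, d.mature_end, count=10, rid="m")]
        lo = signature_logodds(pre, d, reads, monocot)
        # any inconsistent read at the same total count scores lower
        mixed = reads + [aln(pre, d.mature_start + 7, d.mature_end + 7, count=2, rid="x")]
        pure = [aln(pre, d.mature_start, d.mature_end, count=12, rid="m")]
        assert signature_logodds(pre, d, pure, monocot) > signature_logodds(pre, d, mixed, monocot)
        assert lo > 0

    def test_scattered_reads_nonpositive_by_direct_summation(self, monocot):
        pre, d = planted_candidate()
        starts = [d.mature_start + 7, d.mature_start + 11, d.star_start - 9,
                  d.star_start - 17, d.mature_end + 7]
        assert all(0 <= s and s + 21 <= len(pre.sequence) for s in starts)
        reads = [aln(pre, s, s + 21, rid=f"r{i}") for i, s in enumerate(starts)]
        lo = signature_logodds(pre, d, reads, monocot)
        assert lo <= 0
        # independent recomputation by direct summation of the two likelihoods
        tol = monocot.signature_tolerance
        loop = (d.mature_end, d.star_start)
        n = k = 0
        for a in reads:
            r0 = a.start - pre.start
            r1 = a.end - pre.start
            cons = (abs(r0 - d.mature_start) <= tol or abs(r0 - d.star_start) <= tol
                    or (loop[0] <= r0 and r1 <= loop[1]))
            n += a.count
            k += a.count if cons else 0
        L = len(pre.sequence)
        u = min(max((2 * (2 * tol + 1) + (loop[1] - loop[0])) / L, 1e-6), 0.99)
        p = monocot.signature_geometric_p
        expected = (math.log(p) + (n - k) * math.log(1 - p)) - (k * math.log(u) + (n - k) * math.log(1 - u))
        assert lo == pytest.approx(expected)

    def test_doubling_counts_preserves_classification(self, monocot):
        pre, d = planted_candidate()
        reads = [aln(pre, d.mature_start, d.mature_end, count=5, rid="m"),
                 aln(pre, d.mature_start + 9, d.mature_end + 9, count=5, rid="x")]
        doubled = [aln(pre, d.mature_start, d.mature_end, count=10, rid="m"),
                   aln(pre, d.mature_start + 9, d.mature_end + 9, count=10, rid="x")]
        r1, b1 = signature_logliks(pre, d, reads, monocot)
        r2, b2 = signature_logliks(pre, d, doubled, monocot)
        # consistent fraction unchanged; log-likelihood terms scale with count
        p = monocot.signature_geometric_p
        assert (r2 - math.log(p)) == pytest.approx(2 * (r1 - math.log(p)))
        assert b2 == pytest.approx(2 * b1)

    def test_no_reads_rejected(self, monocot):
        pre, d = planted_candidate()
        with pytest.raises(ValueError):
            signature_logodds(pre, d, [], monocot)
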
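import math

import numpy as np
import pytest
from scipy import stats

from plantpin.estimation import (
    align_family,
    binned_logodds,
    conservation_profile,
    empirical_cdf_error,
    estimate_discrete_frequencies,
    fit_gumbel_min,
    fit_sigmoid,
    fit_sigmoid_xy,
    ks_two_sample,
    mfe_length_regression,
    nucleus_frequency_cv,
    select_excision_length,
)

from oracles import bruteforce_ks


class TestFitGumbelMin:
    def test_parameter_recovery(self):
        x = stats.gumbel_l.rvs(loc=32.0, scale=5.5, size=10000, random_state=1234)
        fit = fit_gumbel_min(x)
        assert fit.location == pytest.approx(32.0, abs=0.3)
        assert fit.scale == pytest.approx(5.5, abs=0.2)

    def test_shift_equivariance(self):
        x = stats.gumbel_l.rvs(loc=0.0, scale=2.0, size=5000, random_state=7)
        a, b = fit_gumbel_min(x), fit_gumbel_min(x + 5.0)
        assert b.location - a.location == pytest.approx(5.0, abs=0.05)
        assert b.scale == pytest.approx(a.scale, abs=0.05)

    def test_fit_beats_misspecified_normal(self):
        x = stats.gumbel_l.rvs(loc=10.0, scale=3.0, size=4000, random_state=3)
        fit = fit_gumbel_min(x)
        normal_err = empirical_cdf_error(x, stats.norm(np.mean(x), np.std(x)).cdf)
        assert fit.cdf_error <= normal_err

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_gumbel_min([1.0] * 100)


class TestBinnedLogOdds:
    def test_identical_samples_give_zero(self, rng):
        x = rng.normal(-0.3, 0.1, 500)
        b = binned_logodds(x, x)
        assert np.allclose(b.logodds[b.defined], 0.0)

    def test_shifted_sample_sign_pattern(self, rng):
        x = rng.normal(-0.35, 0.05, 4000)
        b = binned_logodds(x - 0.05, x)
        defined = np.where(b.defined)[0]
        assert b.logodds[defined[0]] > 0     # left tail enriched in "real"
        assert b.logodds[defined[-1]] < 0    # right tail enriched in background

    def test_toy_three_bin_hand_computation(self):
        real = [0.005, 0.005, 0.015, 0.025]
        bgr = [0.005, 0.015, 0.025, 0.025]
        b = binned_logodds(real, bgr, 0.01)
        assert b.logodds == pytest.approx([math.log(2), 0.0, math.log(0.5)])


class TestFitSigmoid:
    TRUE = (1.0, 0.5, 10.0)

    def _bins(self, noise=0.0, seed=11):
        x = np.linspace(-0.8, 0.2, 60)
        a, b, c = self.TRUE
        y = a / (b + np.exp(c * x))
        if noise:
            y = y + np.random.default_rng(seed).normal(0, noise, x.size)
        return x, y

    def test_noise_free_exact_recovery(self):
        fit = fit_sigmoid_xy(*self._bins())
        assert fit.rss < 1e-10
        assert fit.a == pytest.approx(1.0, rel=1e-4)
        assert fit.b == pytest.approx(0.5, rel=1e-4)
        assert fit.c == pytest.approx(10.0, rel=1e-4)

    def test_noisy_recovery_within_ten_percent(self):
        fit = fit_sigmoid_xy(*self._bins(noise=0.01))
        assert fit.a == pytest.approx(1.0, rel=0.10)
        assert fit.b == pytest.approx(0.5, rel=0.10)
        assert fit.c == pytest.approx(10.0, rel=0.10)

    def test_reproducible_across_runs(self):
        x, y = self._bins(noise=0.01)
        f1, f2 = fit_sigmoid_xy(x, y), fit_sigmoid_xy(x, y)
        assert (f1.a, f1.b, f1.c) == (f2.a, f2.b, f2.c)

    def test_binned_interface_and_min_bins(self, rng):
        with pytest.raises(ValueError, match="5"):
            fit_sigmoid_xy([0.1, 0.2], [1.0, 2.0])
        real = rng.normal(-0.5, 0.08, 3000)
        bgr = rng.normal(-0.35, 0.08, 3000)
        fit = fit_sigmoid(binned_logodds(real, bgr))
        assert np.isfinite(fit.rss)


class TestDiscreteFrequencies:
    def test_reproduces_stability_logodds(self):
        p_real, p_bgr, (lo1, lo0) = estimate_discrete_frequencies(
            [1] * 98 + [0] * 2, [1] * 25 + [0] * 75)
        assert (p_real, p_bgr) == (0.98, 0.25)
        assert lo1 == pytest.approx(1.37, abs=0.005)
        assert lo0 == pytest.approx(-3.624, abs=0.0005)

    def test_empty_background_uses_pseudocount(self):
        _, p_bgr, (lo1, _) = estimate_discrete_frequencies(
            [1] * 69 + [0] * 31, [0] * 100, pseudo_count=1 / 3000)
        assert p_bgr == pytest.approx(1 / 3000)
        assert lo1 == pytest.approx(math.log(0.69 * 3000))

    def test_identical_flags_zero_logodds(self):
        _, _, (lo1, lo0) = estimate_discrete_frequencies([1, 0, 1, 0], [1, 0, 1, 0])
        assert lo1 == 0.0 and lo0 == 0.0


class TestConservationProfile:
    def test_identical_families_fully_conserved(self):
        fams = {f"f{i}": ["ACGTACGTACGTACGTACGTA"] * 4 for i in range(18)}
        prof = conservation_profile(fams)
        assert prof.n_families == 18
        assert (prof.counts == 18).all()
        assert prof.blocks(0.75) == [(1, 21)]

    def test_modal_fraction_below_threshold_not_conserved(self):
        members = ["ACGTA", "ACGTA", "ACGTA", "ACGTA", "ACATA"]  # pos 3: 0.8
        prof = conservation_profile({"f": members, "g": ["ACGTA"] * 2})
        assert (prof.family_fractions["f"] >= 0.9).tolist() == [True, True, False, True, True]

    def test_two_block_fixture(self):
        """Four families with positions 2-13 and 16-19 conserved in three of
        them yield exactly those blocks at the 0.75 across-family threshold."""
        L = 21
        conserved_pos = set(range(1, 13)) | set(range(15, 19))  # 0-based
        base = "ACGTACGTACGTACGTACGTA"

        def family(conserve: bool):
            members = [list(base) for _ in range(5)]
            for pos in range(L):
                if not (conserve and pos in conserved_pos):
                    # break conservation: 2 of 5 members differ -> modal 0.6
                    for m in (3, 4):
                        members[m][pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[members[m][pos]]
            return ["".join(m) for m in members]

        fams = {"f1": family(True), "f2": family(True), "f3": family(True), "f4": family(False)}
        prof = conservation_profile(fams)
        assert prof.blocks(0.75) == [(2, 13), (16, 19)]

    def test_permutation_invariance(self, rng):
        fams = {"a": ["ACGTACGTACGTACGTACGTA"] * 3, "b": ["TTTTACGTACGTACGTACGGG"] * 3}
        p1 = conservation_profile(fams)
        p2 = conservation_profile({k: fams[k][::-1] for k in reversed(list(fams))})
        assert (p1.counts == p2.counts).all()

    def test_singleton_family_excluded(self):
        prof = conservation_profile({"a": ["ACGTACGTACGTACGTACGTA"] * 2,
                                     "solo": ["ACGTACGTACGTACGTACGTA"]})
        assert prof.n_families == 1


class TestNucleusFrequencyCV:
    def test_identical_matures(self, rng):
        assert nucleus_frequency_cv(["TAGCTAGCTAGCTAGCTAGCT"] * 20, rng=rng) == 1.0

    def test_pairwise_distinct_nuclei(self, rng):
        base = "TAGCTAGCTAGCTAGCTAGCT"
        matures = []
        for i in range(12):
            m = list(base)
            m[4] = "ACGT"[i % 4]
            m[6] = "ACGT"[(i // 4) % 4]
            m[8] = "ACGT"[(i // 8) % 4]
            matures.append("".join(m))
        assert len(set(m[1:12] for m in matures)) == len(matures)
        assert nucleus_frequency_cv(matures, rng=rng) == 0.0

    def test_family_structure_gives_full_conservation(self, rng):
        """10 families x 10 members sharing a family nucleus: every test
        mature finds a training family mate (exhaustive-matching oracle)."""
        matures = []
        for f in range(10):
            nucleus = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 11)])
            for m in range(10):
                tail = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 9)])
                matures.append("T" + nucleus + tail)
        # oracle: every mature shares its window with 9 family mates
        for m in matures:
            assert sum(1 for o in matures if o[1:12] == m[1:12]) >= 10
        assert nucleus_frequency_cv(matures, rng=rng) == 1.0


class TestSelectExcisionLength:
    def test_cdf_forced_choice(self):
        lengths = [100] * 96 + [400] * 4
        assert select_excision_length(lengths, 0.96) == 100

    def test_full_coverage_returns_maximum(self):
        lengths = [100] * 50 + [250] * 50
        assert select_excision_length(lengths, 1.0) == 250

    def test_quantile_oracle_on_seeded_mixture(self, rng):
        lengths = np.concatenate([
            rng.normal(120, 20, 700), rng.normal(280, 40, 300)]).astype(int)
        lengths = lengths[lengths > 50]
        L = select_excision_length(lengths, 0.96, min_tail_sample=5)
        srt = np.sort(lengths)
        oracle = srt[int(np.ceil(0.96 * srt.size)) - 1]
        assert L == oracle

    def test_monotone_in_coverage(self, rng):
        lengths = rng.integers(60, 400, 500)
        picks = [select_excision_length(lengths, c, min_tail_sample=5)
                 for c in (0.5, 0.7, 0.9, 0.96, 0.98)]
        assert picks == sorted(picks)

    def test_unattainable_coverage_reports_best(self):
        with pytest.raises(ValueError, match="best feasible"):
            select_excision_length([100] * 40 + [400] * 5, 0.99, min_tail_sample=30)


class TestKsTwoSample:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        d, p = ks_two_sample(x, x)
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
        assert d == 1.0

    def test_matches_bruteforce_and_scipy(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, int(rng.integers(5, 40)))
            y = rng.normal(0.3, 1.2, int(rng.integers(5, 40)))
            d, _ = ks_two_sample(x, y)
            assert d == pytest.approx(bruteforce_ks(list(x), list(y)))
            assert d == pytest.approx(stats.ks_2samp(x, y).statistic)


class TestMfeLengthRegression:
    def test_exact_linear_slope(self):
        lengths = np.repeat([100, 150, 200, 250, 300], 20)
        reg = mfe_length_regression(lengths, 0.5 * lengths)
        assert reg.slope == pytest.approx(0.5)
        assert (reg.table["sd_abs_mfe"] == 0).all()

    def test_constant_mfe_zero_slope(self):
        lengths = np.repeat([100, 200, 300], 30)
        reg = mfe_length_regression(lengths, np.full(90, 40.0))
        assert reg.slope == pytest.approx(0.0, abs=1e-12)

    def test_noisy_slope_recovery(self, rng):
        lengths = rng.integers(60, 400, 3000).astype(float)
        noise_sd = 0.05 * lengths  # dispersion grows with length
        mfe = 0.48 * lengths + rng.normal(0, 1, lengths.size) * noise_sd
        reg = mfe_length_regression(lengths, mfe)
        assert reg.slope == pytest.approx(0.48, abs=0.02)


class TestAlignFamily:
    def test_prealigned_returned_unchanged(self):
        seqs = ["ACGT-ACGT", "ACGTTACGT"]
        assert align_family(seqs) == seqs

    def test_gapped_alignment_equal_width(self):
        out = align_family(["ACGTACGTACGT", "ACGTACGT", "ACGTACGTAC"])
        assert len({len(s) for s in out}) == 1
        assert [s.replace("-", "") for s in out] == ["ACGTACGTACGT", "ACGTACGT", "ACGTACGTAC"]
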
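"""Coverage scaling, the copy-number HMM, and gamma-posterior rates."""

import numpy as np
import pytest
from scipy import stats

from lineageseq import (
    CopyNumberTrack,
    SegmentCount,
    estimate_rate,
    fit_cnv_hmm,
    fit_scaling,
    haploid_rate,
    poisson_qq,
)
from lineageseq.cnv import CnvHmm, brute_force_viterbi, viterbi_path
from lineageseq.core import IntervalTrack, LeafVariant, VariantLocus
from lineageseq.rates import rate_posterior_draws, segment_counts_from_calls


class TestScaling:
    def test_exact_integer_alignment(self):
        sc = fit_scaling(np.array([0.5, 1.0, 1.5]))
        assert sc.s == pytest.approx(2.0, abs=1e-4)
        assert sc.objective == pytest.approx(0.0, abs=1e-9)

    def test_smallest_minimizer_on_ties(self):
        # all-integer coverage: s = 1, 2, 3... all give objective 0
        sc = fit_scaling(np.ones(10))
        assert sc.s == pytest.approx(1.0, abs=1e-4)

    def test_all_zero_coverage_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            fit_scaling(np.zeros(5))

    def test_noisy_mixture_recovery(self):
        """Median-normalized diploid/triploid bin coverage at 35x
        (~3500 reads per 10-kb bin): recovered scaling within 2% of the
        integer-aligning truth over 50 seeds."""
        reads_per_diploid_bin = 3500  # 35x, 100-bp reads, 10-kb bins
        errors = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            states = np.concatenate([np.full(300, 2), np.full(150, 3)])
            reads = rng.poisson(reads_per_diploid_bin * states / 2.0)
            cov = reads / np.median(reads)
            # truth: the scale mapping normalized coverage back to states
            true_s = np.median(states / cov)
            sc = fit_scaling(cov)
            errors.append(abs(sc.s - true_s) / true_s)
        assert max(errors) < 0.02


class TestHmm:
    def test_constant_diploid_track(self):
        track = fit_cnv_hmm(np.full(200, 1.0) * 2 / 2, scaling=None)
        # constant coverage 1.0 scales to state 1 under the smallest-tie
        # rule; supply the known scaling to pin states at 2
        from lineageseq.cnv import CoverageScaling

        track = fit_cnv_hmm(np.ones(200), scaling=CoverageScaling(2.0, 0.0))
        assert (track.states == 2).all()
        assert len(track.segments()) == 1
        assert track.effective_genome_size == 2 * 200 * 10_000

    def test_planted_three_state_recovery(self):
        rng = np.random.default_rng(0)
        states = np.concatenate(
            [np.full(1400, 2), np.full(400, 3), np.full(200, 1)]
        )
        cov = states + 0.08 * rng.standard_cauchy(len(states))
        cov = np.clip(cov, -2, 8)
        norm = cov / np.median(cov)
        track = fit_cnv_hmm(norm)
        assert (track.states == states).mean() >= 0.99
        assert track.hmm.gamma == pytest.approx(0.08, rel=0.25)

    def test_em_loglik_nondecreasing(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([np.full(50, 2.0), np.full(50, 3.0)])
        x = x + 0.05 * rng.standard_normal(100)
        hmm = CnvHmm()
        lls = []
        prev = None
        for _ in range(5):
            hmm.fit(x, max_iter=1)
            lls.append(hmm.log_likelihood_)
        assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(2)
        x = 2 + 0.1 * rng.standard_normal(50)
        hmm = CnvHmm().fit(x, max_iter=5)
        post = hmm.posteriors(x)
        assert np.allclose(post.sum(axis=1), 1.0)

    def test_viterbi_matches_brute_force(self):
        """Dynamic-programming Viterbi equals exhaustive enumeration on
        tiny chains (<= 12 bins, 3 states)."""
        rng = np.random.default_rng(3)
        for trial in range(5):
            T, S = 8, 3
            log_pi = np.log(rng.dirichlet(np.ones(S)))
            A = rng.dirichlet(np.ones(S), size=S)
            log_b = np.log(rng.dirichlet(np.ones(S), size=T))
            got = viterbi_path(log_pi, np.log(A), log_b)
            want = brute_force_viterbi(log_pi, np.log(A), log_b)
            assert np.array_equal(got, want)


class TestRateEstimate:
    def test_posterior_mean_is_y_over_n(self):
        est = estimate_rate(
            [SegmentCount("a", 2, 1), SegmentCount("b", 3, 1), SegmentCount("c", 1, 1)]
        )
        assert (est.shape, est.rate) == (6, 3)
        assert est.mean == 2.0
        assert est.ci95[0] < est.mean < est.ci95[1]

    def test_printed_rate_arithmetic(self):
        est = estimate_rate([SegmentCount("all", 173, 1)], G=5.7e9)
        assert float(f"{est.per_bp:.1e}") == 3.0e-8

    def test_quantiles_match_sampling(self):
        """Closed-form gamma quantiles equal 1e6-draw Monte-Carlo
        quantiles to 3 decimals."""
        est = estimate_rate(
            [SegmentCount("a", 2, 1), SegmentCount("b", 3, 1), SegmentCount("c", 1, 1)]
        )
        draws = rate_posterior_draws(est, n_draws=10**6, seed=0)
        lo, hi = np.quantile(draws, [0.025, 0.975])
        assert est.ci95[0] == pytest.approx(lo, abs=1e-2)
        assert est.ci95[1] == pytest.approx(hi, abs=1e-2)

    def test_improper_posterior_error(self):
        with pytest.raises(ValueError, match="improper posterior"):
            estimate_rate([SegmentCount("a", 0, 1)])

    def test_method2_tree_refused(self, quartet_tree):
        from lineageseq.calling import CladeFrequencyTable, build_tree_from_sets

        table = CladeFrequencyTable()
        for _ in range(10):
            table.add(frozenset({"A", "B"}))
        tree2 = build_tree_from_sets(table, ["A", "B", "C"], min_count=5)
        with pytest.raises(ValueError, match="lower bounds"):
            segment_counts_from_calls([], tree2)
        assert segment_counts_from_calls([], tree2, allow_approx_generations=True) is not None


class TestHaploidRate:
    def _setup(self, counts_builder, carrier_cell):
        track = IntervalTrack([("chr1", 0, 1_000_000, 1)])
        vl = VariantLocus("chr1", 500, "G", "T")
        table = counts_builder([vl], ["s0", "s1"], {(0, "s0"): carrier_cell})
        variants = [LeafVariant(vl, "s0")]
        return variants, table, track

    def test_clonal_haploid_variant_kept(self, counts_builder):
        variants, table, track = self._setup(counts_builder, (1, 29))
        est = haploid_rate(variants, table, track, divisions=4, n_sims=10**4)
        assert est.n_variants == 1
        assert est.rate_per_bp == pytest.approx(1 / (1e6 * 4))

    def test_subclonal_variant_excluded(self, counts_builder):
        variants, table, track = self._setup(counts_builder, (15, 15))
        est = haploid_rate(variants, table, track, divisions=4, n_sims=10**4)
        assert est.n_variants == 0

    def test_zero_haploid_territory_error(self, counts_builder):
        variants, table, _ = self._setup(counts_builder, (1, 29))
        track = IntervalTrack([("chr1", 0, 1_000_000, 2)])
        with pytest.raises(ValueError, match="zero haploid"):
            haploid_rate(variants, table, track, divisions=4)


class TestPoissonQq:
    def test_zero_count_has_p_one(self):
        df = poisson_qq([SegmentCount("a", 0, 1)], lam=2.0, n_null=10, seed=0)
        assert df["observed_p"].iloc[-1] == 1.0

    def test_null_calibration(self):
        """Counts generated from the Poisson model: observed and expected
        p-value distributions agree (two-sample KS at 5%)."""
        rng = np.random.default_rng(0)
        lam = 20.0
        segments = [
            SegmentCount(f"e{i}", int(rng.poisson(lam)), 1) for i in range(300)
        ]
        df = poisson_qq(segments, lam, n_null=100, seed=1)
        # compare against a second null data set run through the same
        # machinery (same discrete support on both sides of the KS test)
        null_counts = [
            SegmentCount(f"n{i}", int(c), 1)
            for i, c in enumerate(np.random.default_rng(2).poisson(lam, 300))
        ]
        df_null = poisson_qq(null_counts, lam, n_null=10, seed=3)
        stat = stats.ks_2samp(df["observed_p"], df_null["observed_p"])
        assert stat.pvalue > 0.05

    def test_overdispersion_detected(self):
        """Gamma-mixed per-segment rates push the tails off the diagonal."""
        rng = np.random.default_rng(0)
        lam = 20.0
        mixed = rng.gamma(0.5, lam / 0.5, size=300)
        segments = [
            SegmentCount(f"e{i}", int(rng.poisson(m)), 1)
            for i, m in enumerate(mixed)
        ]
        df = poisson_qq(segments, lam, n_null=100, seed=1)
        stat = stats.ks_2samp(df["observed_p"], df["expected_p"])
        assert stat.pvalue < 0.05
        # extreme tail is orders of magnitude off the diagonal
        assert (
            df["observed_log10p"].iloc[0] < df["expected_log10p"].iloc[0] - 2
        )
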
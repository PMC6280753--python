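"""Trinucleotide spectra, similarity, enrichment, strand asymmetry, and
the frozen-signature projection."""

import numpy as np
import pytest

from lineageseq import (
    CHANNELS,
    SegmentCount,
    Spectrum96,
    build_spectrum,
    cosine_similarity,
    project_signatures,
    rclass_asymmetry,
    region_enrichment,
    subtract_signature,
)
from lineageseq.core import IntervalTrack, VariantLocus
from lineageseq.spectra import (
    channel_of,
    classify_slope,
    classify_timing,
    direction_track_from_slopes,
    revcomp,
    slope_track_from_timing,
    timing_class_track,
)


class TestSpectrum:
    def test_exactly_96_channels(self):
        assert len(CHANNELS) == 96
        assert len(set(CHANNELS)) == 96
        # blocks of 16 per substitution class, alphabetical within blocks
        assert CHANNELS[0] == "A[C>A]A" and CHANNELS[-1] == "T[T>G]T"

    def test_worked_pyrimidine_binning(self):
        # C>T in T.C.G context is the TpCpG > TpTpG channel
        assert channel_of("C", "T", "T", "G") == "T[C>T]G"

    def test_purine_reference_reverse_complemented(self):
        # G>A with 5'C 3'A maps to the same channel as its pyrimidine
        # partner on the other strand: T[C>T]G
        assert channel_of("G", "A", "C", "A") == "T[C>T]G"

    def test_build_from_reference(self):
        ref = {"chr1": "ATCGA"}
        spec = build_spectrum([VariantLocus("chr1", 3, "C", "T")], ref)
        assert spec.total == 1
        assert spec.counts[CHANNELS.index("T[C>T]G")] == 1

    def test_strand_involution_invariance(self):
        """Complementing the reference and swapping alleles leaves the
        spectrum unchanged."""
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        ref = {"chr1": seq}
        variants = []
        for pos in range(2, 199, 7):
            r = seq[pos - 1]
            a = rng.choice([b for b in "ACGT" if b != r])
            variants.append(VariantLocus("chr1", pos, r, str(a)))
        fwd = build_spectrum(variants, ref)
        # the genuine strand involution: reverse-complement the genome and
        # remap positions, complementing the alleles
        L = len(seq)
        flipped_ref = {"chr1": revcomp(seq)}
        flipped = [
            VariantLocus(v.chrom, L - v.pos + 1, revcomp(v.ref), revcomp(v.alt))
            for v in variants
        ]
        rev = build_spectrum(flipped, flipped_ref)
        assert np.array_equal(fwd.counts, rev.counts)

    def test_totals_conserved_and_edges_skipped(self, caplog):
        ref = {"chr1": "ACGT"}
        variants = [
            VariantLocus("chr1", 1, "A", "C"),  # no 5' flank -> skipped
            VariantLocus("chr1", 2, "C", "T"),
            VariantLocus("chr1", 4, "T", "G"),  # no 3' flank -> skipped
        ]
        with caplog.at_level("WARNING"):
            spec = build_spectrum(variants, ref)
        assert spec.total == 1 and spec.n_skipped == 2

    def test_empty_input_all_zero(self):
        spec = build_spectrum([], {"chr1": "AAAA"})
        assert spec.total == 0 and spec.counts.shape == (96,)


class TestCosine:
    def test_identity(self):
        a = Spectrum96(np.arange(96, dtype=float))
        sim, _ = cosine_similarity(a, a, n_boot=0)
        assert sim == 1.0

    def test_orthogonal(self):
        a = Spectrum96(np.eye(96)[0] * 5)
        b = Spectrum96(np.eye(96)[1] * 5)
        sim, _ = cosine_similarity(a, b, n_boot=0)
        assert sim == 0.0

    def test_half_overlap(self):
        a = Spectrum96(np.eye(96)[0] * 10)
        b = Spectrum96((np.eye(96)[0] + np.eye(96)[1]) * 5)
        sim, ci = cosine_similarity(a, b, n_boot=500, seed=0)
        assert sim == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        assert ci[0] <= sim <= ci[1] or ci[1] >= 0.7

    def test_zero_vector_error(self):
        with pytest.raises(ValueError, match="zero spectrum"):
            cosine_similarity(Spectrum96(), Spectrum96(np.ones(96)))


class TestRegionEnrichment:
    def test_uniform_null_is_flat(self):
        regions = IntervalTrack(
            [("chr1", 0, 500_000, "genic"), ("chr1", 500_000, 1_000_000, "intergenic")]
        )
        rng = np.random.default_rng(0)
        variants = [
            VariantLocus("chr1", int(p), "C", "T")
            for p in rng.integers(1, 1_000_000, size=400)
        ]
        df = region_enrichment(variants, regions, n_boot=200, seed=0)
        assert (df["expected"].sum()) == pytest.approx(len(variants))
        assert (df["log2_ratio"].abs() < 0.3).all()
        assert (df["p_value"] > 0.01).all()

    def test_planted_density_detected(self):
        regions = IntervalTrack(
            [("chr1", 0, 500_000, "early"), ("chr1", 500_000, 1_000_000, "late")]
        )
        rng = np.random.default_rng(1)
        # 2x density in "late" half: expect log2(obs/exp) ~ log2(4/3)
        pos = np.concatenate(
            [
                rng.integers(1, 500_000, size=200),
                rng.integers(500_001, 1_000_000, size=400),
            ]
        )
        variants = [VariantLocus("chr1", int(p), "C", "T") for p in pos]
        df = region_enrichment(variants, regions, n_boot=200, seed=0)
        late = df[df["region_class"] == "late"].iloc[0]
        assert late["log2_ratio"] == pytest.approx(np.log2(4 / 3), abs=0.1)
        assert late["significant"]

    def test_single_class_is_exactly_zero(self):
        regions = IntervalTrack([("chr1", 0, 1_000_000, "genome")])
        variants = [VariantLocus("chr1", 10, "C", "T")]
        df = region_enrichment(variants, regions, n_boot=0)
        assert df["log2_ratio"].iloc[0] == 0.0

    def test_copy_weighting(self):
        regions = IntervalTrack(
            [("chr1", 0, 500_000, "a"), ("chr1", 500_000, 1_000_000, "b")]
        )
        copies = IntervalTrack(
            [("chr1", 0, 500_000, 4), ("chr1", 500_000, 1_000_000, 2)]
        )
        variants = [VariantLocus("chr1", 10, "C", "T")] * 1
        df = region_enrichment(variants, regions, copy_track=copies, n_boot=0)
        a = df[df["region_class"] == "a"].iloc[0]
        assert a["expected"] == pytest.approx(1 * (4 / 6))


class TestTimingClasses:
    @pytest.mark.parametrize(
        "value,cls",
        [(60, "early"), (75, "early"), (59.9, "intermediate"),
         (33.1, "intermediate"), (33, "late"), (10, "late")],
    )
    def test_timing_thresholds(self, value, cls):
        assert classify_timing(value) == cls

    @pytest.mark.parametrize(
        "slope,cls",
        [(0.2, "right"), (0.1, "undefined"), (0.3, "undefined"),
         (-0.2, "left"), (-0.05, "undefined"), (0.5, "undefined")],
    )
    def test_slope_windows(self, slope, cls):
        assert classify_slope(slope) == cls

    def test_slope_from_timing_track(self):
        timing = IntervalTrack(
            [("chr1", 0, 100, 50.0), ("chr1", 100, 200, 50.2),
             ("chr1", 200, 300, 50.4)]
        )
        slopes = slope_track_from_timing(timing)
        directions = direction_track_from_slopes(slopes)
        assert directions.lookup("chr1", 50) == "right"
        classes = timing_class_track(timing)
        assert classes.lookup("chr1", 50) == "intermediate"


class TestAsymmetry:
    def _territory(self):
        return {(d, b): 1_000_000 for d in ("left", "right") for b in "ACGT"}

    def test_equal_counts_symmetric(self):
        track = IntervalTrack([("chr1", 0, 500, "left"), ("chr2", 0, 500, "right")])
        variants = [
            VariantLocus("chr1", 10, "C", "A"),
            VariantLocus("chr1", 20, "G", "T"),
        ]
        df = rclass_asymmetry(variants, track, self._territory(), seed=0)
        row = df[df["pair"] == "C>A/G>T"].iloc[0]
        assert row["n_leading"] == 1 and row["n_lagging"] == 1
        assert row["log2_asymmetry"] == 0.0

    def test_planted_leading_strand_bias(self):
        track = IntervalTrack([("chr1", 0, 1000, "left"), ("chr2", 0, 1000, "right")])
        variants = [VariantLocus("chr1", 2 * i + 1, "C", "A") for i in range(16)]
        variants += [VariantLocus("chr2", 2 * i + 1, "C", "A") for i in range(2)]
        df = rclass_asymmetry(variants, track, self._territory(), seed=0)
        row = df[df["pair"] == "C>A/G>T"].iloc[0]
        assert row["log2_asymmetry"] == pytest.approx(np.log2(16 / 2))
        assert row["asymmetry_ci"][0] > 0
        assert row["p_value"] < 0.01

    def test_zero_counts_reported_missing(self):
        track = IntervalTrack([("chr1", 0, 500, "left")])
        variants = [VariantLocus("chr1", 10, "C", "A")]
        df = rclass_asymmetry(variants, track, self._territory(), seed=0)
        row = df[df["pair"] == "T>A/A>T"].iloc[0]
        assert row["log2_asymmetry"] is None or np.isnan(row["log2_asymmetry"])

    def test_boundary_beta_ci(self):
        track = IntervalTrack([("chr1", 0, 500, "left")])
        territory = {("left", b): 1_000_000 for b in "ACGT"}
        df = rclass_asymmetry([], track, territory, seed=0)
        row = df[df["pair"] == "C>A/G>T"].iloc[0]
        lo, hi = row["rate_leading_ci"]
        assert lo == pytest.approx(0, abs=0.05)  # per Mb; essentially zero
        from scipy import stats

        want_hi = 1e6 * stats.beta.ppf(0.975, 1, 1_000_000 + 1)
        assert hi == pytest.approx(want_hi, rel=1e-9)


class TestSignatureProjection:
    def _signatures(self):
        W = np.zeros((96, 2))
        W[:48, 0] = 1 / 48
        W[48:, 1] = 1 / 48
        return W

    def test_exact_factorization_recovered(self):
        W = self._signatures()
        h = np.array([[10.0, 5.0], [30.0, 1.0]])
        X = W @ h
        d = project_signatures(X, W)
        assert np.max(np.abs(d.H - h)) < 1e-6
        assert d.kl < 1e-10

    def test_single_signature_closed_form(self):
        W = np.full((96, 1), 1 / 96)
        X = np.abs(np.sin(np.arange(96 * 3)).reshape(96, 3)) + 0.1
        d = project_signatures(X, W)
        # K=1: H equals the column sums of X (W column sums to 1)
        assert np.allclose(d.H[0], X.sum(axis=0), rtol=1e-6)

    def test_zero_matrix(self):
        d = project_signatures(np.zeros((96, 2)), self._signatures())
        assert np.array_equal(d.H, np.zeros((2, 2)))

    def test_zero_signature_column_error(self):
        W = self._signatures()
        W[:, 1] = 0
        with pytest.raises(ValueError, match="all-zero column"):
            project_signatures(np.ones((96, 1)), W)


class TestSubtraction:
    def test_zero_activity_no_change(self):
        W = np.full((96, 1), 1 / 96)
        d = project_signatures(np.zeros((96, 2)), W)
        segs = [SegmentCount("e1", 10, 1), SegmentCount("e2", 5, 2)]
        out = subtract_signature(d, 0, segs)
        assert out == segs

    def test_ten_percent_contribution(self):
        from lineageseq.spectra import SignatureDecomposition

        W = np.full((96, 1), 1 / 96)
        H = np.array([[10.0]])
        d = SignatureDecomposition(np.zeros((96, 1)), W, H, 0.0, 1)
        out = subtract_signature(d, 0, [SegmentCount("e1", 100, 1)])
        assert out[0].y == pytest.approx(90.0)

    def test_floor_at_zero(self):
        from lineageseq.spectra import SignatureDecomposition

        W = np.full((96, 1), 1 / 96)
        H = np.array([[50.0]])
        d = SignatureDecomposition(np.zeros((96, 1)), W, H, 0.0, 1)
        out = subtract_signature(d, 0, [SegmentCount("e1", 10, 1)])
        assert out[0].y == 0.0

    def test_rate_ratio_after_subtraction(self):
        """Removing an artifact signature's contribution moves the
        between-line rate ratio from ~7x to ~9x (printed-arithmetic
        check on the published magnitudes)."""
        from lineageseq import estimate_rate

        ht115 = estimate_rate([SegmentCount("all", 173, 1)], G=5.7e9)
        rpe1 = estimate_rate([SegmentCount("all", 39, 1)], G=9.2e9)
        assert round(ht115.per_bp / rpe1.per_bp) == 7
        rpe1_adj = estimate_rate([SegmentCount("all", 30.4, 1)], G=9.2e9)
        assert rpe1_adj.per_bp == pytest.approx(3.3e-9, rel=0.01)
        assert 8.5 < ht115.per_bp / rpe1_adj.per_bp < 10
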
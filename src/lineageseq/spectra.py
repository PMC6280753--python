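"""96-channel trinucleotide mutation spectra and genomic-context analyses.

Each substitution is expressed on the pyrimidine strand (purine-reference
events are reverse-complemented) and binned into one of 96 channels: six
substitution classes (C>A, C>G, C>T, T>A, T>C, T>G) x four 5' bases x four
3' bases, ordered alphabetically within each class block.  On top of the
spectrum sit cosine similarity with bootstrap CIs, genic/timing-class
enrichment, replication-class (leading/lagging strand) asymmetry, and the
frozen-signature KL projection used to subtract in-vitro artifact
signatures from per-segment counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import IntervalTrack, VariantLocus
from .rates import SegmentCount

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTION_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
CHANNELS = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in "ACGT"
    for three in "ACGT"
]
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def channel_of(ref: str, alt: str, five: str, three: str) -> str:
    """Canonical pyrimidine-strand channel of a substitution in context."""
    if ref in "AG":  # purine reference: flip to the pyrimidine partner
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five, three = _COMPLEMENT[three], _COMPLEMENT[five]
    return f"{five}[{ref}>{alt}]{three}"


@dataclass
class Spectrum96:
    """Counts over the 96 canonical trinucleotide channels."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=float))
    n_skipped: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have exactly 96 channels")
        if (self.counts < 0).any():
            raise ValueError("negative channel counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty spectrum")
        return self.counts / self.total

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=CHANNELS, name="count")


def _fetch_context(reference, chrom: str, pos: int) -> Optional[str]:
    """Trinucleotide centred at 1-based pos, or None at a contig edge."""
    if isinstance(reference, dict):
        seq = reference.get(chrom)
        if seq is None or pos < 2 or pos + 1 > len(seq):
            return None
        return seq[pos - 2: pos + 1].upper()
    # pyfaidx.Fasta-like
    if chrom not in reference:
        return None
    record = reference[chrom]
    if pos < 2 or pos + 1 > len(record):
        return None
    return str(record[pos - 2: pos + 1]).upper()


def build_spectrum(variants: Sequence, reference) -> Spectrum96:
    """Bin variants into the 96-channel spectrum.

    ``reference`` is a pyfaidx.Fasta, a path to a FASTA, or a
    {chrom: sequence} dict.  Variants at contig edges or with N in the
    flank are skipped with a warning.
    """
    if isinstance(reference, str):
        import pyfaidx

        reference = pyfaidx.Fasta(reference)
    spec = Spectrum96()
    for v in variants:
        vl = v if isinstance(v, VariantLocus) else v.variant_locus
        ctx = _fetch_context(reference, vl.chrom, vl.pos)
        if ctx is None:
            logger.warning("no +/-1 bp context at %s:%d; skipped", vl.chrom, vl.pos)
            spec.n_skipped += 1
            continue
        if any(b not in "ACGT" for b in ctx):
            logger.warning("ambiguous context %s at %s:%d; skipped", ctx, vl.chrom, vl.pos)
            spec.n_skipped += 1
            continue
        if ctx[1] != vl.ref:
            logger.warning(
                "reference mismatch at %s:%d (%s vs %s); skipped",
                vl.chrom, vl.pos, ctx[1], vl.ref,
            )
            spec.n_skipped += 1
            continue
        ch = channel_of(vl.ref, vl.alt, ctx[0], ctx[2])
        spec.counts[_CHANNEL_INDEX[ch]] += 1
    return spec


# ---------------------------------------------------------------------------
# Cosine similarity
# ---------------------------------------------------------------------------


def cosine_similarity(
    a: Spectrum96,
    b: Spectrum96,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """sim(A,B) = sum A_i B_i / (||A|| ||B||), with a 95% CI from
    bootstrap-resampling each underlying variant list (multinomial
    resampling of the channel counts)."""
    va, vb = a.counts, b.counts
    if not va.any() or not vb.any():
        raise ValueError("cosine similarity undefined for a zero spectrum")

    def cos(x, y):
        return float(x @ y / (np.linalg.norm(x) * np.linalg.norm(y)))

    sim = cos(va, vb)
    if n_boot <= 0:
        return sim, (sim, sim)
    rng = np.random.default_rng(seed)
    na, nb = int(round(va.sum())), int(round(vb.sum()))
    boots = np.empty(n_boot)
    pa, pb = va / va.sum(), vb / vb.sum()
    ra = rng.multinomial(na, pa, size=n_boot)
    rb = rng.multinomial(nb, pb, size=n_boot)
    for k in range(n_boot):
        xa, xb = ra[k], rb[k]
        if not xa.any() or not xb.any():
            boots[k] = np.nan
            continue
        boots[k] = cos(xa, xb)
    lo, hi = np.nanquantile(boots, [0.025, 0.975])
    return sim, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Region enrichment
# ---------------------------------------------------------------------------


def region_enrichment(
    variants: Sequence,
    regions: IntervalTrack,
    copy_track: Optional[IntervalTrack] = None,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-class log2(observed/expected) with one-tailed binomial p and a
    bootstrap CI.

    Expected counts distribute the classified variants in proportion to
    each class's copy-weighted genomic territory, so expected sums to
    observed exactly.  Classes with zero territory are excluded with a
    warning.
    """
    classes = regions.payload_classes()
    weighted: dict = {}
    for cls in classes:
        w = regions.weighted_bp(weights=copy_track, payload=cls)
        if w == 0:
            logger.warning("class %r has zero territory; excluded", cls)
            continue
        weighted[cls] = w
    if not weighted:
        raise ValueError("no region class with non-zero territory")
    total_w = sum(weighted.values())

    labels = []
    for v in variants:
        vl = v if isinstance(v, VariantLocus) else v.variant_locus
        cls = regions.lookup(vl.chrom, vl.pos)
        if cls in weighted:
            labels.append(cls)
    n = len(labels)
    if n == 0:
        raise ValueError("no variants fall in the region classes")
    obs = {cls: labels.count(cls) for cls in weighted}
    rng = np.random.default_rng(seed)
    share = {cls: weighted[cls] / total_w for cls in weighted}
    label_arr = np.array([list(weighted).index(c) for c in labels])
    boot_counts = None
    if n_boot > 0:
        resampled = rng.integers(0, n, size=(n_boot, n))
        drawn = label_arr[resampled]
        boot_counts = np.stack(
            [(drawn == k).sum(axis=1) for k in range(len(weighted))], axis=1
        )

    rows = []
    for k, cls in enumerate(weighted):
        expected = n * share[cls]
        o = obs[cls]
        log2_ratio = (
            float(np.log2(o / expected)) if o > 0 else -np.inf
        )
        alternative = "greater" if o >= expected else "less"
        p = stats.binomtest(o, n, share[cls], alternative=alternative).pvalue
        if boot_counts is not None:
            with np.errstate(divide="ignore"):
                boot_ratio = np.log2(boot_counts[:, k] / expected)
            lo, hi = np.quantile(boot_ratio, [0.025, 0.975])
        else:
            lo = hi = log2_ratio
        rows.append(
            {
                "region_class": cls,
                "observed": o,
                "expected": expected,
                "log2_ratio": log2_ratio,
                "p_value": float(p),
                "significant": bool(p < alpha),
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Replication timing / direction
# ---------------------------------------------------------------------------


def classify_timing(value: float) -> str:
    """Early (>=60), intermediate, or late (<=33) replication-timing class."""
    if value >= 60:
        return "early"
    if value <= 33:
        return "late"
    return "intermediate"


def classify_slope(slope: float) -> str:
    """Replication direction from the timing-profile slope (units/interval):
    right-replicating for 0.1 < slope < 0.3, left for -0.3 < slope < -0.1,
    undefined otherwise."""
    if 0.1 < slope < 0.3:
        return "right"
    if -0.3 < slope < -0.1:
        return "left"
    return "undefined"


def timing_class_track(timing: IntervalTrack) -> IntervalTrack:
    """Map a numeric timing-value track to early/intermediate/late classes."""
    return IntervalTrack(
        [(c, s, e, classify_timing(float(v))) for c, s, e, v in timing]
    )


def slope_track_from_timing(timing: IntervalTrack) -> IntervalTrack:
    """Finite-difference slopes over adjacent intervals of a numeric timing
    track (one value per interval; slope assigned to the left interval)."""
    intervals = list(timing)
    out = []
    for (c1, s1, e1, v1), (c2, s2, e2, v2) in zip(intervals, intervals[1:]):
        if c1 != c2:
            continue
        out.append((c1, s1, e1, float(v2) - float(v1)))
    return IntervalTrack(out)


def direction_track_from_slopes(slopes: IntervalTrack) -> IntervalTrack:
    ivs = [
        (c, s, e, classify_slope(float(v)))
        for c, s, e, v in slopes
        if classify_slope(float(v)) != "undefined"
    ]
    return IntervalTrack(ivs)


# ---------------------------------------------------------------------------
# Replication-class (leading/lagging strand) asymmetry
# ---------------------------------------------------------------------------

_PAIRS = [("C>A", "G>T"), ("C>G", "G>C"), ("C>T", "G>A"),
          ("T>A", "A>T"), ("T>C", "A>G"), ("T>G", "A>C")]


def rclass_asymmetry(
    variants: Sequence,
    direction_track: IntervalTrack,
    base_territory: dict,
    n_beta: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Leading-strand mutation rates and asymmetries.

    ``base_territory``: {("left"|"right", base): bp} — the number of
    reference-strand occurrences of each base within the left-/right-
    replicating territory.

    For each complementary substitution pair (e.g. C>A / G>T) the
    leading-strand count pools the pyrimidine-reference substitution in
    left-replicating regions with its purine complement in
    right-replicating regions (and vice versa for the lagging strand).
    Rates are per Mb of matching base territory with Beta(n+1, N-n+1) 95%
    CIs; the asymmetry is log2 of the count ratio with a CI from sampled
    beta pairs and a binomial p under the base-composition null.
    """
    rng = np.random.default_rng(seed)
    counts: dict[tuple, int] = {}
    for v in variants:
        vl = v if isinstance(v, VariantLocus) else v.variant_locus
        direction = direction_track.lookup(vl.chrom, vl.pos)
        if direction not in ("left", "right"):
            continue
        counts[(direction, f"{vl.ref}>{vl.alt}")] = (
            counts.get((direction, f"{vl.ref}>{vl.alt}"), 0) + 1
        )

    rows = []
    for pyr_sub, pur_sub in _PAIRS:
        pyr_base, pur_base = pyr_sub[0], pur_sub[0]
        # leading strand: pyrimidine sub in left regions + purine in right
        n_lead = counts.get(("left", pyr_sub), 0) + counts.get(("right", pur_sub), 0)
        n_lag = counts.get(("left", pur_sub), 0) + counts.get(("right", pyr_sub), 0)
        N_lead = base_territory.get(("left", pyr_base), 0) + base_territory.get(
            ("right", pur_base), 0
        )
        N_lag = base_territory.get(("left", pur_base), 0) + base_territory.get(
            ("right", pyr_base), 0
        )
        if N_lead == 0 or N_lag == 0:
            logger.warning("pair %s/%s has zero base territory; skipped",
                           pyr_sub, pur_sub)
            continue
        rate_lead = n_lead / N_lead * 1e6
        rate_lag = n_lag / N_lag * 1e6
        ci_lead = tuple(
            1e6 * stats.beta.ppf([0.025, 0.975], n_lead + 1, N_lead - n_lead + 1)
        )
        ci_lag = tuple(
            1e6 * stats.beta.ppf([0.025, 0.975], n_lag + 1, N_lag - n_lag + 1)
        )
        if n_lead == 0 and n_lag == 0:
            log2_ratio, ci_ratio, p = None, (None, None), None
        else:
            log2_ratio = (
                float(np.log2(n_lead / n_lag))
                if n_lead > 0 and n_lag > 0
                else (np.inf if n_lag == 0 else -np.inf)
            )
            b1 = rng.beta(n_lead + 1, N_lead - n_lead + 1, size=n_beta)
            b2 = rng.beta(n_lag + 1, N_lag - n_lag + 1, size=n_beta)
            q = np.log2(b1 / b2)
            ci_ratio = tuple(float(x) for x in np.quantile(q, [0.025, 0.975]))
            p0 = N_lead / (N_lead + N_lag)
            p = float(
                stats.binomtest(n_lead, n_lead + n_lag, p0).pvalue
            )
        rows.append(
            {
                "pair": f"{pyr_sub}/{pur_sub}",
                "n_leading": n_lead,
                "n_lagging": n_lag,
                "rate_leading_per_mb": rate_lead,
                "rate_lagging_per_mb": rate_lag,
                "rate_leading_ci": ci_lead,
                "rate_lagging_ci": ci_lag,
                "log2_asymmetry": log2_ratio,
                "asymmetry_ci": ci_ratio,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Frozen-signature KL projection
# ---------------------------------------------------------------------------


@dataclass
class SignatureDecomposition:
    X: np.ndarray  # 96 x N counts
    W: np.ndarray  # 96 x K frozen signatures (columns sum to 1)
    H: np.ndarray  # K x N activities
    kl: float
    n_iter: int


def _kl_divergence(X, WH) -> float:
    eps = 1e-12
    WH = np.maximum(WH, eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(X > 0, X * np.log(X / WH), 0.0)
    return float(term.sum() - X.sum() + WH.sum())


def project_signatures(
    X: np.ndarray,
    W: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> SignatureDecomposition:
    """Fit non-negative activities H so that X ~ W H, with W strictly
    frozen, by multiplicative KL updates of H only.

    The KL objective is asserted non-increasing at every update; H is
    initialized uniform positive for determinism.
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if W.ndim == 1:
        W = W[:, None]
    if (W < 0).any() or (X < 0).any():
        raise ValueError("X and W must be non-negative")
    col_sums = W.sum(axis=0)
    if (col_sums == 0).any():
        raise ValueError("W contains an all-zero column")
    K, N = W.shape[1], X.shape[1]
    if X.shape[0] != W.shape[0]:
        raise ValueError("X and W row dimensions differ")
    if not X.any():
        return SignatureDecomposition(X, W, np.zeros((K, N)), 0.0, 0)
    H = np.full((K, N), X.sum() / (K * N) + 1e-9)
    eps = 1e-12
    kl = _kl_divergence(X, W @ H)
    for it in range(max_iter):
        WH = np.maximum(W @ H, eps)
        H = H * (W.T @ (X / WH)) / np.maximum(col_sums[:, None], eps)
        new_kl = _kl_divergence(X, W @ H)
        if new_kl > kl + 1e-9 * max(1.0, abs(kl)):
            raise RuntimeError("KL objective increased during update")
        if kl - new_kl < tol * max(1.0, abs(kl)):
            kl = new_kl
            break
        kl = new_kl
    return SignatureDecomposition(X, W, H, kl, it + 1)


def subtract_signature(
    decomp: SignatureDecomposition,
    k: int,
    segments: Sequence[SegmentCount],
    column_of_segment: Optional[dict] = None,
) -> list[SegmentCount]:
    """Remove signature k's fitted contribution from per-segment counts.

    With W columns normalized to 1, signature k contributes H[k, j] of
    segment j's count; adjusted counts are floored at zero.
    """
    if not (0 <= k < decomp.W.shape[1]):
        raise ValueError(f"signature index {k} out of range")
    contrib_per_col = decomp.W[:, k].sum() * decomp.H[k]
    out = []
    for j, seg in enumerate(segments):
        seg = SegmentCount(*seg)
        col = column_of_segment[seg.edge_id] if column_of_segment else j
        adj = max(0.0, seg.y - float(contrib_per_col[col]))
        out.append(SegmentCount(seg.edge_id, adj, seg.n))
    return out
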
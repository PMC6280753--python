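"""Coincident SNV grouping and binomial membership scoring.

An SNV observed at the same locus in two or more (but not all) subclones is
a *coincident* candidate.  Each subclone is assigned to the variant or the
reference group and the probability that its allele counts belong to the
assigned group rather than the other is scored with a binomial posterior

    posterior = P1 / (P1 + P2),

where P1 and P2 are binomial likelihoods of the observed alt count under
the assigned and the non-assigned group's alt-allele probability.  The
minimum posterior over samples is the group's quality; groups below the
quality threshold (default 0.99) are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence, Union

import numpy as np
from scipy.special import expit
from scipy.stats import binom

from .core import (
    AlleleCounts,
    BranchVariant,
    Clade,
    CoincidentGroup,
    LeafVariant,
    LocusCountTable,
    RawSnv,
    ScoreBreakdown,
    VariantLocus,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringParams:
    """Parameters of the two-group binomial membership score.

    f_alt: expected clonal alt fraction in the variant group (0.5 for a
        heterozygous variant on a diploid locus; use ``copy_aware_f_alt``
        for other ploidies).
    eps_ref: expected alt fraction in the reference group (sequencing
        error floor).
    q_threshold: minimum quality; groups scoring strictly below are
        rejected.
    min_alt_reads: minimum alt reads required in every variant-group
        sample.
    """

    f_alt: float = 0.5
    eps_ref: float = 0.005
    q_threshold: float = 0.99
    min_alt_reads: int = 5

    def __post_init__(self):
        if not (0 < self.eps_ref < self.f_alt <= 1):
            raise ValueError("need 0 < eps_ref < f_alt <= 1")
        if not (0 < self.q_threshold < 1):
            raise ValueError("q_threshold must be in (0,1)")


def copy_aware_f_alt(variant_copies: int, copy_number: int) -> float:
    """Expected clonal alt fraction m/CN for a variant on ``variant_copies``
    of ``copy_number`` local copies."""
    if not (1 <= variant_copies <= copy_number):
        raise ValueError("need 1 <= variant_copies <= copy_number")
    return variant_copies / copy_number


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------


@dataclass
class GroupingResult:
    candidates: list[CoincidentGroup]
    leaf_snvs: list[RawSnv]
    founder_loci: list[VariantLocus]


def group_coincident(raw: Sequence[RawSnv], n_subclones: int) -> GroupingResult:
    """Group raw SNVs into coincident candidates.

    SNVs present in >=2 and < all subclones become candidates; SNVs in
    exactly one subclone are routed to the leaf-variant stream; SNVs in all
    subclones are discarded as founder variants (present in the founding
    cell).
    """
    if n_subclones < 3:
        raise ValueError(
            "need at least 3 subclones to distinguish branch from founder variants"
        )
    by_variant: dict[VariantLocus, set[str]] = {}
    for snv in raw:
        by_variant.setdefault(snv.variant_locus, set()).add(snv.subclone_id)
    candidates, leaf_snvs, founders = [], [], []
    for vl in sorted(by_variant):
        carriers = by_variant[vl]
        if len(carriers) == 1:
            (sid,) = carriers
            leaf_snvs.append(RawSnv(vl.chrom, vl.pos, vl.ref, vl.alt, sid))
        elif len(carriers) >= n_subclones:
            founders.append(vl)
        else:
            candidates.append(CoincidentGroup(vl, frozenset(carriers)))
    return GroupingResult(candidates, leaf_snvs, founders)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def membership_posterior(
    counts: AlleleCounts, assigned_p: float, other_p: float
) -> ScoreBreakdown:
    """Posterior that a sample's allele counts belong to its assigned group.

    Computed in log space: posterior = P1/(P1+P2) with P1, P2 the binomial
    pmfs of the observed alt count under the assigned / other group's alt
    probability.  Raises on zero coverage (the caller decides how to treat
    unscorable samples).
    """
    counts = AlleleCounts(*counts)
    if counts.total == 0:
        raise ValueError("no coverage: membership posterior undefined")
    for p in (assigned_p, other_p):
        if not (0 < p < 1):
            raise ValueError("group probabilities must be in (0,1)")
    logp1 = binom.logpmf(counts.alt_n, counts.total, assigned_p)
    logp2 = binom.logpmf(counts.alt_n, counts.total, other_p)
    posterior = float(expit(logp1 - logp2))
    return ScoreBreakdown(
        p1=float(np.exp(logp1)), p2=float(np.exp(logp2)), posterior=posterior
    )


def _variant_posteriors(
    ref_n: np.ndarray, alt_n: np.ndarray, params: ScoringParams
) -> np.ndarray:
    """Per-sample posterior of belonging to the *variant* group (vectorized).

    The reference-group posterior is its complement.  Zero-coverage samples
    get the neutral value 0.5.
    """
    total = ref_n + alt_n
    with np.errstate(divide="ignore", invalid="ignore"):
        log_f = binom.logpmf(alt_n, total, params.f_alt)
        log_e = binom.logpmf(alt_n, total, params.eps_ref)
    pv = expit(log_f - log_e)
    pv = np.where(total == 0, 0.5, pv)
    return pv


def score_group(
    candidate: CoincidentGroup,
    counts: LocusCountTable,
    params: ScoringParams = ScoringParams(),
) -> CoincidentGroup:
    """Score a candidate group: quality = min over subclones of the
    membership posterior.

    Variant-group samples failing the ``min_alt_reads`` read-support filter
    mark the candidate rejected before scoring.  Zero-coverage samples
    contribute a neutral posterior of 0.5 with a warning.
    """
    vl = candidate.variant_locus
    ref_n, alt_n = counts.row(vl)
    breakdowns: dict[str, ScoreBreakdown] = {}
    quality = 1.0
    for j, sid in enumerate(counts.subclones):
        in_set = sid in candidate.variant_set
        if in_set and alt_n[j] < params.min_alt_reads:
            return replace(candidate, quality=None, rejected="low_alt_support")
    for j, sid in enumerate(counts.subclones):
        in_set = sid in candidate.variant_set
        cell = AlleleCounts(int(ref_n[j]), int(alt_n[j]))
        if cell.total == 0:
            logger.warning(
                "zero coverage for %s at %s:%d; neutral posterior 0.5",
                sid, vl.chrom, vl.pos,
            )
            bd = ScoreBreakdown(p1=np.nan, p2=np.nan, posterior=0.5)
        else:
            assigned = params.f_alt if in_set else params.eps_ref
            other = params.eps_ref if in_set else params.f_alt
            bd = membership_posterior(cell, assigned, other)
        breakdowns[sid] = bd
        quality = min(quality, bd.posterior)
    return replace(
        candidate, quality=float(quality), breakdowns=breakdowns, rejected=None
    )


def brute_force_min_posterior(
    candidate: CoincidentGroup,
    counts: LocusCountTable,
    params: ScoringParams = ScoringParams(),
) -> float:
    """Independent per-sample enumeration of the min posterior (test oracle;
    no vectorization, no read-support filter)."""
    import math

    vl = candidate.variant_locus
    best = 1.0
    for sid in counts.subclones:
        cell = counts.counts(vl, sid)
        if cell.total == 0:
            post = 0.5
        else:
            assigned = params.f_alt if sid in candidate.variant_set else params.eps_ref
            other = params.eps_ref if sid in candidate.variant_set else params.f_alt
            p1 = math.comb(cell.total, cell.alt_n) * assigned**cell.alt_n * (
                1 - assigned
            ) ** (cell.total - cell.alt_n)
            p2 = math.comb(cell.total, cell.alt_n) * other**cell.alt_n * (
                1 - other
            ) ** (cell.total - cell.alt_n)
            post = p1 / (p1 + p2)
        best = min(best, post)
    return best


# ---------------------------------------------------------------------------
# LOH filter
# ---------------------------------------------------------------------------


def loh_filter(
    variants: Sequence[Union[CoincidentGroup, BranchVariant, LeafVariant]],
    counts: LocusCountTable,
) -> tuple[list, list]:
    """Split variants into (kept, flagged) by the loss-of-heterozygosity
    rule: flagged when, pooled over carrier samples, the alt allele
    fraction is > 0.85 and the reference allele fraction is < 0.85 (strict
    inequalities)."""
    kept, flagged = [], []
    for v in variants:
        if isinstance(v, LeafVariant):
            carriers: Clade = frozenset([v.subclone_id])
            vl = v.variant_locus
        elif isinstance(v, BranchVariant):
            carriers = v.clade
            vl = v.variant_locus
        else:
            carriers = v.variant_set
            vl = v.variant_locus
        ref_n, alt_n = counts.row(vl)
        idx = [j for j, s in enumerate(counts.subclones) if s in carriers]
        ref_tot = int(ref_n[idx].sum())
        alt_tot = int(alt_n[idx].sum())
        total = ref_tot + alt_tot
        if total == 0:
            kept.append(v)
            continue
        alt_frac = alt_tot / total
        ref_frac = ref_tot / total
        if alt_frac > 0.85 and ref_frac < 0.85:
            flagged.append(v)
        else:
            kept.append(v)
    return kept, flagged
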
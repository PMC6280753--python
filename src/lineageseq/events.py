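"""Correlated mutation events.

Three analyses on top of the branch/leaf call sets:

* nearest-neighbour distances between SNVs of the same sublineage versus a
  uniform-placement null (multinucleotide variants at <= 1 bp, clustered
  events at <= 100 bp by default);
* same-site multi-allele events — two different substitutions at one locus
  in related sublineages, the signature of a persistent DNA lesion copied
  through successive replications — scored with a three-group
  (reference / alt1 / alt2) membership posterior;
* overlap and lineage-congruence statistics: an empirical binomial null
  for the number of same-position coincidences, and the probability that
  all observed same-site pairs fall within one proper sublineage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .coincidence import ScoringParams
from .core import LineageTree, LocusCountTable, VariantLocus

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Nearest-neighbour distances / MNV detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterNull:
    n_variants: int
    genome_length: int
    n_sims: int = 1000
    seed: int = 0


@dataclass
class DistanceReport:
    within_distances: np.ndarray
    across_distances: np.ndarray
    n_mnv_pairs: int
    n_clustered_pairs: int
    null_close_fraction: float
    observed_close_fraction: float
    p_value: float


def _nearest_distances(positions_by_chrom: dict) -> np.ndarray:
    out = []
    for chrom, pos in positions_by_chrom.items():
        pos = np.sort(np.asarray(pos))
        if len(pos) < 2:
            continue
        diffs = np.diff(pos)
        nearest = np.minimum(
            np.concatenate([[diffs[0]], diffs]),
            np.concatenate([diffs, [diffs[-1]]]),
        )
        out.append(nearest)
    if not out:
        return np.array([], dtype=np.int64)
    return np.concatenate(out)


def nearest_distance_test(
    variants_by_group: dict,
    null: ClusterNull,
    window: int = 100,
    mnv_window: int = 1,
) -> DistanceReport:
    """Nearest-neighbour distance analysis against uniform placement.

    ``variants_by_group`` maps a sublineage key (edge id or subclone set)
    to its variant loci.  Within-group distances power the MNV/cluster
    calls; across-group distances (each variant's nearest neighbour in a
    *different* group) are reported for comparison.  The null close-pair
    fraction comes from ``null.n_sims`` uniform placements of
    ``null.n_variants`` positions.
    """
    all_positions: list[tuple[str, int, int]] = []  # (chrom, pos, group idx)
    for g, (key, variants) in enumerate(sorted(variants_by_group.items(),
                                               key=lambda kv: str(kv[0]))):
        for v in variants:
            vl = v if isinstance(v, VariantLocus) else v.variant_locus
            all_positions.append((vl.chrom, vl.pos, g))
    if len(all_positions) < 2:
        raise ValueError("need >= 2 variants")

    within: dict[tuple, list[int]] = {}
    for chrom, pos, g in all_positions:
        within.setdefault((g, chrom), []).append(pos)
    within_d = _nearest_distances(
        {k: v for k, v in within.items()}
    )

    across_d = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, pos, g in all_positions:
        by_chrom.setdefault(chrom, []).append((pos, g))
    for chrom, entries in by_chrom.items():
        entries.sort()
        pos = np.array([p for p, _ in entries])
        grp = np.array([g for _, g in entries])
        for i in range(len(pos)):
            other = np.abs(pos - pos[i])[grp != grp[i]]
            if len(other):
                across_d.append(int(other.min()))
    across_d = np.array(across_d, dtype=np.int64)

    n_mnv = int((within_d <= mnv_window).sum() // 2) if len(within_d) else 0
    n_clustered = int((within_d <= window).sum() // 2) if len(within_d) else 0
    obs_frac = (
        float((within_d <= window).mean()) if len(within_d) else 0.0
    )

    rng = np.random.default_rng(null.seed)
    null_fracs = np.empty(null.n_sims)
    for s in range(null.n_sims):
        pos = np.sort(rng.integers(1, null.genome_length + 1, size=null.n_variants))
        d = _nearest_distances({("all", "g"): pos})
        null_fracs[s] = (d <= window).mean() if len(d) else 0.0
    p = float((1 + (null_fracs >= obs_frac).sum()) / (null.n_sims + 1))
    return DistanceReport(
        within_d, across_d, n_mnv, n_clustered,
        float(null_fracs.mean()), obs_frac, p,
    )


def uniform_close_pair_probability(n: int, genome_length: int, window: int) -> float:
    """Closed-form P(nearest-neighbour distance <= window) for one variant
    among n uniformly placed (oracle for the simulation null):
    1 - (1 - 2*window/G)^(n-1), to first order."""
    return 1.0 - (1.0 - min(1.0, 2 * window / genome_length)) ** (n - 1)


# ---------------------------------------------------------------------------
# Same-site (persistent lesion) events
# ---------------------------------------------------------------------------


@dataclass
class SameSiteEvent:
    chrom: str
    pos: int
    ref: str
    alt_a: str
    alt_b: str
    clade_a: frozenset
    clade_b: frozenset
    edge_a: str
    edge_b: str
    quality: float

    def __post_init__(self):
        if self.alt_a == self.alt_b:
            raise ValueError("same-site event needs two distinct alts")
        if self.clade_a & self.clade_b:
            raise ValueError("same-site subclone sets must be disjoint")


def _three_group_posterior(
    ref_n, alt1_n, alt2_n, assignment, centers, eps: float
) -> float:
    """Min over samples of the multinomial membership posterior
    P1/(P1+P2+P3), with group centers (f_alt1, f_alt2) per group."""
    n_samples = len(ref_n)
    min_post = 1.0
    for j in range(n_samples):
        total = ref_n[j] + alt1_n[j] + alt2_n[j]
        if total == 0:
            min_post = min(min_post, 0.5)
            continue
        counts = [ref_n[j], alt1_n[j], alt2_n[j]]
        logls = []
        for g in range(3):
            f1, f2 = centers[g]
            f1 = min(max(f1, eps), 1 - 2 * eps)
            f2 = min(max(f2, eps), 1 - 2 * eps)
            p = [max(1 - f1 - f2, eps), f1, f2]
            p = np.array(p) / sum(p)
            logls.append(stats.multinomial.logpmf(counts, total, p))
        logls = np.array(logls)
        post = float(np.exp(logls[assignment[j]] - np.logaddexp.reduce(logls)))
        min_post = min(min_post, post)
    return min_post


def detect_same_site(
    counts: LocusCountTable,
    tree: LineageTree,
    params: ScoringParams = ScoringParams(),
) -> list[SameSiteEvent]:
    """Find loci carrying two different alternate alleles in disjoint,
    tree-consistent subclone sets.

    Samples are clustered into three groups (reference / alt1 / alt2) on
    their two alt-allele fractions; cluster centers parameterize a
    multinomial likelihood, and the event quality is the minimum sample
    posterior P1/(P1+P2+P3).  Events are accepted when the quality reaches
    the threshold and both alt sets map onto tree segments.
    """
    by_pos: dict[tuple, list[VariantLocus]] = {}
    for vl in counts.loci:
        by_pos.setdefault((vl.chrom, vl.pos), []).append(vl)
    events: list[SameSiteEvent] = []
    for (chrom, pos), rows in sorted(by_pos.items()):
        alts = sorted(set(r.alt for r in rows))
        if len(alts) < 2:
            continue
        if len(alts) > 2:
            logger.warning("%s:%d has >2 alts; using the two best-supported",
                           chrom, pos)
            totals = {
                a: counts.row(next(r for r in rows if r.alt == a))[1].sum()
                for a in alts
            }
            alts = sorted(sorted(alts, key=lambda a: -totals[a])[:2])
        row_a = next(r for r in rows if r.alt == alts[0])
        row_b = next(r for r in rows if r.alt == alts[1])
        ref_a, alt1_n = counts.row(row_a)
        ref_b, alt2_n = counts.row(row_b)
        ref_n = np.minimum(ref_a, ref_b)
        total = ref_n + alt1_n + alt2_n
        with np.errstate(invalid="ignore"):
            f1 = np.where(total > 0, alt1_n / np.maximum(total, 1), 0.0)
            f2 = np.where(total > 0, alt2_n / np.maximum(total, 1), 0.0)
        X = np.stack([f1, f2], axis=1)
        if np.allclose(X, X[0]):
            continue
        Z = linkage(X, method="average")
        labels = fcluster(Z, t=3, criterion="maxclust")
        if len(set(labels)) < 3:
            continue
        # identify the roles of the three clusters by their centers
        centers_by_label = {
            lab: X[labels == lab].mean(axis=0) for lab in set(labels)
        }
        ref_label = min(centers_by_label, key=lambda l: centers_by_label[l].sum())
        others = [l for l in centers_by_label if l != ref_label]
        a_label = max(others, key=lambda l: centers_by_label[l][0])
        b_label = [l for l in others if l != a_label][0]
        if centers_by_label[a_label][0] <= centers_by_label[ref_label][0]:
            continue
        if centers_by_label[b_label][1] <= centers_by_label[ref_label][1]:
            continue
        role = {ref_label: 0, a_label: 1, b_label: 2}
        assignment = np.array([role[l] for l in labels])
        set_a = frozenset(
            s for s, r in zip(counts.subclones, assignment) if r == 1
        )
        set_b = frozenset(
            s for s, r in zip(counts.subclones, assignment) if r == 2
        )
        if not set_a or not set_b or (set_a & set_b):
            continue
        if not (tree.is_consistent(set_a) and tree.is_consistent(set_b)):
            continue
        centers = {
            0: tuple(centers_by_label[ref_label]),
            1: tuple(centers_by_label[a_label]),
            2: tuple(centers_by_label[b_label]),
        }
        q = _three_group_posterior(
            ref_n, alt1_n, alt2_n, assignment, centers, params.eps_ref
        )
        if q < params.q_threshold:
            continue
        # read-support filter on both carrier sets
        idx_a = [j for j, s in enumerate(counts.subclones) if s in set_a]
        idx_b = [j for j, s in enumerate(counts.subclones) if s in set_b]
        if min(alt1_n[j] for j in idx_a) < params.min_alt_reads:
            continue
        if min(alt2_n[j] for j in idx_b) < params.min_alt_reads:
            continue
        events.append(
            SameSiteEvent(
                chrom, pos, row_a.ref, alts[0], alts[1],
                set_a, set_b,
                tree.edge_id_of(set_a), tree.edge_id_of(set_b),
                q,
            )
        )
    return events


# ---------------------------------------------------------------------------
# Overlap statistics
# ---------------------------------------------------------------------------


def empirical_overlap_rate(
    n_overlaps: int, n_ancestor_separating: int, n_independent_leaf: int
) -> tuple[float, int]:
    """Per-variant overlap rate from an independent comparison set.

    The effective number of comparisons pools the SNVs separating the
    outgroup subclone from the lineage founder with the leaf variants that
    accumulated independently inside the lineage; the rate is
    observed overlaps / that denominator.
    """
    n = n_ancestor_separating + n_independent_leaf
    if n <= 0:
        raise ValueError("empty comparison set")
    return n_overlaps / n, n


def overlap_pvalue(
    k_observed: int,
    n_variants: int,
    null_rate: float,
    n_sims: int = 10**5,
    seed: int = 0,
) -> dict:
    """Empirical p for observing >= k same-position overlaps among n
    variants given a per-variant null overlap rate (binomial model), plus
    the exact binomial tail as oracle."""
    if not (0 <= null_rate <= 1):
        raise ValueError("null_rate must be in [0,1]")
    if k_observed < 0:
        raise ValueError("k_observed must be >= 0")
    rng = np.random.default_rng(seed)
    if k_observed == 0:
        return {"p_empirical": 1.0, "p_exact": 1.0}
    sims = rng.binomial(n_variants, null_rate, size=n_sims)
    p_emp = float((1 + (sims >= k_observed).sum()) / (n_sims + 1))
    p_exact = float(stats.binom.sf(k_observed - 1, n_variants, null_rate))
    return {"p_empirical": p_emp, "p_exact": p_exact}


# ---------------------------------------------------------------------------
# Lineage congruence
# ---------------------------------------------------------------------------


def is_congruent(tree: LineageTree, clade_a, clade_b) -> bool:
    """Two segments are congruent (fall within one proper sublineage) when
    the MRCA of their clades is not the root."""
    return tree.mrca(clade_a, clade_b) is not tree.root


def congruence_test(
    events: Sequence[SameSiteEvent],
    call_clades: Sequence,
    tree: LineageTree,
    n_sims: int = 500_000,
    seed: int = 0,
) -> dict:
    """Fraction of same-site events congruent with the lineage, and the
    null probability that all of them would be.

    The null draws pairs of segments from the empirical distribution of
    the call set's subclone sets (branch clades and leaf singletons) and
    asks how often ``len(events)`` independent pairs are all congruent.
    """
    if not call_clades:
        raise ValueError("empty call set")
    k = len(events)
    observed = [is_congruent(tree, e.clade_a, e.clade_b) for e in events]
    frac = float(np.mean(observed)) if events else float("nan")
    unique = sorted({frozenset(c) for c in call_clades},
                    key=lambda c: sorted(c))
    weights = np.array(
        [sum(1 for c in call_clades if frozenset(c) == u) for u in unique],
        dtype=float,
    )
    weights /= weights.sum()
    m = len(unique)
    cong = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(m):
            cong[i, j] = is_congruent(tree, unique[i], unique[j])
    rng = np.random.default_rng(seed)
    if k == 0:
        return {"fraction_congruent": frac, "p_all_congruent": 1.0}
    draws_a = rng.choice(m, size=(n_sims, k), p=weights)
    draws_b = rng.choice(m, size=(n_sims, k), p=weights)
    all_cong = cong[draws_a, draws_b].all(axis=1)
    p = float((1 + all_cong.sum()) / (n_sims + 1))
    return {"fraction_congruent": frac, "p_all_congruent": p}
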
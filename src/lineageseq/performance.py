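"""Sensitivity/specificity estimation by the scrambled-label null.

False positives are estimated by relabelling each coincident SNV's
subclone identities with a random scrambling pattern (a permutation
verified to disrupt every clade of the consensus tree), re-running the
scoring, and counting scrambled SNVs that still come out tree-consistent
above the quality threshold.  False negatives are the excess of
sub-threshold branch predictions in the real data over the scrambled
data:  FN = max(0, #branch<t  -  #scrambled_branch<t).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .calling import _best_clade
from .coincidence import ScoringParams, _variant_posteriors
from .core import CoincidentGroup, LineageTree, LocusCountTable

logger = logging.getLogger(__name__)


@dataclass
class ScramblePatternSet:
    """Permutations of subclone labels, each verified to disrupt every
    non-trivial clade of the consensus tree (no true clade maps onto any
    tree-consistent set)."""

    patterns: np.ndarray  # (n_patterns, n_subclones) permutation index rows
    subclones: list
    seed: int

    @classmethod
    def build(
        cls,
        tree: LineageTree,
        n_patterns: int = 10_000,
        seed: int = 0,
        max_tries: int = 200,
    ) -> "ScramblePatternSet":
        subclones = tree.leaves
        n = len(subclones)
        idx = {s: i for i, s in enumerate(subclones)}
        clades = [
            frozenset(idx[s] for s in c)
            for c in tree.clades(min_size=2, max_size=n - 1)
        ]
        tree_sets = set(clades)
        rng = np.random.default_rng(seed)
        patterns = np.empty((n_patterns, n), dtype=np.int64)
        for k in range(n_patterns):
            for attempt in range(max_tries):
                perm = rng.permutation(n)
                if all(
                    frozenset(int(perm[i]) for i in c) not in tree_sets
                    for c in clades
                ):
                    patterns[k] = perm
                    break
            else:
                raise RuntimeError(
                    "could not find a clade-disrupting permutation; "
                    "tree too small to scramble"
                )
            if attempt > 0:
                logger.debug("pattern %d regenerated %d times", k, attempt)
        return cls(patterns, subclones, seed)

    def disrupts_all(self, tree: LineageTree) -> bool:
        idx = {s: i for i, s in enumerate(self.subclones)}
        n = len(self.subclones)
        clades = [
            frozenset(idx[s] for s in c)
            for c in tree.clades(min_size=2, max_size=n - 1)
        ]
        tree_sets = set(clades)
        for perm in self.patterns:
            for c in clades:
                if frozenset(int(perm[i]) for i in c) in tree_sets:
                    return False
        return True


@dataclass
class PerformanceReport:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")


def _branch_scores(
    candidates: Sequence[CoincidentGroup],
    counts: LocusCountTable,
    tree: LineageTree,
    params: ScoringParams,
    permutations: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Best tree-consistent branch score per candidate (singleton options
    excluded; NaN when the read-support filter rejects the best clade).

    With ``permutations``, each candidate's count columns are relabelled by
    a randomly drawn scrambling pattern before scoring.
    """
    n = counts.n_subclones
    sub_index = {s: j for j, s in enumerate(counts.subclones)}
    options = sorted(
        (c for c in tree.clades(min_size=2, max_size=n - 1)),
        key=lambda c: (len(c), sorted(c)),
    )
    scores = np.full(len(candidates), np.nan)
    for i, cand in enumerate(candidates):
        vl = cand.variant_locus
        if vl not in counts:
            continue
        ref_n, alt_n = counts.row(vl)
        if permutations is not None:
            perm = permutations[rng.integers(len(permutations))]
            inv = np.argsort(perm)
            ref_n, alt_n = ref_n[inv], alt_n[inv]
        pv = _variant_posteriors(ref_n, alt_n, params)
        clade, q = _best_clade(pv, options, sub_index)
        idx = [sub_index[s] for s in clade]
        if min(alt_n[j] for j in idx) < params.min_alt_reads:
            continue
        scores[i] = q
    return scores


def scramble_null(
    candidates: Sequence[CoincidentGroup],
    counts: LocusCountTable,
    tree: LineageTree,
    patterns: ScramblePatternSet,
    threshold: float = 0.99,
    params: ScoringParams = ScoringParams(),
    seed: int = 0,
) -> dict:
    """Estimate false-positive branch calls from scrambled labels.

    Returns {"fp": accepted scrambled branch calls, "sub_threshold":
    scrambled branch predictions below threshold, "n": number of scrambled
    candidates}.
    """
    rng = np.random.default_rng(seed)
    scores = _branch_scores(
        candidates, counts, tree, params, permutations=patterns.patterns, rng=rng
    )
    valid = ~np.isnan(scores)
    fp = int((scores[valid] >= threshold).sum())
    sub = int((scores[valid] < threshold).sum())
    return {"fp": fp, "sub_threshold": sub, "n": len(candidates)}


def fn_estimate(
    branch_predicted_but_subthreshold: int, scrambled_subthreshold: int
) -> int:
    """FN = max(0, #sub-threshold branch predictions - scrambled ditto)."""
    fn = branch_predicted_but_subthreshold - scrambled_subthreshold
    if fn < 0:
        logger.warning("negative FN estimate (%d); clamped to 0", fn)
        return 0
    return fn


def roc_curve(
    candidates: Sequence[CoincidentGroup],
    counts: LocusCountTable,
    tree: LineageTree,
    patterns: ScramblePatternSet,
    thresholds: Sequence[float],
    params: ScoringParams = ScoringParams(),
    seed: int = 0,
) -> list[PerformanceReport]:
    """Sensitivity/specificity at each threshold via the scramble
    estimators.  FP counts are asserted monotone non-increasing in the
    threshold."""
    rng = np.random.default_rng(seed)
    real = _branch_scores(candidates, counts, tree, params)
    scram = _branch_scores(
        candidates, counts, tree, params, permutations=patterns.patterns, rng=rng
    )
    real = real[~np.isnan(real)]
    scram = scram[~np.isnan(scram)]
    reports = []
    last_fp = None
    for t in sorted(thresholds):
        tp = int((real >= t).sum())
        real_sub = int((real < t).sum())
        fp = int((scram >= t).sum())
        scram_sub = int((scram < t).sum())
        fn = fn_estimate(real_sub, scram_sub)
        tn = len(scram) - fp
        if last_fp is not None and fp > last_fp:
            raise AssertionError("FP must be non-increasing in threshold")
        last_fp = fp
        reports.append(PerformanceReport(t, tp, fp, tn, fn))
    return reports
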
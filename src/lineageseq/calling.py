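"""Branch/leaf variant calling under a lineage prior.

Method 1 ("tracking -> lineage -> calls"): the lineage tree is supplied
(e.g. from time-lapse imaging); for every candidate locus the min-sample
membership posterior is evaluated for every tree-consistent clade plus
every singleton, and the best-scoring option is assigned:

    quality = max over clades ( min over samples  P1/(P1+P2) ).

Method 2 ("raw variants -> lineage -> calls"): the tree is first inferred
from the data itself — subclones are grouped per locus by clustering on
alt fraction, high-quality subclone sets are tallied, and the frequent
sets (which nest into a laminar family when the data are lineage-shaped)
define the tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .coincidence import ScoringParams, _variant_posteriors, loh_filter
from .core import (
    BranchVariant,
    Clade,
    CoincidentGroup,
    LeafVariant,
    LineageTree,
    LocusCountTable,
    TreeNode,
    VariantLocus,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Method 1
# ---------------------------------------------------------------------------


@dataclass
class CallResult:
    branch: list
    leaf: list
    loh_flagged: list
    discordant: list  # candidates whose best tree-consistent option failed


def _best_clade(
    pv: np.ndarray,
    clades: Sequence[Clade],
    sub_index: dict,
) -> tuple[Clade, float]:
    """argmax over clades of min-sample posterior; ties toward the smaller
    clade (clades must be pre-sorted by (size, labels))."""
    best_clade, best_q = None, -1.0
    log_pv = None
    for clade in clades:
        member = np.zeros(len(sub_index), dtype=bool)
        for s in clade:
            member[sub_index[s]] = True
        q = float(np.minimum(np.where(member, pv, 1 - pv), 1.0).min())
        if q > best_q:
            best_clade, best_q = clade, q
    return best_clade, best_q


def call_method1(
    candidates: Sequence[CoincidentGroup],
    counts: LocusCountTable,
    tree: LineageTree,
    params: ScoringParams = ScoringParams(),
    leaf_snvs: Sequence = (),
    apply_loh: bool = True,
) -> CallResult:
    """Call branch and leaf variants with a supplied lineage tree.

    For each candidate locus every tree-consistent clade (all subtree leaf
    sets of size 2..n-1 plus singletons) is scored; the argmax clade is
    assigned.  Candidates whose best option scores below the quality
    threshold are dropped as lineage-discordant.
    """
    missing = set(counts.subclones) - set(tree.leaves)
    if missing:
        raise ValueError(f"tree lacks subclones {sorted(missing)}")
    sub_index = {s: j for j, s in enumerate(counts.subclones)}
    n = counts.n_subclones
    tree_clades = [
        c for c in tree.clades(min_size=2, max_size=n - 1)
        if c <= set(counts.subclones)
    ]
    singletons = [frozenset([s]) for s in counts.subclones]
    options = sorted(tree_clades + singletons, key=lambda c: (len(c), sorted(c)))

    branch: list[BranchVariant] = []
    leaf: list[LeafVariant] = []
    discordant: list[CoincidentGroup] = []
    for cand in candidates:
        vl = cand.variant_locus
        if vl not in counts:
            logger.warning("locus %s:%d absent from counts; skipped", vl.chrom, vl.pos)
            continue
        ref_n, alt_n = counts.row(vl)
        pv = _variant_posteriors(ref_n, alt_n, params)
        clade, q = _best_clade(pv, options, sub_index)
        if q < params.q_threshold:
            discordant.append(cand)
            continue
        # read-support filter on the assigned clade
        idx = [sub_index[s] for s in clade]
        if min(alt_n[j] for j in idx) < params.min_alt_reads:
            discordant.append(cand)
            continue
        if len(clade) >= 2:
            grp = CoincidentGroup(vl, clade, quality=q)
            assert tree.is_consistent(clade)
            branch.append(BranchVariant(grp, tree.edge_id_of(clade)))
        else:
            (sid,) = clade
            j = sub_index[sid]
            total = ref_n[j] + alt_n[j]
            af = float(alt_n[j] / total) if total else None
            leaf.append(LeafVariant(vl, sid, allele_fraction=af, quality=q))

    # raw single-subclone SNVs go straight to the leaf stream
    for snv in leaf_snvs:
        vl = snv.variant_locus
        if vl not in counts:
            continue
        ref_n, alt_n = counts.row(vl)
        j = sub_index[snv.subclone_id]
        if alt_n[j] < params.min_alt_reads:
            continue
        pv = _variant_posteriors(ref_n, alt_n, params)
        q = float(
            min(pv[j], np.delete(1 - pv, j).min() if counts.n_subclones > 1 else 1.0)
        )
        if q < params.q_threshold:
            continue
        total = ref_n[j] + alt_n[j]
        af = float(alt_n[j] / total) if total else None
        leaf.append(LeafVariant(vl, snv.subclone_id, allele_fraction=af, quality=q))

    loh_flagged: list = []
    if apply_loh:
        branch, flagged_b = loh_filter(branch, counts)
        leaf, flagged_l = loh_filter(leaf, counts)
        loh_flagged = list(flagged_b) + list(flagged_l)
    return CallResult(branch, leaf, loh_flagged, discordant)


# ---------------------------------------------------------------------------
# Method 2: infer subclone sets, build the tree
# ---------------------------------------------------------------------------


@dataclass
class CladeFrequencyTable:
    """High-quality coincident SNV counts per subclone set."""

    counts: dict = field(default_factory=dict)  # Clade -> int

    def add(self, clade: Clade) -> None:
        clade = frozenset(clade)
        self.counts[clade] = self.counts.get(clade, 0) + 1

    def sorted_items(self) -> list:
        return sorted(
            self.counts.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
        )


def infer_sets(
    candidates: Sequence[CoincidentGroup],
    counts: LocusCountTable,
    params: ScoringParams = ScoringParams(),
) -> CladeFrequencyTable:
    """Tally high-quality subclone sets without any lineage prior.

    Per candidate locus, subclones are split into variant/reference groups
    by 2-group hierarchical clustering on alt fraction; sets whose
    min-sample posterior passes the quality threshold are counted.
    """
    table = CladeFrequencyTable()
    n = counts.n_subclones
    for cand in candidates:
        vl = cand.variant_locus
        if vl not in counts:
            continue
        ref_n, alt_n = counts.row(vl)
        total = ref_n + alt_n
        with np.errstate(invalid="ignore"):
            frac = np.where(total > 0, alt_n / np.maximum(total, 1), 0.0)
        if np.allclose(frac, frac[0]):
            continue
        Z = linkage(frac.reshape(-1, 1), method="average")
        labels = fcluster(Z, t=2, criterion="maxclust")
        means = [frac[labels == g].mean() for g in (1, 2)]
        variant_label = 1 + int(np.argmax(means))
        variant_set = frozenset(
            s for s, lab in zip(counts.subclones, labels) if lab == variant_label
        )
        if not (2 <= len(variant_set) < n):
            continue
        idx = [j for j, s in enumerate(counts.subclones) if s in variant_set]
        if min(alt_n[j] for j in idx) < params.min_alt_reads:
            continue
        pv = _variant_posteriors(ref_n, alt_n, params)
        member = np.array([s in variant_set for s in counts.subclones])
        q = float(np.where(member, pv, 1 - pv).min())
        if q >= params.q_threshold:
            table.add(variant_set)
    return table


def _is_laminar(sets: Sequence[Clade]) -> Optional[tuple]:
    for i, a in enumerate(sets):
        for b in sets[i + 1:]:
            if a & b and not (a <= b or b <= a):
                return (a, b)
    return None


def gap_min_count(table: CladeFrequencyTable) -> int:
    """Default retention cutoff: the count just above the largest gap in
    the sorted count sequence."""
    values = sorted((c for _, c in table.sorted_items()), reverse=True)
    if not values:
        raise ValueError("insufficient signal: empty clade frequency table")
    if len(values) == 1:
        return values[0]
    gaps = [values[i] - values[i + 1] for i in range(len(values) - 1)]
    k = int(np.argmax(gaps))
    return values[k]


def build_tree_from_sets(
    table: CladeFrequencyTable,
    subclones: Sequence[str],
    min_count: Optional[int] = None,
) -> LineageTree:
    """Build a lineage tree from frequent subclone sets.

    Retained sets must form a laminar family (pairwise disjoint or
    nested).  Edges carry n=1 generations flagged as lower bounds
    (``generations_exact=False``): shared variants alone carry no
    information about the number of divisions an edge represents.
    """
    if not table.counts:
        raise ValueError("insufficient signal: empty clade frequency table")
    if min_count is None:
        min_count = gap_min_count(table)
    retained = sorted(
        (set(c) for c, n in table.counts.items() if n >= min_count),
        key=lambda s: (-len(s), sorted(s)),
    )
    if not retained:
        raise ValueError("insufficient signal: no subclone set passes min_count")
    conflict = _is_laminar([frozenset(s) for s in retained])
    if conflict:
        raise ValueError(
            f"retained sets are not laminar: {sorted(conflict[0])} conflicts "
            f"with {sorted(conflict[1])}"
        )
    all_set = set(subclones)
    for s in retained:
        if not s <= all_set:
            raise ValueError(f"set {sorted(s)} contains unknown subclones")

    def make_node(members: set, available: list) -> TreeNode:
        node = TreeNode()
        node.n = 1
        children_sets = [
            s for s in available if s < members
            and not any(s < t < members for t in available)
        ]
        covered: set = set()
        for s in children_sets:
            node.children.append(make_node(s, [t for t in available if t < s]))
            covered |= s
        for sid in sorted(members - covered):
            leaf = TreeNode(name=sid)
            leaf.n = 1
            node.children.append(leaf)
        if len(node.children) == 1:
            return node.children[0]
        return node

    proper = [s for s in retained if s != all_set]
    root = make_node(all_set, proper)
    return LineageTree(root, generations_exact=False)


# ---------------------------------------------------------------------------
# Pairwise dendrogram
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    labels: list
    distances: np.ndarray  # square matrix
    linkage: np.ndarray  # scipy linkage matrix

    def topology(self) -> frozenset:
        """Non-trivial clades implied by the merge order."""
        from scipy.cluster.hierarchy import to_tree

        root = to_tree(self.linkage)
        clades = []

        def collect(node) -> frozenset:
            if node.is_leaf():
                return frozenset([self.labels[node.id]])
            c = collect(node.left) | collect(node.right)
            clades.append(c)
            return c

        collect(root)
        n = len(self.labels)
        return frozenset(c for c in clades if 1 < len(c) < n)


def pairwise_dendrogram(
    hq_candidates: Sequence[CoincidentGroup],
    subclones: Sequence[str],
    method: str = "average",
) -> Dendrogram:
    """Agglomerative dendrogram from pairwise sharing of high-quality
    coincident SNVs: distance(i,j) = 1 - shared_ij / total."""
    subclones = list(subclones)
    if len(subclones) < 2:
        raise ValueError("need >= 2 subclones")
    total = len(hq_candidates)
    if total == 0:
        raise ValueError("no high-quality coincident SNVs")
    idx = {s: i for i, s in enumerate(subclones)}
    shared = np.zeros((len(subclones), len(subclones)))
    for cand in hq_candidates:
        members = [idx[s] for s in cand.variant_set if s in idx]
        for a in members:
            for b in members:
                if a != b:
                    shared[a, b] += 1
    dist = 1.0 - shared / total
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method=method)
    return Dendrogram(subclones, dist, Z)


# ---------------------------------------------------------------------------
# First-division allele orientation
# ---------------------------------------------------------------------------


@dataclass
class OrientationReport:
    oriented: list  # (BranchVariant, mutated_side_clade)
    unoriented: list
    fraction_hom_to_het: Optional[float]


def orient_root_split(
    first_division_variants: Sequence[BranchVariant],
    tree: LineageTree,
    outgroup_counts: Optional[dict] = None,
    reference_alleles: Optional[dict] = None,
) -> OrientationReport:
    """Orient branch variants whose clade is one of the two root subtrees.

    The allele matching the outgroup (or the reference genome) is labelled
    ancestral; the subtree carrying the non-ancestral allele is the mutated
    side.  Reports the fraction of variants consistent with a homozygous ->
    heterozygous change (ancestral allele = the variant's reference base)
    and warns when that fraction is <= 0.5.
    """
    if outgroup_counts is None and reference_alleles is None:
        return OrientationReport(
            [], list(first_division_variants), None
        )
    root_clades = {tree.clade(c) for c in tree.root.children}
    oriented, unoriented = [], []
    n_hom_to_het = 0
    for bv in first_division_variants:
        if bv.clade not in root_clades:
            raise ValueError(
                f"variant clade {sorted(bv.clade)} is not a root subtree"
            )
        vl = bv.variant_locus
        ancestral = None
        if reference_alleles is not None and (vl.chrom, vl.pos) in reference_alleles:
            ancestral = reference_alleles[(vl.chrom, vl.pos)]
        elif outgroup_counts is not None and (vl.chrom, vl.pos) in outgroup_counts:
            cell = outgroup_counts[(vl.chrom, vl.pos)]
            if cell.total == 0:
                ancestral = None
            else:
                ancestral = vl.alt if cell.alt_fraction > 0.5 else vl.ref
        if ancestral is None:
            unoriented.append(bv)
            continue
        if ancestral == vl.ref:
            mutated_side = bv.clade
            n_hom_to_het += 1
        else:
            (other,) = root_clades - {bv.clade}
            mutated_side = other
        oriented.append((bv, mutated_side))
    frac = n_hom_to_het / len(oriented) if oriented else None
    if frac is not None and frac <= 0.5:
        logger.warning(
            "only %.0f%% of first-division variants are hom->het; "
            "reference assignment may be inverted", 100 * frac,
        )
    return OrientationReport(oriented, unoriented, frac)
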
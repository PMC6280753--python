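"""Forward simulator of lineage growth, mutation accrual and read counts.

The stated world: a founding cell grows through a complete binary division
tree; a subset of terminal cells is sampled and expanded into subclones
that are whole-genome sequenced at ~35x.  Mutations attach at division
(edge) granularity — per-edge counts are Poisson(lambda * n_i) with n_i the
number of divisions the edge represents (or gamma-mixed for an
overdispersed alternative).  A clonal variant's allele fraction is set by
local copy number (m variant copies of CN total); reads are binomial
samples at Poisson depth with a flat per-read miscall rate for
non-carriers.  Persistent-lesion events (two different alts at one locus
in related sublineages) and multinucleotide clusters can be planted with
known ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    IntervalTrack,
    LineageTree,
    LocusCountTable,
    RawSnv,
    TreeNode,
    VariantLocus,
)

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated lineage experiment.

    Defaults mirror the measured regime of a POLE-proofreading-deficient
    lineage: ~173 SNVs per division, 35x mean depth, 0.5% per-read error.
    """

    n_generations: int = 4
    n_subclones_sampled: int = 11
    chrom_lengths: tuple = (("chr1", 50_000_000),)
    rate_per_division: float = 173.0
    overdispersion: str = "poisson"  # or "gamma"
    gamma_shape: float = 2.0
    mean_depth: float = 35.0
    error_rate: float = 0.005
    ploidy_profile: Optional[tuple] = None  # ((chrom, start0, end0, copy), ...)
    variant_copies: int = 1
    lesion_rate: float = 0.0
    mnv_rate: float = 0.0
    mnv_window: int = 100
    subclonal_leaf_rate: float = 0.0
    caller_fp_rate: float = 0.0
    coverage_bin_size: int = 10_000
    coverage_noise_scale: float = 0.08
    emit_reads: bool = True  # False: truth only (fast Monte-Carlo over counts)
    seed: int = 0

    def __post_init__(self):
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not (1 <= self.n_subclones_sampled <= 2**self.n_generations):
            raise ValueError("cannot sample more subclones than terminal cells")
        for r in (
            self.rate_per_division,
            self.lesion_rate,
            self.mnv_rate,
            self.subclonal_leaf_rate,
            self.caller_fp_rate,
            self.error_rate,
        ):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.overdispersion not in ("poisson", "gamma"):
            raise ValueError("overdispersion must be 'poisson' or 'gamma'")
        if self.ploidy_profile is not None:
            for _, _, _, cn in self.ploidy_profile:
                if not (0 <= cn <= 5):
                    raise ValueError("copy numbers must be in 0..5")

    @property
    def genome_length(self) -> int:
        return sum(l for _, l in self.chrom_lengths)


@dataclass(frozen=True)
class PlantedMutation:
    variant_locus: VariantLocus
    clade: frozenset
    edge_id: str
    expected_fraction: float
    kind: str  # branch | leaf | founder | subclonal | lesion


@dataclass(frozen=True)
class PlantedLesion:
    """One damaged base: two different alts at one position on two disjoint
    segments whose MRCA is not the root."""

    locus_a: VariantLocus
    locus_b: VariantLocus
    clade_a: frozenset
    clade_b: frozenset
    edge_a: str
    edge_b: str


@dataclass
class SimTruth:
    tree: LineageTree
    mutations: list  # of PlantedMutation
    lesions: list  # of PlantedLesion
    mnv_clusters: list  # of tuples of PlantedMutation
    copy_track: IntervalTrack
    founder_generations: int

    def by_edge(self) -> dict:
        out: dict[str, list[PlantedMutation]] = {}
        for m in self.mutations:
            out.setdefault(m.edge_id, []).append(m)
        return out

    def branch_truth(self) -> dict:
        """(VariantLocus -> clade) for plantings visible as branch variants."""
        return {
            m.variant_locus: m.clade
            for m in self.mutations
            if m.kind in ("branch", "lesion") and len(m.clade) >= 2
        }


@dataclass
class SimResult:
    truth: SimTruth
    raw_snvs: list
    counts: LocusCountTable
    coverage: pd.DataFrame  # chrom, start, coverage (median-normalized)


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------


def _sampled_tree(
    n_generations: int, n_sampled: int, rng: np.random.Generator
) -> tuple[LineageTree, int]:
    """Complete binary tree of ``n_generations``, restricted to a random
    sample of terminal cells with unary paths collapsed into multi-division
    edges.  Returns (tree, generations above the sampled MRCA)."""
    n_leaves = 2**n_generations
    sampled = sorted(rng.choice(n_leaves, size=n_sampled, replace=False))
    sampled_set = set(int(s) for s in sampled)
    width = len(str(n_leaves - 1))

    def build(depth: int, lo: int, hi: int) -> Optional[TreeNode]:
        # subtree over terminal-cell interval [lo, hi)
        if not any(lo <= s < hi for s in sampled_set):
            return None
        if depth == n_generations:
            node = TreeNode(name=f"s{lo:0{width}d}")
            node.n = 1
            return node
        mid = (lo + hi) // 2
        left = build(depth + 1, lo, mid)
        right = build(depth + 1, mid, hi)
        if left is not None and right is not None:
            node = TreeNode()
            node.n = 1
            node.children = [left, right]
            return node
        child = left if left is not None else right
        child.n += 1  # collapse the unary division into the surviving edge
        return child

    root = build(0, 0, n_leaves)
    # the collapsed path above the first branching node = founder divisions
    founder_gens = root.n - 1
    root.n = 1
    return LineageTree(root), founder_gens


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_lineage(config: SimConfig) -> SimResult:
    """Run the forward simulation; identical config+seed gives identical
    output."""
    rng = np.random.default_rng(config.seed)
    tree, founder_gens = _sampled_tree(
        config.n_generations, config.n_subclones_sampled, rng
    )
    subclones = tree.leaves
    copy_track = _copy_track(config)
    chroms = [c for c, _ in config.chrom_lengths]
    lengths = np.array([l for _, l in config.chrom_lengths], dtype=float)
    chrom_p = lengths / lengths.sum()

    used_positions: set[tuple[str, int]] = set()

    def draw_locus() -> tuple[str, int]:
        for _ in range(10_000):
            ci = rng.choice(len(chroms), p=chrom_p)
            pos = int(rng.integers(1, int(lengths[ci]) + 1))
            key = (chroms[ci], pos)
            if key in used_positions:
                continue
            if _copy_at(copy_track, *key) == 0:
                continue
            used_positions.add(key)
            return key
        raise ValueError("genome too small to place requested mutations")

    def draw_alleles(n_alts: int = 1) -> tuple[str, list[str]]:
        ref = str(rng.choice(_BASES))
        alts = [str(b) for b in rng.permutation([b for b in _BASES if b != ref])]
        return ref, alts[:n_alts]

    mutations: list[PlantedMutation] = []
    mnv_clusters: list[tuple] = []

    # --- per-edge mutation counts -------------------------------------
    for node in tree.edges():
        clade = tree.clade(node)
        n_i = node.n
        lam = config.rate_per_division * n_i
        if config.overdispersion == "gamma" and lam > 0:
            lam = rng.gamma(config.gamma_shape, lam / config.gamma_shape)
        count = rng.poisson(lam) if lam > 0 else 0
        kind = "leaf" if len(clade) == 1 else "branch"
        for _ in range(count):
            chrom, pos = draw_locus()
            ref, (alt,) = draw_alleles()
            cn = _copy_at(copy_track, chrom, pos)
            f = min(1.0, config.variant_copies / cn)
            mut = PlantedMutation(
                VariantLocus(chrom, pos, ref, alt), clade, node.edge_id, f, kind
            )
            mutations.append(mut)
            if config.mnv_rate > 0 and rng.random() < config.mnv_rate:
                offset = int(rng.integers(1, config.mnv_window + 1))
                pos2 = pos + offset
                key2 = (chrom, pos2)
                if key2 not in used_positions and pos2 <= _chrom_len(config, chrom):
                    used_positions.add(key2)
                    ref2, (alt2,) = draw_alleles()
                    mut2 = PlantedMutation(
                        VariantLocus(chrom, pos2, ref2, alt2),
                        clade,
                        node.edge_id,
                        f,
                        kind,
                    )
                    mutations.append(mut2)
                    mnv_clusters.append((mut, mut2))

    # --- founder mutations above the sampled MRCA ---------------------
    if founder_gens > 0 and config.rate_per_division > 0:
        all_clade = frozenset(subclones)
        for _ in range(rng.poisson(config.rate_per_division * founder_gens)):
            chrom, pos = draw_locus()
            ref, (alt,) = draw_alleles()
            cn = _copy_at(copy_track, chrom, pos)
            f = min(1.0, config.variant_copies / cn)
            mutations.append(
                PlantedMutation(
                    VariantLocus(chrom, pos, ref, alt),
                    all_clade,
                    tree.root.edge_id,
                    f,
                    "founder",
                )
            )

    # --- subclonal culture mutations (reduced allele fraction) --------
    if config.subclonal_leaf_rate > 0:
        for sid in subclones:
            for _ in range(rng.poisson(config.subclonal_leaf_rate)):
                chrom, pos = draw_locus()
                ref, (alt,) = draw_alleles()
                f = float(rng.uniform(0.05, 0.4))
                mutations.append(
                    PlantedMutation(
                        VariantLocus(chrom, pos, ref, alt),
                        frozenset([sid]),
                        sid,
                        f,
                        "subclonal",
                    )
                )

    # --- persistent lesions -------------------------------------------
    lesions: list[PlantedLesion] = []
    internal = [
        n
        for n in tree.edges(include_root=True)
        if not n.is_leaf and n is not tree.root and len(n.children) == 2
    ]
    n_lesions = rng.poisson(config.lesion_rate) if config.lesion_rate > 0 else 0
    for _ in range(n_lesions):
        if not internal:
            logger.warning("no non-root internal node; lesion not planted")
            break
        v = internal[int(rng.integers(len(internal)))]
        side_nodes = []
        for child in v.children:
            sub = [child]
            stack = [child]
            while stack:
                nd = stack.pop()
                stack.extend(nd.children)
                if nd is not child:
                    sub.append(nd)
            side_nodes.append(sub)
        a = side_nodes[0][int(rng.integers(len(side_nodes[0])))]
        b = side_nodes[1][int(rng.integers(len(side_nodes[1])))]
        chrom, pos = draw_locus()
        ref, (alt1, alt2) = draw_alleles(2)
        cn = _copy_at(copy_track, chrom, pos)
        f = min(1.0, config.variant_copies / cn)
        vl1 = VariantLocus(chrom, pos, ref, alt1)
        vl2 = VariantLocus(chrom, pos, ref, alt2)
        clade_a, clade_b = tree.clade(a), tree.clade(b)
        mutations.append(PlantedMutation(vl1, clade_a, a.edge_id, f, "lesion"))
        mutations.append(PlantedMutation(vl2, clade_b, b.edge_id, f, "lesion"))
        lesions.append(
            PlantedLesion(vl1, vl2, clade_a, clade_b, a.edge_id, b.edge_id)
        )

    # --- caller-noise false positives ---------------------------------
    n_fp = rng.poisson(config.caller_fp_rate) if config.caller_fp_rate > 0 else 0
    fp_plants: list[PlantedMutation] = []
    for _ in range(n_fp):
        chrom, pos = draw_locus()
        ref, (alt,) = draw_alleles()
        sid = subclones[int(rng.integers(len(subclones)))]
        fp_plants.append(
            PlantedMutation(
                VariantLocus(chrom, pos, ref, alt),
                frozenset([sid]),
                sid,
                float(rng.uniform(0.03, 0.15)),
                "noise",
            )
        )

    truth = SimTruth(tree, mutations, lesions, mnv_clusters, copy_track, founder_gens)
    if config.emit_reads:
        counts, raw = _emit_reads(config, truth, fp_plants, subclones, rng)
        coverage = _emit_coverage(config, copy_track, rng)
    else:
        counts = LocusCountTable(
            [], subclones,
            np.zeros((0, len(subclones)), dtype=np.int64),
            np.zeros((0, len(subclones)), dtype=np.int64),
        )
        raw = []
        coverage = pd.DataFrame(columns=["chrom", "start", "coverage"])
    return SimResult(truth, raw, counts, coverage)


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------


def _emit_reads(config, truth, fp_plants, subclones, rng):
    # group plantings by (chrom, pos) so same-site alts share coverage
    by_pos: dict[tuple, list[PlantedMutation]] = {}
    for m in list(truth.mutations) + list(fp_plants):
        by_pos.setdefault((m.variant_locus.chrom, m.variant_locus.pos), []).append(m)

    loci: list[VariantLocus] = []
    ref_rows: list[np.ndarray] = []
    alt_rows: list[np.ndarray] = []
    n_sub = len(subclones)
    sub_index = {s: j for j, s in enumerate(subclones)}

    for key in sorted(by_pos):
        plants = by_pos[key]
        chrom, pos = key
        cn = _copy_at(truth.copy_track, chrom, pos)
        depth = rng.poisson(config.mean_depth * cn / 2.0, size=n_sub)
        n_alleles = len(plants)
        probs = np.full((n_sub, n_alleles), config.error_rate)
        for a, m in enumerate(plants):
            for sid in m.clade:
                probs[sub_index[sid], a] = m.expected_fraction
        # multinomial per subclone over (alt_1..alt_k, ref)
        alt_mat = np.zeros((n_sub, n_alleles), dtype=np.int64)
        for j in range(n_sub):
            p = probs[j]
            total_p = p.sum()
            if total_p >= 1.0:
                p = p / total_p
                total_p = 1.0
            draw = rng.multinomial(depth[j], np.append(p, 1.0 - total_p))
            alt_mat[j] = draw[:-1]
        ref_counts = depth - alt_mat.sum(axis=1)
        for a, m in enumerate(plants):
            loci.append(m.variant_locus)
            ref_rows.append(ref_counts.copy())
            alt_rows.append(alt_mat[:, a].copy())

    if loci:
        table = LocusCountTable(
            loci, subclones, np.vstack(ref_rows), np.vstack(alt_rows)
        )
    else:
        table = LocusCountTable(
            [], subclones,
            np.zeros((0, n_sub), dtype=np.int64),
            np.zeros((0, n_sub), dtype=np.int64),
        )

    raw: list[RawSnv] = []
    for i, vl in enumerate(table.loci):
        for j, sid in enumerate(table.subclones):
            if table.alt_counts[i, j] >= 1:
                raw.append(RawSnv(vl.chrom, vl.pos, vl.ref, vl.alt, sid))
    raw.sort()
    return table, raw


def _emit_coverage(config, copy_track, rng) -> pd.DataFrame:
    rows = []
    for chrom, length in config.chrom_lengths:
        starts = np.arange(0, length, config.coverage_bin_size)
        for s in starts:
            mid = int(s + config.coverage_bin_size // 2) + 1
            state = _copy_at(copy_track, chrom, mid, allow_zero=True)
            noise = float(
                np.clip(rng.standard_cauchy() * config.coverage_noise_scale, -2, 8)
            )
            rows.append((chrom, int(s), state + noise))
    df = pd.DataFrame(rows, columns=["chrom", "start", "coverage"])
    med = df["coverage"].median()
    if med > 0:
        df["coverage"] = df["coverage"] / med
    return df


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _copy_track(config: SimConfig) -> IntervalTrack:
    if config.ploidy_profile:
        return IntervalTrack(list(config.ploidy_profile))
    return IntervalTrack(
        [(chrom, 0, length, 2) for chrom, length in config.chrom_lengths]
    )


def _copy_at(track: IntervalTrack, chrom: str, pos: int, allow_zero: bool = True) -> int:
    state = track.lookup(chrom, pos)
    if state is None:
        return 2
    return int(state)


def _chrom_len(config: SimConfig, chrom: str) -> int:
    for c, l in config.chrom_lengths:
        if c == chrom:
            return l
    raise KeyError(chrom)
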
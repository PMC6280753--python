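"""Domain types shared across the lineage-sequencing pipeline.

Coordinate conventions
----------------------
All in-memory loci are 1-based (the VCF dialect).  BED-style tracks are
stored as 0-based half-open intervals inside :class:`IntervalTrack` and
converted on lookup, so that converting back to BED is the identity.

Subclone ids are plain strings; wherever a set of subclones is serialized
it is emitted in lexicographic order for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import numpy as np

NUCLEOTIDES = frozenset("ACGT")

# A clade is just a frozen set of subclone ids.
Clade = frozenset


class GenomicLocus(NamedTuple):
    """A 1-based genomic position."""

    chrom: str
    pos: int

    def validate(self) -> "GenomicLocus":
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        return self


class VariantLocus(NamedTuple):
    """A locus together with its reference and alternate base."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def locus(self) -> GenomicLocus:
        return GenomicLocus(self.chrom, self.pos)

    def validate(self) -> "VariantLocus":
        GenomicLocus(self.chrom, self.pos).validate()
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(f"ref/alt must be single bases in ACGT: {self}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ: {self}")
        return self


class RawSnv(NamedTuple):
    """A single-subclone candidate SNV as produced by a pairwise caller."""

    chrom: str
    pos: int
    ref: str
    alt: str
    subclone_id: str

    @property
    def variant_locus(self) -> VariantLocus:
        return VariantLocus(self.chrom, self.pos, self.ref, self.alt)

    def validate(self) -> "RawSnv":
        self.variant_locus.validate()
        if not self.subclone_id:
            raise ValueError("subclone_id must be non-empty")
        return self


class AlleleCounts(NamedTuple):
    """Reference / alternate read counts at one locus in one subclone."""

    ref_n: int
    alt_n: int

    @property
    def total(self) -> int:
        return self.ref_n + self.alt_n

    @property
    def alt_fraction(self) -> float:
        if self.total == 0:
            raise ValueError("allele fraction undefined with zero coverage")
        return self.alt_n / self.total


class LocusCountTable:
    """Per-locus, per-subclone ref/alt read counts.

    A dense (n_loci x n_subclones) matrix pair; every cell is present
    (zero counts allowed).  Rows are keyed by :class:`VariantLocus`, so a
    genomic position carrying two different alternate alleles occupies two
    rows that share the same ``ref_n`` column (reads supporting the
    reference base).
    """

    def __init__(
        self,
        loci: Sequence[VariantLocus],
        subclones: Sequence[str],
        ref_counts: np.ndarray,
        alt_counts: np.ndarray,
    ):
        self.loci = [VariantLocus(*l).validate() for l in loci]
        self.subclones = list(subclones)
        if len(set(self.subclones)) != len(self.subclones):
            raise ValueError("subclone ids must be unique")
        self.ref_counts = np.asarray(ref_counts, dtype=np.int64)
        self.alt_counts = np.asarray(alt_counts, dtype=np.int64)
        shape = (len(self.loci), len(self.subclones))
        if self.ref_counts.shape != shape or self.alt_counts.shape != shape:
            raise ValueError(
                f"count matrices must have shape {shape}, got "
                f"{self.ref_counts.shape}/{self.alt_counts.shape}"
            )
        if (self.ref_counts < 0).any() or (self.alt_counts < 0).any():
            raise ValueError("negative read counts")
        self._row: dict[VariantLocus, int] = {}
        for i, l in enumerate(self.loci):
            if l in self._row:
                raise ValueError(f"duplicate locus row: {l}")
            self._row[l] = i
        self._col = {s: j for j, s in enumerate(self.subclones)}

    # -- access ---------------------------------------------------------
    def __contains__(self, locus: VariantLocus) -> bool:
        return VariantLocus(*locus) in self._row

    def row_index(self, locus: VariantLocus) -> int:
        return self._row[VariantLocus(*locus)]

    def counts(self, locus: VariantLocus, subclone: str) -> AlleleCounts:
        i = self.row_index(locus)
        j = self._col[subclone]
        return AlleleCounts(int(self.ref_counts[i, j]), int(self.alt_counts[i, j]))

    def row(self, locus: VariantLocus) -> tuple[np.ndarray, np.ndarray]:
        """(ref_n, alt_n) arrays over subclones for one locus row."""
        i = self.row_index(locus)
        return self.ref_counts[i], self.alt_counts[i]

    def rows_at_position(self, chrom: str, pos: int) -> list[VariantLocus]:
        return [l for l in self.loci if l.chrom == chrom and l.pos == pos]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_subclones(self) -> int:
        return len(self.subclones)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LocusCountTable):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.subclones == other.subclones
            and np.array_equal(self.ref_counts, other.ref_counts)
            and np.array_equal(self.alt_counts, other.alt_counts)
        )


# ---------------------------------------------------------------------------
# Lineage tree
# ---------------------------------------------------------------------------


class TreeNode:
    """A node of the lineage tree; the edge *above* the node carries the
    generation count ``n`` (number of cell divisions it represents)."""

    __slots__ = ("name", "children", "n", "edge_id", "parent")

    def __init__(self, name: Optional[str] = None, n: int = 1):
        self.name = name
        self.children: list[TreeNode] = []
        self.n = n  # generations on the edge above this node (ignored at root)
        self.edge_id: Optional[str] = None
        self.parent: Optional[TreeNode] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class LineageTree:
    """Rooted tree over subclones with per-edge generation counts.

    The canonical tree is binary (every internal node has exactly two
    children); trees inferred from shared variants alone (Method 2) may be
    multifurcating and carry ``generations_exact=False`` because their edge
    generation counts are lower bounds.
    """

    def __init__(self, root: TreeNode, generations_exact: bool = True):
        self.root = root
        self.generations_exact = generations_exact
        self._index()

    def _index(self) -> None:
        leaves: list[str] = []
        clade_of: dict[TreeNode, Clade] = {}
        for node in self.postorder():
            if node.is_leaf:
                if not node.name:
                    raise ValueError("leaf without a name")
                leaves.append(node.name)
                clade_of[node] = frozenset([node.name])
            else:
                members: set[str] = set()
                for child in node.children:
                    members |= clade_of[child]
                clade_of[node] = frozenset(members)
        if len(set(leaves)) != len(leaves):
            raise ValueError("duplicate leaf names")
        self._leaves = sorted(leaves)
        self._clade_of = clade_of
        self._node_of_clade = {clade_of[n]: n for n in clade_of}
        # deterministic edge ids from the sorted clade each edge subtends
        for node in self.postorder():
            node.edge_id = ",".join(sorted(clade_of[node]))
            for child in node.children:
                child.parent = node
        self.root.parent = None

    # -- traversal ------------------------------------------------------
    def postorder(self) -> Iterator[TreeNode]:
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    @property
    def leaves(self) -> list[str]:
        return list(self._leaves)

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    def is_binary(self) -> bool:
        return all(
            len(n.children) == 2 for n in self.postorder() if not n.is_leaf
        )

    def validate(self) -> "LineageTree":
        if not self.is_binary():
            raise ValueError("tree is not binary")
        for node in self.postorder():
            if node is not self.root and (
                not isinstance(node.n, int) or node.n < 1
            ):
                raise ValueError(f"edge above {node.edge_id} has n={node.n}")
        return self

    # -- clades ---------------------------------------------------------
    def clade(self, node: TreeNode) -> Clade:
        return self._clade_of[node]

    def clades(self, min_size: int = 1, max_size: Optional[int] = None) -> list[Clade]:
        """All subtree leaf sets (including singletons and the full set)."""
        if max_size is None:
            max_size = self.n_leaves
        out = [
            c
            for c in self._node_of_clade
            if min_size <= len(c) <= max_size
        ]
        return sorted(out, key=lambda c: (len(c), sorted(c)))

    def is_consistent(self, subclone_set: Iterable[str]) -> bool:
        """True iff the set equals the leaf set under some node."""
        s = frozenset(subclone_set)
        return s in self._node_of_clade

    def node_of(self, clade: Iterable[str]) -> TreeNode:
        return self._node_of_clade[frozenset(clade)]

    def edge_id_of(self, clade: Iterable[str]) -> str:
        return self.node_of(clade).edge_id

    def generations(self, clade: Iterable[str]) -> int:
        return self.node_of(clade).n

    def mrca(self, clade_a: Iterable[str], clade_b: Iterable[str]) -> TreeNode:
        union = frozenset(clade_a) | frozenset(clade_b)
        best = self.root
        for node, c in self._clade_of.items():
            if union <= c and len(c) < len(self._clade_of[best]):
                best = node
        return best

    def edges(self, include_root: bool = False) -> list[TreeNode]:
        """Nodes whose parent edge is a lineage segment, sorted by edge id."""
        nodes = [
            n
            for n in self.postorder()
            if include_root or n is not self.root
        ]
        return sorted(nodes, key=lambda n: n.edge_id)

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                label = node.name
            else:
                label = "(" + ",".join(fmt(c) for c in _sorted_children(node)) + ")"
            if node is self.root:
                return label
            return f"{label}:{node.n}"

        def _sorted_children(node: TreeNode) -> list[TreeNode]:
            return sorted(node.children, key=lambda c: min(self._clade_of[c]))

        return fmt(self.root) + ";"

    def topology(self) -> frozenset:
        """The set of non-trivial clades; equal topologies compare equal."""
        return frozenset(
            c for c in self._node_of_clade if 1 < len(c) < self.n_leaves
        )


def brute_force_clades(tree: LineageTree) -> set[Clade]:
    """Independent enumeration of all subtree leaf sets (test oracle)."""

    def collect(node: TreeNode) -> set[str]:
        if node.is_leaf:
            return {node.name}
        out: set[str] = set()
        for c in node.children:
            out |= collect(c)
        return out

    result: set[Clade] = set()
    stack = [tree.root]
    while stack:
        node = stack.pop()
        result.add(frozenset(collect(node)))
        stack.extend(node.children)
    return result


# ---------------------------------------------------------------------------
# Scored variant objects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-sample binomial likelihoods and the membership posterior."""

    p1: float
    p2: float
    posterior: float
    p3: Optional[float] = None


@dataclass
class CoincidentGroup:
    """An identical substitution observed in >=2 but not all subclones."""

    variant_locus: VariantLocus
    variant_set: Clade
    quality: Optional[float] = None
    breakdowns: dict = field(default_factory=dict)
    rejected: Optional[str] = None  # reason, if filtered

    def __post_init__(self):
        self.variant_locus = VariantLocus(*self.variant_locus).validate()
        self.variant_set = frozenset(self.variant_set)
        if len(self.variant_set) < 2:
            raise ValueError("coincident group needs >= 2 subclones")

    @property
    def chrom(self) -> str:
        return self.variant_locus.chrom

    @property
    def pos(self) -> int:
        return self.variant_locus.pos


@dataclass
class BranchVariant:
    """A coincident SNV consistent with the lineage tree, assigned to the
    edge (segment) above its clade's node."""

    group: CoincidentGroup
    edge_id: str

    @property
    def variant_locus(self) -> VariantLocus:
        return self.group.variant_locus

    @property
    def clade(self) -> Clade:
        return self.group.variant_set

    @property
    def quality(self) -> Optional[float]:
        return self.group.quality


@dataclass
class LeafVariant:
    """An SNV supported by a single subclone."""

    variant_locus: VariantLocus
    subclone_id: str
    allele_fraction: Optional[float] = None
    quality: Optional[float] = None

    def __post_init__(self):
        self.variant_locus = VariantLocus(*self.variant_locus).validate()


# ---------------------------------------------------------------------------
# Interval tracks (BED-style annotations)
# ---------------------------------------------------------------------------


class IntervalTrack:
    """Half-open 0-based intervals per chromosome with an arbitrary payload
    (region class, timing value, copy state, ...).

    Lookups accept the pipeline's internal 1-based positions.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int, object]]):
        by_chrom: dict[str, list[tuple[int, int, object]]] = {}
        for chrom, start, end, payload in intervals:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end, payload))
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping intervals on {chrom}: "
                        f"[{s1},{e1}) and [{s2},...)"
                    )
            starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
            payloads = [p for _, _, p in ivs]
            self._by_chrom[chrom] = (starts, ends, payloads)

    def __iter__(self) -> Iterator[tuple[str, int, int, object]]:
        for chrom in sorted(self._by_chrom):
            starts, ends, payloads = self._by_chrom[chrom]
            for s, e, p in zip(starts, ends, payloads):
                yield chrom, int(s), int(e), p

    def lookup(self, chrom: str, pos: int) -> Optional[object]:
        """Payload at 1-based position ``pos``, or None."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, payloads = entry
        p0 = pos - 1
        i = int(np.searchsorted(starts, p0, side="right")) - 1
        if i >= 0 and p0 < ends[i]:
            return payloads[i]
        return None

    def total_bp(self, payload=None) -> int:
        total = 0
        for _, s, e, p in self:
            if payload is None or p == payload:
                total += e - s
        return total

    def payload_classes(self) -> list:
        seen = []
        for _, _, _, p in self:
            if p not in seen:
                seen.append(p)
        return seen

    def weighted_bp(
        self, weights: Optional["IntervalTrack"] = None, payload=None
    ) -> float:
        """Total bp, optionally weighted by a numeric payload track
        (e.g. integer copy states) via exact interval intersection."""
        if weights is None:
            return float(self.total_bp(payload))
        total = 0.0
        for chrom, s, e, p in self:
            if payload is not None and p != payload:
                continue
            entry = weights._by_chrom.get(chrom)
            if entry is None:
                continue
            ws, we, wp = entry
            i = max(0, int(np.searchsorted(ws, s, side="right")) - 1)
            for k in range(i, len(ws)):
                if ws[k] >= e:
                    break
                lo = max(s, int(ws[k]))
                hi = min(e, int(we[k]))
                if hi > lo:
                    total += (hi - lo) * float(wp[k])
        return total
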
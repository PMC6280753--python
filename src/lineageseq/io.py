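"""Readers and writers for the external formats the pipeline touches.

VCF (4.2) for variant calls, TSV for count tables, Newick for lineage
trees, BED for annotation tracks, plain TSV for signature matrices and
binned coverage.  Every writer/reader pair is an identity on its domain
type; all positions are 1-based in memory (BED is converted on ingestion).
"""

from __future__ import annotations

import logging
import os
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
import pysam

from .core import (
    AlleleCounts,
    BranchVariant,
    IntervalTrack,
    LeafVariant,
    LineageTree,
    LocusCountTable,
    RawSnv,
    TreeNode,
    VariantLocus,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Raw SNV lists
# ---------------------------------------------------------------------------


def read_raw_snvs(path: str, format: Optional[str] = None) -> list[RawSnv]:
    """Read de-duplicated per-subclone SNV calls from TSV or VCF.

    TSV columns: chrom, pos, ref, alt, subclone (header required).
    VCF: one sample per file (subclone = sample name) or an INFO key
    ``SUBCLONE``; multi-allelic records are split, non-SNV alleles skipped
    with a warning.  The output is unique on (locus, alt, subclone).
    """
    if format is None:
        format = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "vcf":
        records = _read_raw_snvs_vcf(path)
    elif format == "tsv":
        records = _read_raw_snvs_tsv(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    seen: dict[tuple, RawSnv] = {}
    for snv in records:
        key = (snv.chrom, snv.pos, snv.alt, snv.subclone_id)
        if key not in seen:
            seen[key] = snv
    out = sorted(seen.values())
    if not out:
        logger.warning("no SNV records read from %s", path)
    return out


def _read_raw_snvs_tsv(path: str) -> list[RawSnv]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header:
            return out
        cols = header.rstrip("\n").split("\t")
        required = ["chrom", "pos", "ref", "alt", "subclone"]
        if cols[:5] != required:
            raise ValueError(
                f"{path}: expected header columns {required}, got {cols[:5]}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                snv = RawSnv(
                    fields[0], int(fields[1]), fields[2], fields[3], fields[4]
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed record ({exc})")
            if len(snv.ref) != 1 or len(snv.alt) != 1:
                logger.warning("%s:%d: non-SNV record skipped", path, lineno)
                continue
            snv.validate()
            out.append(snv)
    return out


def _read_raw_snvs_vcf(path: str) -> list[RawSnv]:
    out = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if "SUBCLONE" in rec.info:
                subclone = str(rec.info["SUBCLONE"])
            elif len(samples) == 1:
                subclone = samples[0]
            else:
                raise ValueError(
                    f"{path}: cannot determine subclone id "
                    "(need INFO/SUBCLONE or a single-sample VCF)"
                )
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or alt not in "ACGT":
                    logger.warning(
                        "%s: non-SNV allele %s>%s at %s:%d skipped",
                        path, rec.ref, alt, rec.contig, rec.pos,
                    )
                    continue
                out.append(
                    RawSnv(rec.contig, rec.pos, rec.ref, alt, subclone).validate()
                )
    return out


def write_raw_snvs(snvs: Sequence[RawSnv], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tsubclone\n")
        for s in sorted(snvs):
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.subclone_id}\n")


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------


def write_count_table(table: LocusCountTable, path: str) -> None:
    cols = ["chrom", "pos", "ref", "alt"]
    for s in table.subclones:
        cols += [f"{s}_ref", f"{s}_alt"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        order = sorted(range(table.n_loci), key=lambda i: table.loci[i])
        for i in order:
            l = table.loci[i]
            row = [l.chrom, str(l.pos), l.ref, l.alt]
            for j in range(table.n_subclones):
                row += [str(table.ref_counts[i, j]), str(table.alt_counts[i, j])]
            fh.write("\t".join(row) + "\n")


def read_count_table(path: str) -> LocusCountTable:
    """Read a TSV count table (columns ``<id>_ref``/``<id>_alt`` per
    subclone).  Missing cells are filled with zero counts and logged;
    negative counts and duplicate locus rows are errors."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    subclones = []
    for col in df.columns:
        if col.endswith("_ref"):
            sid = col[:-4]
            if f"{sid}_alt" not in df.columns:
                raise ValueError(f"{path}: column {sid}_alt missing")
            subclones.append(sid)
    if not subclones:
        raise ValueError(f"{path}: no subclone count columns")
    loci = [
        VariantLocus(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in df.itertuples()
    ]
    n = len(loci)
    ref_counts = np.zeros((n, len(subclones)), dtype=np.int64)
    alt_counts = np.zeros((n, len(subclones)), dtype=np.int64)
    for j, sid in enumerate(subclones):
        for kind, mat in (("ref", ref_counts), ("alt", alt_counts)):
            col = df[f"{sid}_{kind}"]
            missing = col.isna()
            if missing.any():
                logger.warning(
                    "%s: %d missing %s_%s cells filled with 0",
                    path, int(missing.sum()), sid, kind,
                )
            vals = col.fillna(0).to_numpy(dtype=np.int64)
            if (vals < 0).any():
                raise ValueError(f"{path}: negative counts in {sid}_{kind}")
            mat[:, j] = vals
    return LocusCountTable(loci, subclones, ref_counts, alt_counts)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def read_tree(path_or_string: str) -> LineageTree:
    """Read a rooted binary lineage tree from Newick.

    Edge lengths are interpreted as generation counts (positive integers);
    absent lengths default to 1 with a warning; fractional or non-positive
    lengths and non-binary nodes are errors.
    """
    try:
        if os.path.exists(path_or_string):
            dt = dendropy.Tree.get(path=path_or_string, schema="newick")
        else:
            dt = dendropy.Tree.get(data=path_or_string, schema="newick")
    except Exception as exc:  # dendropy DataParseError on e.g. duplicate leaves
        raise ValueError(f"malformed Newick: {exc}") from exc

    warned = False

    def convert(dnode) -> TreeNode:
        nonlocal warned
        children = dnode.child_nodes()
        if children and len(children) != 2:
            raise ValueError(
                f"non-binary node with {len(children)} children"
            )
        name = dnode.taxon.label if dnode.taxon else dnode.label
        node = TreeNode(name=name if not children else None)
        length = dnode.edge.length
        if length is None:
            if dnode.parent_node is not None and not warned:
                logger.warning("edge lengths absent; defaulting to 1 generation")
                warned = True
            node.n = 1
        else:
            if length <= 0:
                raise ValueError(f"non-positive generation count {length}")
            if abs(length - round(length)) > 1e-9:
                raise ValueError(
                    f"fractional generation count {length}; counts must be integers"
                )
            node.n = int(round(length))
        for child in children:
            node.children.append(convert(child))
        return node

    tree = LineageTree(convert(dt.seed_node))
    return tree.validate()


def write_tree(tree: LineageTree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Call sets (VCF + TSV mirror)
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=CLASS,Number=1,Type=String,Description="branch or leaf">
##INFO=<ID=CLADE,Number=1,Type=String,Description="Comma-joined carrier subclone ids (sorted)">
##INFO=<ID=SEGMENT,Number=1,Type=String,Description="Assigned lineage-tree edge id">
##INFO=<ID=Q,Number=1,Type=Float,Description="Coincident classification quality (min sample posterior)">
"""


def write_callset(
    branch: Sequence[BranchVariant],
    leaf: Sequence[LeafVariant],
    path: str,
) -> None:
    """Write branch + leaf calls as a VCF plus a TSV mirror (``path`` with
    extension .tsv), deterministically ordered by locus then alt."""
    records = []
    for bv in branch:
        vl = bv.variant_locus
        records.append(
            (
                vl,
                "branch",
                ",".join(sorted(bv.clade)),
                bv.edge_id,
                bv.quality,
            )
        )
    for lv in leaf:
        records.append(
            (lv.variant_locus, "leaf", lv.subclone_id, lv.subclone_id, lv.quality)
        )
    records.sort(key=lambda r: r[0])
    contigs = []
    for vl, *_ in records:
        if vl.chrom not in contigs:
            contigs.append(vl.chrom)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for vl, cls, clade, segment, q in records:
            qstr = "." if q is None else f"{q:.6g}"
            info = f"CLASS={cls};CLADE={clade};SEGMENT={segment};Q={qstr}"
            fh.write(
                f"{vl.chrom}\t{vl.pos}\t.\t{vl.ref}\t{vl.alt}\t.\tPASS\t{info}\n"
            )
    tsv_path = os.path.splitext(path)[0] + ".tsv"
    with open(tsv_path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tclass\tclade\tsegment\tquality\n")
        for vl, cls, clade, segment, q in records:
            qstr = "" if q is None else f"{q:.6g}"
            fh.write(
                f"{vl.chrom}\t{vl.pos}\t{vl.ref}\t{vl.alt}\t{cls}\t{clade}\t{segment}\t{qstr}\n"
            )


def _info_str(value) -> str:
    # pysam splits comma-separated INFO strings into tuples
    if isinstance(value, (tuple, list)):
        return ",".join(str(v) for v in value)
    return str(value)


def read_callset(path: str) -> tuple[list[BranchVariant], list[LeafVariant]]:
    """Read back a call-set VCF written by :func:`write_callset`."""
    from .core import CoincidentGroup

    branch: list[BranchVariant] = []
    leaf: list[LeafVariant] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            cls = rec.info["CLASS"]
            q = float(rec.info["Q"]) if "Q" in rec.info else None
            vl = VariantLocus(rec.contig, rec.pos, rec.ref, rec.alts[0])
            clade = sorted(_info_str(rec.info["CLADE"]).split(","))
            if cls == "branch":
                grp = CoincidentGroup(vl, frozenset(clade), quality=q)
                branch.append(BranchVariant(grp, _info_str(rec.info["SEGMENT"])))
            else:
                leaf.append(LeafVariant(vl, clade[0], quality=q))
    return branch, leaf


# ---------------------------------------------------------------------------
# BED tracks, coverage, signature matrices
# ---------------------------------------------------------------------------


def read_bed_track(path: str, payload: str = "name") -> IntervalTrack:
    """Read a BED file into an IntervalTrack.

    ``payload``: "name" uses column 4 (region class); "score" uses column 5
    parsed as float (e.g. a timing value or slope); "none" stores None.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line ({exc})")
            if payload == "name":
                value: object = fields[3] if len(fields) > 3 else None
            elif payload == "score":
                value = float(fields[4] if len(fields) > 4 else fields[3])
            else:
                value = None
            intervals.append((chrom, start, end, value))
    return IntervalTrack(intervals)


def write_bed_track(track: IntervalTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, payload in track:
            name = "." if payload is None else str(payload)
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_coverage(path: str) -> pd.DataFrame:
    """Binned coverage TSV with columns chrom, start, coverage."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "start", "coverage"):
        if col not in df.columns:
            raise ValueError(f"{path}: column {col!r} missing")
    return df


def write_coverage(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_signature_matrix(path: str) -> pd.DataFrame:
    """96 x K signature matrix TSV, first column = channel label."""
    from .spectra import CHANNELS

    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != CHANNELS:
        raise ValueError(
            f"{path}: signature matrix must have the canonical 96 channel "
            "labels in canonical order"
        )
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative signature entries")
    return df
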
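import numpy as np
import pytest

from lineageseq import LocusCountTable, VariantLocus
from lineageseq.io import read_tree


@pytest.fixture
def quartet_tree():
    """((A:1,B:1):2,(C:1,D:1):1); — 4 subclones, edge above {A,B} spans
    two divisions."""
    return read_tree("((A:1,B:1):2,(C:1,D:1):1);")


def make_counts(loci, subclones, cells):
    """Build a LocusCountTable from {(locus_idx, subclone): (ref, alt)};
    unspecified cells default to clean reference coverage 30/0."""
    n, m = len(loci), len(subclones)
    ref = np.full((n, m), 30, dtype=np.int64)
    alt = np.zeros((n, m), dtype=np.int64)
    for (i, sid), (r, a) in cells.items():
        j = subclones.index(sid)
        ref[i, j] = r
        alt[i, j] = a
    return LocusCountTable(loci, subclones, ref, alt)


@pytest.fixture
def counts_builder():
    return make_counts


@pytest.fixture
def het_locus():
    return VariantLocus("chr1", 111370246, "G", "T")
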
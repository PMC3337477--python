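import numpy as np
import pandas as pd
import pytest

from readthrough.annotation import GeneModel, GeneSet
from readthrough.quant import AlignmentSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_genes():
    """Hand-laid gene set: coding genes on both strands, a MIR locus, a
    miRNA target, and a convergent pair with facing 3' ends 200 bp apart."""
    genes = [
        GeneModel("gA", "chr1", "+", 101, 1100),
        GeneModel("gB", "chr1", "-", 3001, 4000),
        GeneModel("mir1", "chr1", "+", 6001, 6300, kind="mir"),
        GeneModel("tgt1", "chr1", "-", 8001, 9000, is_mirna_target=True),
        # convergent pair: gC(+) ends 12000, gD(-) starts 12201
        GeneModel("gC", "chr1", "+", 11001, 12000),
        GeneModel("gD", "chr1", "-", 12201, 13200),
    ]
    return GeneSet(genes=genes, chrom_lengths={"chr1": 20000})


def make_alignments(rows, library_id="lib", genotype="WT", replicate=1, total_mapped=None):
    """rows: iterable of (chrom, begin, end, strand)."""
    df = pd.DataFrame(rows, columns=["chrom", "begin", "end", "strand"])
    return AlignmentSet(library_id, genotype, replicate, df, total_mapped or max(len(df), 1))


def brute_force_count(aln, window, same_strand=True):
    """Independent per-read scan oracle for window counting."""
    n = 0
    for row in aln.intervals.itertuples(index=False):
        if row.chrom != window.chrom:
            continue
        if same_strand and row.strand != window.strand:
            continue
        if row.begin < window.end and window.begin < row.end:
            n += 1
    return n
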
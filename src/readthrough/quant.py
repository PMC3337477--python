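"""Strand-specific read counting over windows and RPKM quantification.

A read counts toward a window if >=1 bp of its interval overlaps the window
and (by default) it lies on the window's strand; read-through products are
continuations on the gene's own strand, so same-strand counting is the
default for downstream and pri-miRNA windows.

RPKM = count / (window_kb * million mapped reads), with the denominator
taken from the library's genome-wide uniquely-mapped total, not the sum of
stored intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .windows import GenomicWindow

logger = logging.getLogger(__name__)

RPKM_CATEGORIES = ("C1", "C2", "C3", "C4")
#: upper bounds of the four abundance categories (RPKM <=0.2, (0.2,1], (1,10], >10)
RPKM_CATEGORY_EDGES = (0.2, 1.0, 10.0)

QUANT_COLUMNS = ["gene_id", "role", "genotype", "replicate", "count", "rpkm"]


@dataclass
class AlignmentSet:
    """Uniquely-mapped read intervals for one sequencing library.

    ``intervals`` is a DataFrame with columns chrom, begin, end, strand
    (0-based half-open). ``total_mapped`` is the library-wide count of
    uniquely mapped reads and may exceed ``len(intervals)`` when only a
    region subset is loaded.
    """

    library_id: str
    genotype: str
    replicate: int
    intervals: pd.DataFrame
    total_mapped: int
    _index: dict = field(default_factory=dict, init=False, repr=False)

    def __post_init__(self) -> None:
        missing = {"chrom", "begin", "end", "strand"} - set(self.intervals.columns)
        if missing:
            raise ValueError(f"intervals missing columns: {sorted(missing)}")
        if self.total_mapped < len(self.intervals):
            raise ValueError("total_mapped smaller than number of stored intervals")

    def _chrom_index(self, chrom: str, strand: str | None):
        """Sorted begin/end arrays for (chrom, strand); strand None pools both."""
        key = (chrom, strand)
        if key not in self._index:
            df = self.intervals
            mask = df["chrom"].to_numpy() == chrom
            if strand is not None:
                mask &= df["strand"].to_numpy() == strand
            begins = np.sort(df["begin"].to_numpy()[mask])
            ends = np.sort(df["end"].to_numpy()[mask])
            self._index[key] = (begins, ends)
        return self._index[key]


def count_reads(aln: AlignmentSet, window: GenomicWindow, same_strand: bool = True) -> int:
    """Number of reads overlapping ``window`` by >=1 bp.

    With ``same_strand`` (default) only reads on the window's strand count;
    otherwise strand is ignored. Each read is counted at most once.
    """
    if window.length <= 0:
        raise ValueError("window length must be positive")
    if window.chrom not in set(aln.intervals["chrom"].unique()):
        logger.warning("library %s has no reads on %s", aln.library_id, window.chrom)
        return 0
    begins, ends = aln._chrom_index(window.chrom, window.strand if same_strand else None)
    # overlap iff begin < window.end and end > window.begin; the two
    # violating sets are disjoint for a positive-length window
    n_begin_after = begins.size - np.searchsorted(begins, window.end, side="left")
    n_end_before = np.searchsorted(ends, window.begin, side="right")
    return int(begins.size - n_begin_after - n_end_before)


def rpkm(count: float, window_length: int, total_mapped: int) -> float:
    """Reads per kilobase of window per million uniquely mapped reads."""
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return count / ((window_length / 1000.0) * (total_mapped / 1e6))


def mean_rpkm(values: Sequence[float]) -> float:
    """Arithmetic mean across replicates."""
    if len(values) == 0:
        raise ValueError("need at least one replicate value")
    return float(np.mean(values))


def categorize_rpkm(value: float) -> str:
    """Four-category abundance bin: C1 <=0.2, C2 (0.2,1], C3 (1,10], C4 >10."""
    if value < 0:
        raise ValueError("RPKM cannot be negative")
    for cat, edge in zip(RPKM_CATEGORIES, RPKM_CATEGORY_EDGES):
        if value <= edge:
            return cat
    return "C4"


def categorize_rpkm_series(values: pd.Series | np.ndarray) -> pd.Series:
    values = pd.Series(values)
    if (values < 0).any():
        raise ValueError("RPKM cannot be negative")
    edges = [-np.inf, *RPKM_CATEGORY_EDGES, np.inf]
    return pd.cut(values, bins=edges, labels=list(RPKM_CATEGORIES)).astype(str)


def quantify(
    windows: Iterable[GenomicWindow],
    libraries: Sequence[AlignmentSet],
    same_strand: bool = True,
) -> pd.DataFrame:
    """Count reads and compute RPKM for every window x library.

    Returns the long-format quantification table with columns
    ``gene_id, role, genotype, replicate, count, rpkm``.
    """
    rows = []
    for w in windows:
        if not w.is_testable:
            continue
        for lib in libraries:
            c = count_reads(lib, w, same_strand=same_strand)
            rows.append((w.gene_id, w.role, lib.genotype, lib.replicate, c, rpkm(c, w.length, lib.total_mapped)))
    return pd.DataFrame(rows, columns=QUANT_COLUMNS)


# ---------------------------------------------------------------------------
# I/O


def read_alignments_bed(
    path: str | Path,
    library_id: str,
    genotype: str,
    replicate: int,
    total_mapped: int | None = None,
) -> AlignmentSet:
    """Load one read interval per BED6 line (chrom, begin, end, name, score, strand).

    ``total_mapped`` defaults to the number of lines, i.e. the file is taken
    to hold the whole library.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 5],
        names=["chrom", "begin", "end", "strand"],
        dtype={"chrom": str, "begin": np.int64, "end": np.int64, "strand": str},
    )
    return AlignmentSet(library_id, genotype, replicate, df, total_mapped or len(df))


def read_alignments_bam(
    path: str | Path,
    library_id: str,
    genotype: str,
    replicate: int,
    total_mapped: int | None = None,
) -> AlignmentSet:
    """Adapter for coordinate-sorted BAM: one interval per aligned block.

    A spliced read contributes all its aligned blocks (so it counts toward a
    window if any block overlaps it); secondary/supplementary/unmapped
    records are skipped.
    """
    import pysam

    rows = []
    n_reads = 0
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            n_reads += 1
            strand = "-" if rec.is_reverse else "+"
            for b, e in rec.get_blocks():
                rows.append((rec.reference_name, b, e, strand))
    df = pd.DataFrame(rows, columns=["chrom", "begin", "end", "strand"])
    return AlignmentSet(library_id, genotype, replicate, df, total_mapped or n_reads)


def read_library_manifest(path: str | Path) -> list[AlignmentSet]:
    """Read libraries from a manifest TSV: library_id, genotype, replicate, path[, total_mapped].

    Relative read-file paths are resolved against the manifest's directory.
    """
    man = pd.read_csv(path, sep="\t")
    required = {"library_id", "genotype", "replicate", "path"}
    if not required <= set(man.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    base = Path(path).parent
    libs = []
    for row in man.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        total = int(row.total_mapped) if "total_mapped" in man.columns and pd.notna(row.total_mapped) else None
        libs.append(read_alignments_bed(p, row.library_id, row.genotype, int(row.replicate), total))
    return libs


def write_quant_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_quant_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(QUANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"quant table missing columns: {sorted(missing)}")
    return df
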
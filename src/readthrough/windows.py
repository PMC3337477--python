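"""Window geometry for 3' surveillance quantification.

Three window families are derived from gene models, all strand-aware and
0-based half-open:

* ``downstream500`` — the fixed-length region immediately 3' of a gene's
  annotated terminus, where read-through ("3' extension") signal appears
  when 5'->3' exonucleolytic surveillance fails.
* ``primirna_ext`` — a pri-miRNA gene span extended by a downstream pad,
  capturing the 3' remnant left after the miRNA hairpin is excised
  (annotated MIR models typically end at the hairpin).
* ``target_head200`` / ``target_tail200`` — the first and last stretch of a
  miRNA-target transcript in transcription order, used to compare 5' vs 3'
  cleavage-fragment accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .annotation import GeneModel, GeneSet

ROLES = ("downstream500", "primirna_ext", "target_head200", "target_tail200")


@dataclass(frozen=True)
class GenomicWindow:
    """Strand-tagged 0-based half-open interval derived from a gene model."""

    gene_id: str
    chrom: str
    strand: str
    begin: int
    end: int
    role: str
    truncated: bool = False

    @property
    def length(self) -> int:
        return self.end - self.begin

    @property
    def is_testable(self) -> bool:
        """False for zero-length windows (gene flush against a chromosome edge)."""
        return self.end > self.begin

    def overlaps(self, begin: int, end: int) -> bool:
        """>=1 bp overlap with a half-open interval, strand-agnostic."""
        return self.begin < end and begin < self.end


def _clamp(begin: int, end: int, chrom_len: int) -> tuple[int, int, bool]:
    b, e = max(begin, 0), min(end, chrom_len)
    if e < b:
        b = e = min(max(begin, 0), chrom_len)
    return b, e, (b, e) != (begin, end)


def downstream_window(gene: GeneModel, length: int = 500, chrom_len: int | None = None) -> GenomicWindow:
    """Window of ``length`` nt immediately downstream of the gene's 3' end.

    For a ``+`` gene ending at 1-based ``end`` this is 1-based bases
    ``end+1 .. end+length``; for a ``-`` gene starting at ``start`` it is
    ``start-length .. start-1``. Truncated (and flagged) at chromosome
    boundaries; a gene flush against the edge yields a zero-length window
    that callers exclude as untestable.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if chrom_len is None:
        chrom_len = gene.end + length
    if gene.strand == "+":
        begin, end = gene.end0, gene.end0 + length
    else:
        begin, end = gene.begin0 - length, gene.begin0
    begin, end, trunc = _clamp(begin, end, chrom_len)
    return GenomicWindow(gene.id, gene.chrom, gene.strand, begin, end, "downstream500", trunc)


def primirna_window(gene: GeneModel, pad: int = 500, chrom_len: int | None = None) -> GenomicWindow:
    """Gene span extended ``pad`` nt past its 3' end (strand-aware union)."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    if gene.kind != "mir":
        raise ValueError(f"gene {gene.id} is not a MIR locus")
    if chrom_len is None:
        chrom_len = gene.end + pad
    if gene.strand == "+":
        begin, end = gene.begin0, gene.end0 + pad
    else:
        begin, end = gene.begin0 - pad, gene.end0
    begin, end, trunc = _clamp(begin, end, chrom_len)
    return GenomicWindow(gene.id, gene.chrom, gene.strand, begin, end, "primirna_ext", trunc)


def target_end_windows(gene: GeneModel, length: int = 200) -> tuple[GenomicWindow, GenomicWindow]:
    """Head (first ``length`` nt) and tail (last ``length`` nt) of a target.

    Both windows lie inside the gene span and are clipped to it (flagged)
    when the gene is shorter than ``length``.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    trunc = gene.length < length
    n = min(length, gene.length)
    five = (gene.begin0, gene.begin0 + n)   # 5'-most n bases in genome coords
    three = (gene.end0 - n, gene.end0)      # 3'-most n bases
    if gene.strand == "+":
        head, tail = five, three
    else:
        head, tail = three, five
    return (
        GenomicWindow(gene.id, gene.chrom, gene.strand, head[0], head[1], "target_head200", trunc),
        GenomicWindow(gene.id, gene.chrom, gene.strand, tail[0], tail[1], "target_tail200", trunc),
    )


def build_windows(
    genes: GeneSet,
    downstream_length: int = 500,
    primirna_pad: int = 500,
    target_length: int = 200,
) -> list[GenomicWindow]:
    """All quantification windows for a gene set.

    Every gene gets a downstream window; MIR loci additionally get the
    padded pri-miRNA window; miRNA targets get head/tail windows.
    Zero-length (untestable) downstream windows are dropped.
    """
    out: list[GenomicWindow] = []
    for g in genes:
        clen = genes.chrom_length(g.chrom)
        w = downstream_window(g, downstream_length, clen)
        if w.is_testable:
            out.append(w)
        if g.kind == "mir":
            out.append(primirna_window(g, primirna_pad, clen))
        if g.is_mirna_target:
            out.extend(target_end_windows(g, target_length))
    return out


def write_bed6(windows: Iterable[GenomicWindow], path: str | Path) -> None:
    """Write windows as BED6: name = ``gene_id:role``, score 0."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.begin}\t{w.end}\t{w.gene_id}:{w.role}\t0\t{w.strand}\n")
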
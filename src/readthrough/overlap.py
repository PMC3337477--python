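"""Strand-aware interval integration of extension calls, genes and DMRs.

Three questions from the downstream analysis:

* which extension spans run into an opposite-strand neighbouring gene
  (potential double-stranded RNA from antisense overlap);
* which pairs of extension spans from convergent genes overlap each other;
* whether any DMR intersects an extension span (strand-agnostic).

All overlaps are >=1 bp on half-open intervals; indexed queries use an
interval tree, and the test suite checks them against a quadratic
all-pairs scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .annotation import GeneSet
from .dmr import DMR
from .extensions import ExtensionCall
from .windows import downstream_window


@dataclass(frozen=True)
class ExtensionSpan:
    """The downstream window of a passed extension call (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    begin: int
    end: int


def spans_from_calls(
    calls: Sequence[ExtensionCall], genes: GeneSet, length: int = 500
) -> list[ExtensionSpan]:
    """Downstream windows (possibly boundary-truncated) of passed calls."""
    spans = []
    for c in calls:
        if not c.passed:
            continue
        g = genes[c.gene_id]
        w = downstream_window(g, length, genes.chrom_length(g.chrom))
        if w.is_testable:
            spans.append(ExtensionSpan(g.id, g.chrom, g.strand, w.begin, w.end))
    return spans


def _tree_by_chrom(items: Iterable[tuple[int, int, object]], chroms: Iterable[str]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, begin, end, payload in items:
        if end > begin:
            trees.setdefault(chrom, IntervalTree()).addi(begin, end, payload)
    return trees


def antisense_overlaps(spans: Sequence[ExtensionSpan], genes: GeneSet) -> list[tuple[str, str]]:
    """(span gene, partner gene) pairs where the span overlaps an
    opposite-strand gene other than its own parent."""
    trees = _tree_by_chrom(((g.chrom, g.begin0, g.end0, g) for g in genes), genes.chrom_lengths)
    pairs = []
    for s in spans:
        tree = trees.get(s.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(s.begin, s.end), key=lambda iv: (iv.begin, iv.data.id)):
            g = iv.data
            if g.strand != s.strand and g.id != s.gene_id:
                pairs.append((s.gene_id, g.id))
    return pairs


def antisense_span_count(pairs: Sequence[tuple[str, str]]) -> int:
    """Summary count: spans with >=1 opposite-strand partner (each once)."""
    return len({a for a, _ in pairs})


def mutual_extension_overlaps(spans: Sequence[ExtensionSpan]) -> list[tuple[str, str]]:
    """Unordered pairs of opposite-strand extension spans that overlap."""
    trees = _tree_by_chrom(
        ((s.chrom, s.begin, s.end, s) for s in spans), {s.chrom for s in spans}
    )
    seen: set[tuple[str, str]] = set()
    for s in spans:
        for iv in trees[s.chrom].overlap(s.begin, s.end):
            o = iv.data
            if o.gene_id == s.gene_id or o.strand == s.strand:
                continue
            seen.add(tuple(sorted((s.gene_id, o.gene_id))))
    return sorted(seen)


def dmr_extension_overlap(dmrs: Sequence[DMR], spans: Sequence[ExtensionSpan]) -> list[tuple[int, str]]:
    """Strand-agnostic (dmr index, span gene) intersection pairs."""
    trees = _tree_by_chrom(
        ((s.chrom, s.begin, s.end, s) for s in spans), {s.chrom for s in spans}
    )
    pairs = []
    for i, d in enumerate(dmrs):
        tree = trees.get(d.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(d.begin, d.end), key=lambda iv: (iv.begin, iv.data.gene_id)):
            pairs.append((i, iv.data.gene_id))
    return pairs
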
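"""Gene annotation input: gene models, gene sets, GFF3/GTF reading.

Coordinates follow the field's two conventions explicitly: :class:`GeneModel`
stores the annotation's 1-based inclusive span (as in GFF3/GTF), while all
derived windows (:mod:`readthrough.windows`) and interval arithmetic use
0-based half-open coordinates. Conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils.iterators

logger = logging.getLogger(__name__)

#: gene classes recognised throughout the package
GENE_KINDS = ("coding", "mir", "transposon", "other")

_MIR_FEATURETYPES = {"miRNA", "miRNA_primary_transcript", "pre_miRNA"}
_TE_FEATURETYPES = {"transposable_element_gene", "transposable_element"}


@dataclass(frozen=True)
class GeneModel:
    """One annotated transcript unit.

    ``start``/``end`` are 1-based inclusive genomic coordinates
    (``start <= end``); ``strand`` is ``'+'`` or ``'-'``.
    """

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    kind: str = "coding"
    is_mirna_target: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"gene {self.id}: invalid span {self.start}..{self.end}")
        if self.kind not in GENE_KINDS:
            raise ValueError(f"gene {self.id}: unknown kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def begin0(self) -> int:
        """0-based half-open begin of the gene span."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based half-open end of the gene span."""
        return self.end

    def three_prime_end(self) -> int:
        """1-based coordinate of the annotated 3' terminus (strand-aware)."""
        return self.end if self.strand == "+" else self.start


@dataclass
class GeneSet:
    """Ordered collection of gene models plus chromosome lengths."""

    genes: list[GeneModel] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.id in seen:
                raise ValueError(f"duplicate gene ID {g.id!r}")
            seen.add(g.id)
            clen = self.chrom_lengths.get(g.chrom)
            if clen is not None and g.end > clen:
                raise ValueError(
                    f"gene {g.id} span {g.start}..{g.end} exceeds {g.chrom} length {clen}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def chrom_length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            # fall back to the furthest annotated base on that chromosome
            ends = [g.end for g in self.genes if g.chrom == chrom]
            if not ends:
                raise
            return max(ends)

    def mir_loci(self) -> list[GeneModel]:
        return [g for g in self.genes if g.kind == "mir"]

    def mirna_targets(self) -> list[GeneModel]:
        return [g for g in self.genes if g.is_mirna_target]


def _read_id_list(path: str | Path | None) -> set[str]:
    if path is None:
        return set()
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def _feature_id(feature) -> str | None:
    for key in ("ID", "gene_id", "Name"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    return None


def read_annotation(
    path: str | Path,
    mir_ids: Iterable[str] | str | Path | None = None,
    target_ids: Iterable[str] | str | Path | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
    feature_types: Sequence[str] = ("gene",),
) -> GeneSet:
    """Read a GFF3/GTF annotation into a :class:`GeneSet`.

    Parameters
    ----------
    path
        GFF3 or GTF file; top-level features whose type is in
        ``feature_types`` (or a recognised miRNA/transposon type) become
        gene models.
    mir_ids, target_ids
        Either an iterable of IDs or the path of a plain-text file with one
        ID per line. Genes in ``mir_ids`` (or with a miRNA feature type)
        get ``kind='mir'``; genes in ``target_ids`` are flagged
        ``is_mirna_target``.
    chrom_lengths
        Optional chromosome sizes; otherwise taken from
        ``##sequence-region`` pragmas when present.

    Records without a usable strand are skipped with a warning; duplicate
    gene IDs raise ``ValueError``.
    """
    path = Path(path)
    mir_set = set(mir_ids) if isinstance(mir_ids, (set, frozenset, list, tuple)) else _read_id_list(mir_ids)
    target_set = (
        set(target_ids) if isinstance(target_ids, (set, frozenset, list, tuple)) else _read_id_list(target_ids)
    )

    lengths: dict[str, int] = dict(chrom_lengths or {})
    if not chrom_lengths:
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    parts = line.split()
                    if len(parts) >= 4:
                        lengths[parts[1]] = int(parts[3])
                elif not line.startswith("#"):
                    break

    accepted = set(feature_types) | _MIR_FEATURETYPES | _TE_FEATURETYPES
    genes: list[GeneModel] = []
    n_skipped = 0
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feat.featuretype not in accepted:
            continue
        gid = _feature_id(feat)
        if gid is None:
            logger.warning("feature at %s:%d-%d has no ID; skipped", feat.seqid, feat.start, feat.end)
            n_skipped += 1
            continue
        if feat.strand not in ("+", "-"):
            logger.warning("gene %s has no strand; skipped", gid)
            n_skipped += 1
            continue
        if feat.featuretype in _MIR_FEATURETYPES or gid in mir_set:
            kind = "mir"
        elif feat.featuretype in _TE_FEATURETYPES:
            kind = "transposon"
        else:
            kind = "coding"
        genes.append(
            GeneModel(
                id=gid,
                chrom=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
                kind=kind,
                is_mirna_target=gid in target_set,
            )
        )
    if n_skipped:
        logger.warning("skipped %d annotation records", n_skipped)
    return GeneSet(genes=genes, chrom_lengths=lengths)
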
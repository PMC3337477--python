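"""Calling 3' transcript-extension candidates from downstream-window RPKM.

A gene is called when its 500-nt downstream window shows mutant/wild-type
fold change above ``min_fold``, mutant mean RPKM above ``min_mut_rpkm``, a
replicate t-test p-value below ``max_p``, and the signal cannot be a
pri-miRNA 3' remnant (the gene is not a MIR locus and its downstream window
does not touch one on either strand). All comparisons are strict.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneSet
from .stats import student_t
from .windows import downstream_window

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExtensionFilterParams:
    """Four-parameter candidate filter; ``max_p=None`` disables the p filter."""

    min_fold: float = 5.0
    min_mut_rpkm: float = 1.0
    max_p: float | None = 0.1
    exclude_mir: bool = True

    def __post_init__(self) -> None:
        if self.min_fold <= 0:
            raise ValueError("min_fold must be positive")
        if self.max_p is not None and not (0 < self.max_p <= 1):
            raise ValueError("max_p must be in (0, 1]")


#: stringent preset: fold > 5, mutant RPKM > 1, p < 0.1, non-pri-miRNA
DEFAULT_PARAMS = ExtensionFilterParams()
#: relaxed preset: fold > 2, mutant RPKM > 1, non-pri-miRNA (no p filter)
RELAXED_PARAMS = ExtensionFilterParams(min_fold=2.0, max_p=None)


@dataclass(frozen=True)
class ExtensionCall:
    gene_id: str
    wt_mean_rpkm: float
    mut_mean_rpkm: float
    fold: float            # mut/wt; +inf when wt==0 < mut; nan when both 0
    p: float               # nan when the p filter was not applicable
    passed: bool
    filter_trace: dict = field(hash=False, compare=False, default_factory=dict)


def _fold_change(wt_mean: float, mut_mean: float) -> float:
    if wt_mean > 0:
        return mut_mean / wt_mean
    return math.inf if mut_mean > 0 else math.nan


def _mir_conflicts(genes: GeneSet, downstream_length: int) -> set[str]:
    """Genes that are MIR loci or whose downstream window overlaps one (either strand)."""
    mirs = genes.mir_loci()
    bad: set[str] = {m.id for m in mirs}
    for g in genes:
        if g.id in bad:
            continue
        w = downstream_window(g, downstream_length, genes.chrom_length(g.chrom))
        for m in mirs:
            if m.chrom == g.chrom and w.overlaps(m.begin0, m.end0):
                bad.add(g.id)
                break
    return bad


def call_extensions(
    quant: pd.DataFrame,
    wt: str,
    mut: str,
    genes: GeneSet,
    params: ExtensionFilterParams = DEFAULT_PARAMS,
    downstream_length: int = 500,
) -> list[ExtensionCall]:
    """Score every gene with a downstream window and apply the candidate filter.

    ``quant`` is the long quantification table (see :mod:`readthrough.quant`);
    fold and means use per-replicate RPKM, the p-value comes from the pooled
    t-test on the same replicate RPKM values. With fewer than two replicates
    in either genotype the p filter is skipped with a warning (as in the
    relaxed preset).
    """
    sub = quant[quant["role"] == "downstream500"]
    for label in (wt, mut):
        if label not in set(sub["genotype"].unique()):
            raise ValueError(f"genotype {label!r} absent from quantification table")
    mir_bad = _mir_conflicts(genes, downstream_length) if params.exclude_mir else set()

    grouped = sub.groupby(["gene_id", "genotype"])["rpkm"].apply(list)
    calls: list[ExtensionCall] = []
    warned = False
    for gene_id in sub["gene_id"].unique():
        wt_reps = np.asarray(grouped.get((gene_id, wt), []), dtype=float)
        mut_reps = np.asarray(grouped.get((gene_id, mut), []), dtype=float)
        if wt_reps.size == 0 or mut_reps.size == 0:
            continue
        wt_mean = float(wt_reps.mean())
        mut_mean = float(mut_reps.mean())
        fold = _fold_change(wt_mean, mut_mean)

        trace: dict[str, bool | None] = {}
        trace["fold"] = fold > params.min_fold  # nan fails, inf passes
        trace["mut_rpkm"] = mut_mean > params.min_mut_rpkm
        p = math.nan
        if params.max_p is None:
            trace["p"] = None
        elif wt_reps.size < 2 or mut_reps.size < 2:
            if not warned:
                logger.warning("fewer than 2 replicates in a genotype; p filter skipped")
                warned = True
            trace["p"] = None
        else:
            p = student_t(mut_reps, wt_reps).p
            trace["p"] = p < params.max_p
        trace["non_pri_mirna"] = (gene_id not in mir_bad) if params.exclude_mir else None
        passed = all(v for v in trace.values() if v is not None)
        calls.append(ExtensionCall(gene_id, wt_mean, mut_mean, fold, p, passed, trace))
    return calls


def passed_ids(calls: Sequence[ExtensionCall]) -> set[str]:
    return {c.gene_id for c in calls if c.passed}


def raw_extension_count(quant: pd.DataFrame, mut: str, wt: str | None = None) -> int:
    """Number of genes with any downstream signal in the mutant.

    Default reading: mutant mean downstream RPKM > 0. Passing ``wt``
    switches to the stricter "new transcript" reading (mutant > 0 AND
    wild-type == 0).
    """
    sub = quant[quant["role"] == "downstream500"]
    if mut not in set(sub["genotype"].unique()):
        raise ValueError(f"genotype {mut!r} absent from quantification table")
    means = sub.groupby(["gene_id", "genotype"])["rpkm"].mean().unstack("genotype")
    positive = means[mut] > 0
    if wt is not None:
        positive &= means[wt].fillna(0) == 0
    return int(positive.sum())


def candidate_overlap(
    calls_a: Sequence[ExtensionCall], calls_b: Sequence[ExtensionCall]
) -> tuple[int, float, float]:
    """Shared passed gene IDs and the fraction of each call set they represent."""
    a, b = passed_ids(calls_a), passed_ids(calls_b)
    shared = len(a & b)
    frac_a = shared / len(a) if a else 0.0
    frac_b = shared / len(b) if b else 0.0
    if not a or not b:
        logger.warning("empty passed set in candidate overlap")
    return shared, frac_a, frac_b


def calls_to_table(calls: Sequence[ExtensionCall]) -> pd.DataFrame:
    """Per-gene call table (TSV-ready) with the per-filter trace flattened."""
    rows = []
    for c in calls:
        trace = ";".join(f"{k}={'skip' if v is None else ('pass' if v else 'fail')}" for k, v in c.filter_trace.items())
        rows.append((c.gene_id, c.wt_mean_rpkm, c.mut_mean_rpkm, c.fold, c.p, c.passed, trace))
    return pd.DataFrame(
        rows, columns=["gene_id", "wt_mean_rpkm", "mut_mean_rpkm", "fold", "p", "passed", "filter_trace"]
    )


def relaxed(params: ExtensionFilterParams = DEFAULT_PARAMS) -> ExtensionFilterParams:
    """The relaxed variant of a parameter set (fold > 2, p filter off)."""
    return replace(params, min_fold=2.0, max_p=None)
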
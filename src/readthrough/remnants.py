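"""Quantification of miRNA-pathway degradation intermediates.

Two read-outs of failed 5'->3' exonucleolytic decay:

* pri-miRNA 3' remnants — signal over the padded pri-miRNA window
  (annotated hairpin span plus downstream pad), summarised per genotype;
* miRNA-target cleavage fragments — head (5') versus tail (3') window
  signal per target; the 3' cleavage product accumulates in surveillance
  mutants while the 5' end is unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .quant import categorize_rpkm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RemnantProfile:
    locus_id: str
    role: str
    mean_rpkm: dict          # genotype -> mean RPKM over replicates
    category: dict           # genotype -> C1..C4
    fold: float              # mut/wt convention of the caller; nan if undefined

    @property
    def expressed(self) -> bool:
        return any(v > 0 for v in self.mean_rpkm.values())


def _fold(wt: float, mut: float) -> float:
    if wt > 0:
        return mut / wt
    return math.inf if mut > 0 else math.nan


def _mean_by_genotype(sub: pd.DataFrame, genotypes: Sequence[str]) -> pd.DataFrame:
    means = sub.groupby(["gene_id", "genotype"])["rpkm"].mean().unstack("genotype")
    missing = set(genotypes) - set(means.columns)
    if missing:
        raise ValueError(f"genotypes absent from quantification table: {sorted(missing)}")
    return means[list(genotypes)]


def quantify_primirnas(
    quant: pd.DataFrame, wt: str, mut: str, min_expressed_rpkm: float = 0.0
) -> list[RemnantProfile]:
    """One profile per MIR locus over the padded pri-miRNA window.

    A locus is "expressed" when its mean RPKM exceeds
    ``min_expressed_rpkm`` in at least one genotype; count expressed
    profiles via :func:`expressed_count`.
    """
    sub = quant[quant["role"] == "primirna_ext"]
    if sub.empty:
        logger.warning("no pri-miRNA windows in quantification table")
        return []
    means = _mean_by_genotype(sub, (wt, mut))
    profiles = []
    for locus_id, row in means.iterrows():
        mr = {g: float(row[g]) for g in (wt, mut)}
        profiles.append(
            RemnantProfile(
                locus_id,
                "primirna_ext",
                mr,
                {g: categorize_rpkm(v) for g, v in mr.items()},
                _fold(mr[wt], mr[mut]),
            )
        )
    return profiles


def expressed_count(profiles: Sequence[RemnantProfile], min_rpkm: float = 0.0) -> int:
    """Number of loci with mean RPKM above ``min_rpkm`` in >=1 genotype."""
    return sum(1 for p in profiles if any(v > min_rpkm for v in p.mean_rpkm.values()))


def quantify_target_ends(
    quant: pd.DataFrame, wt: str, mut: str
) -> list[tuple[RemnantProfile, RemnantProfile]]:
    """Paired head/tail profiles per miRNA target.

    Targets missing either window are dropped with a warning. Per-target
    tail/head ratios per genotype come from :func:`tail_head_ratios`.
    """
    head = quant[quant["role"] == "target_head200"]
    tail = quant[quant["role"] == "target_tail200"]
    head_ids = set(head["gene_id"].unique())
    tail_ids = set(tail["gene_id"].unique())
    dropped = head_ids ^ tail_ids
    if dropped:
        logger.warning("%d target(s) missing a head or tail window; dropped", len(dropped))
    shared = sorted(head_ids & tail_ids)
    if not shared:
        return []
    hm = _mean_by_genotype(head[head["gene_id"].isin(shared)], (wt, mut))
    tm = _mean_by_genotype(tail[tail["gene_id"].isin(shared)], (wt, mut))
    pairs = []
    for gid in shared:
        h = {g: float(hm.loc[gid, g]) for g in (wt, mut)}
        t = {g: float(tm.loc[gid, g]) for g in (wt, mut)}
        pairs.append(
            (
                RemnantProfile(gid, "target_head200", h, {g: categorize_rpkm(v) for g, v in h.items()}, _fold(h[wt], h[mut])),
                RemnantProfile(gid, "target_tail200", t, {g: categorize_rpkm(v) for g, v in t.items()}, _fold(t[wt], t[mut])),
            )
        )
    return pairs


def tail_head_ratios(pair: tuple[RemnantProfile, RemnantProfile]) -> dict:
    """Per-genotype tail/head RPKM ratio; nan (undefined) when head is 0."""
    head, tail = pair
    out = {}
    for g, h in head.mean_rpkm.items():
        t = tail.mean_rpkm[g]
        out[g] = t / h if h > 0 else math.nan
    return out


def profiles_to_table(profiles: Sequence[RemnantProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"locus_id": p.locus_id, "role": p.role, "fold": p.fold, "expressed": p.expressed}
        for g, v in p.mean_rpkm.items():
            row[f"mean_rpkm_{g}"] = v
            row[f"category_{g}"] = p.category[g]
        rows.append(row)
    return pd.DataFrame(rows)


def category_histogram(profiles: Sequence[RemnantProfile]) -> pd.DataFrame:
    """Counts of C1..C4 per genotype across profiles (abundance-profile table)."""
    records = [
        {"genotype": g, "category": c}
        for p in profiles
        for g, c in p.category.items()
    ]
    if not records:
        return pd.DataFrame(columns=["genotype", "C1", "C2", "C3", "C4"])
    df = pd.DataFrame(records)
    hist = df.groupby(["genotype", "category"]).size().unstack("category", fill_value=0)
    for c in ("C1", "C2", "C3", "C4"):
        if c not in hist.columns:
            hist[c] = 0
    return hist[["C1", "C2", "C3", "C4"]].reset_index()
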
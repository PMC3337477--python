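"""Windowed calling of differentially methylated regions (DMRs).

Pipeline, run independently per cytosine context (CG, CHG, CHH) and then
pooled for multiple-testing control:

1. scan fixed non-overlapping 100-bp tiles for >= ``min_diff_sites``
   cytosines whose methylation level differs between samples;
2. compare per-site levels across samples within each candidate tile with a
   Kruskal-Wallis test;
3. join neighbouring candidate tiles within ``join_gap`` bp, combining
   their p-values with Fisher's method;
4. Benjamini-Hochberg across all joined regions from all contexts; retain
   adjusted p < ``max_adj_p``;
5. require a >= ``min_fold`` spread in methylation density (coverage-
   weighted Sum(mc)/Sum(cov) over cytosines of all three contexts in the
   region) between the least and most methylated sample.

Input is allc-style per-cytosine call tables (chrom, pos, strand, context,
mc, cov). Strands are pooled; symmetric CG positions are not merged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import TestResult, bh_adjust, fisher_combine, kruskal_wallis

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
ALLC_COLUMNS = ["chrom", "pos", "strand", "context", "mc", "cov"]


@dataclass(frozen=True)
class DMRParams:
    window: int = 100            # tile size, bp
    min_diff_sites: int = 10     # differential cytosines required per tile
    join_gap: int = 100          # max gap when consolidating tiles, bp
    max_adj_p: float = 0.01      # BH-adjusted p cutoff
    min_fold: float = 8.0        # density spread, most/least methylated sample
    min_cov: int = 3             # coverage for a site to be comparable
    site_diff_min: float = 0.1   # level difference defining a differential site

    def __post_init__(self) -> None:
        if min(self.window, self.min_diff_sites, self.join_gap, self.min_cov) <= 0:
            raise ValueError("window, min_diff_sites, join_gap and min_cov must be positive")
        if not (0 < self.max_adj_p <= 1):
            raise ValueError("max_adj_p must be in (0, 1]")
        if self.min_fold <= 0 or self.site_diff_min <= 0:
            raise ValueError("min_fold and site_diff_min must be positive")


@dataclass(frozen=True)
class CandidateWindow:
    chrom: str
    begin: int      # 0-based half-open
    end: int
    context: str
    n_sites: int


@dataclass(frozen=True)
class DMR:
    chrom: str
    begin: int
    end: int
    context: str
    n_sites: int
    fisher_p: float
    adj_p: float = math.nan
    density: dict = field(default_factory=dict, hash=False, compare=False)
    fold: float = math.nan
    passed: bool = False


def read_allc(path: str | Path) -> pd.DataFrame:
    """Read an allc-style TSV, rejecting malformed rows (count logged).

    A row is malformed when mc > cov, cov < 0, the context is not
    CG/CHG/CHH, or the strand is not +/-.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=ALLC_COLUMNS,
        dtype={"chrom": str, "strand": str, "context": str},
    )
    if df.empty:
        return df
    ok = (
        (df["mc"] >= 0)
        & (df["cov"] >= 0)
        & (df["mc"] <= df["cov"])
        & df["context"].isin(CONTEXTS)
        & df["strand"].isin(["+", "-"])
        & (df["pos"] >= 1)
    )
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: rejected %d malformed row(s)", path, n_bad)
    return df[ok].reset_index(drop=True)


def _level_matrix(
    samples: Mapping[str, pd.DataFrame], context: str
) -> tuple[pd.DataFrame, list[str]]:
    """Per-site table with mc_<s>/cov_<s> columns, inner-joined across samples."""
    names = list(samples)
    merged: pd.DataFrame | None = None
    for name in names:
        sub = samples[name]
        sub = sub[sub["context"] == context][["chrom", "pos", "strand", "mc", "cov"]]
        sub = sub.rename(columns={"mc": f"mc_{name}", "cov": f"cov_{name}"})
        merged = sub if merged is None else merged.merge(sub, on=["chrom", "pos", "strand"], how="inner")
    if merged is None:
        raise ValueError("no samples")
    return merged, names


def scan_windows(
    samples: Mapping[str, pd.DataFrame], context: str, params: DMRParams = DMRParams()
) -> list[CandidateWindow]:
    """Candidate tiles with >= ``min_diff_sites`` differential cytosines.

    A site is differential when it is covered >= ``min_cov`` in every
    sample and the spread of per-sample levels is >= ``site_diff_min``.
    Tiles are fixed ``window``-bp intervals anchored at coordinate 0.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    merged, names = _level_matrix(samples, context)
    if merged.empty:
        return []
    cov = merged[[f"cov_{n}" for n in names]].to_numpy(dtype=float)
    mc = merged[[f"mc_{n}" for n in names]].to_numpy(dtype=float)
    covered = (cov >= params.min_cov).all(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(cov > 0, mc / cov, np.nan)
    spread = np.nanmax(level, axis=1) - np.nanmin(level, axis=1)
    diff = covered & (spread >= params.site_diff_min)

    sites = merged.loc[diff, ["chrom", "pos"]].copy()
    if sites.empty:
        return []
    sites["tile"] = (sites["pos"] - 1) // params.window
    counts = sites.groupby(["chrom", "tile"]).size()
    out = [
        CandidateWindow(chrom, int(tile) * params.window, (int(tile) + 1) * params.window, context, int(n))
        for (chrom, tile), n in counts.items()
        if n >= params.min_diff_sites
    ]
    out.sort(key=lambda c: (c.chrom, c.begin))
    return out


def test_window(
    candidate: CandidateWindow,
    samples: Mapping[str, pd.DataFrame],
    params: DMRParams = DMRParams(),
) -> TestResult | None:
    """Kruskal-Wallis over per-site levels across samples within the tile.

    Each sample contributes the levels of its own covered sites (>=
    ``min_cov``) in the tile; a sample with fewer than two such sites drops
    the window (returns None, warning logged).
    """
    groups = []
    for name, df in samples.items():
        sub = df[
            (df["context"] == candidate.context)
            & (df["chrom"] == candidate.chrom)
            & (df["pos"] > candidate.begin)
            & (df["pos"] <= candidate.end)
            & (df["cov"] >= params.min_cov)
        ]
        if len(sub) < 2:
            logger.warning(
                "window %s:%d-%d dropped: sample %s has <2 covered sites",
                candidate.chrom, candidate.begin, candidate.end, name,
            )
            return None
        groups.append((sub["mc"] / sub["cov"]).to_numpy())
    return kruskal_wallis(groups)


def join_dmrs(tested: Sequence[tuple[CandidateWindow, TestResult]], params: DMRParams = DMRParams()) -> list[DMR]:
    """Transitively merge same-context windows within ``join_gap`` bp.

    The merged span runs from the first begin to the last end; member
    p-values are combined with Fisher's method (a singleton keeps its own
    p-value — the k=1 identity).
    """
    by_key: dict[tuple[str, str], list[tuple[CandidateWindow, TestResult]]] = {}
    for cand, res in tested:
        by_key.setdefault((cand.chrom, cand.context), []).append((cand, res))
    out: list[DMR] = []
    for (chrom, context), members in by_key.items():
        members.sort(key=lambda t: t[0].begin)
        cluster: list[tuple[CandidateWindow, TestResult]] = []
        for item in members:
            if cluster and item[0].begin - cluster[-1][0].end > params.join_gap:
                out.append(_merge_cluster(chrom, context, cluster))
                cluster = []
            cluster.append(item)
        if cluster:
            out.append(_merge_cluster(chrom, context, cluster))
    out.sort(key=lambda d: (d.chrom, d.begin, d.context))
    return out


def _merge_cluster(chrom: str, context: str, cluster: list[tuple[CandidateWindow, TestResult]]) -> DMR:
    begin = min(c.begin for c, _ in cluster)
    end = max(c.end for c, _ in cluster)
    n_sites = sum(c.n_sites for c, _ in cluster)
    p = fisher_combine([r.p for _, r in cluster]).p
    return DMR(chrom, begin, end, context, n_sites, p)


def methylation_density(df: pd.DataFrame, chrom: str, begin: int, end: int) -> float:
    """Coverage-weighted methylation level Sum(mc)/Sum(cov), all contexts pooled."""
    sub = df[(df["chrom"] == chrom) & (df["pos"] > begin) & (df["pos"] <= end) & (df["cov"] > 0)]
    total = sub["cov"].sum()
    return float(sub["mc"].sum() / total) if total > 0 else math.nan


def _density_fold(densities: dict) -> float:
    vals = [v for v in densities.values() if not math.isnan(v)]
    if len(vals) < 2:
        return math.nan
    lo, hi = min(vals), max(vals)
    if hi == 0:
        return math.nan
    return math.inf if lo == 0 else hi / lo


def call_dmrs(
    samples: Mapping[str, pd.DataFrame],
    params: DMRParams = DMRParams(),
    contexts: Sequence[str] = CONTEXTS,
) -> list[DMR]:
    """Full scan -> test -> join -> BH -> density-fold pipeline.

    Returns every joined region with its adjusted p-value, per-sample
    density and fold; ``passed`` marks regions meeting both the adjusted-p
    and the density-fold requirement. BH is applied once across all joined
    regions from all contexts (a single genome-wide FDR).
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    tested: list[tuple[CandidateWindow, TestResult]] = []
    for context in contexts:
        for cand in scan_windows(samples, context, params):
            res = test_window(cand, samples, params)
            if res is not None:
                tested.append((cand, res))
    joined = join_dmrs(tested, params)
    if not joined:
        return []
    adj = bh_adjust([d.fisher_p for d in joined])
    out = []
    for d, a in zip(joined, adj):
        dens = {name: methylation_density(df, d.chrom, d.begin, d.end) for name, df in samples.items()}
        fold = _density_fold(dens)
        passed = bool(a < params.max_adj_p) and (fold >= params.min_fold)
        out.append(DMR(d.chrom, d.begin, d.end, d.context, d.n_sites, d.fisher_p, float(a), dens, fold, passed))
    return out


def dmrs_to_table(dmrs: Sequence[DMR]) -> pd.DataFrame:
    """BED-like TSV-ready table with per-sample density columns."""
    sample_names = sorted({s for d in dmrs for s in d.density})
    rows = []
    for d in dmrs:
        row = {
            "chrom": d.chrom, "begin": d.begin, "end": d.end, "context": d.context,
            "n_sites": d.n_sites, "fisher_p": d.fisher_p, "adj_p": d.adj_p,
            "fold": d.fold, "passed": d.passed,
        }
        for s in sample_names:
            row[f"density_{s}"] = d.density.get(s, math.nan)
        rows.append(row)
    cols = ["chrom", "begin", "end", "context", "n_sites", "fisher_p", "adj_p"]
    cols += [f"density_{s}" for s in sample_names] + ["fold", "passed"]
    return pd.DataFrame(rows, columns=cols if rows else cols)
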
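"""Synthetic annotations, strand-specific read sets and methylomes with
planted signals, plus the truth tables needed to score recovery.

What is emulated
----------------
* a multi-gene two-strand annotation with MIR loci, miRNA targets and
  optional convergent gene pairs whose 3' ends face each other;
* per-replicate read counts with negative-binomial overdispersion; reads
  are fixed-length single-end intervals placed uniformly on the gene
  strand (quantification consumes intervals, so base-level realism is
  unnecessary);
* a planted read-through signal in the 500-nt downstream window of chosen
  genes in mutant genotypes, against a small background leakage present in
  every genotype;
* pri-miRNA 3'-remnant and miRNA-target 3'-fragment accumulation in
  mutants;
* per-cytosine methylation calls in three contexts with binomial sampling
  noise and planted differentially methylated regions.

Every output is a deterministic function of the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import GeneModel, GeneSet
from .quant import AlignmentSet
from .windows import downstream_window, target_end_windows


@dataclass
class MethylomeConfig:
    """Synthetic bisulfite-call layout; defaults approximate a plant genome."""

    chrom: str = "chr1"
    genome_len: int = 100_000
    samples: tuple[str, ...] = ("WT", "fry1")
    mean_cov: float = 20.0
    site_spacing: dict = field(default_factory=lambda: {"CG": 20, "CHG": 15, "CHH": 8})
    background_level: dict = field(default_factory=lambda: {"CG": 0.30, "CHG": 0.10, "CHH": 0.05})
    n_dmrs: int = 20
    dmr_len: int = 200
    dmr_sites: int = 24
    dmr_levels: tuple[float, ...] = (0.9, 0.05)   # one level per sample
    dmr_context: str = "CG"


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment."""

    seed: int = 0
    n_genes: int = 200
    chrom: str = "chr1"
    gene_len_range: tuple[int, int] = (800, 3000)
    spacing: int = 1000              # minimum intergenic gap, bp
    spacing_jitter: int = 1000
    frac_minus_strand: float = 0.5
    n_mir_loci: int = 8
    n_targets: int = 10
    convergent_pairs: int = 0        # opposite-strand pairs with facing 3' ends
    genotypes: dict = field(default_factory=lambda: {"WT": 3, "fry1": 3})
    wt_genotype: str = "WT"
    depth: int = 5_000_000           # nominal uniquely-mapped reads per library
    read_length: int = 42
    nb_dispersion: float = 0.1
    expression_log_mean: float = 2.0   # ln-RPKM of gene bodies (lognormal)
    expression_log_sigma: float = 1.0
    n_extensions: int = 40
    extension_rpkm: float = 8.0      # planted mutant downstream-window RPKM
    leakage_rpkm: float = 0.05       # background downstream RPKM, all genotypes
    mir_remnant_rpkm: float = 4.0    # planted mutant pri-miRNA remnant RPKM
    target_tail_rpkm: float = 5.0    # planted mutant 3'-fragment RPKM on targets
    downstream_length: int = 500
    methylome: MethylomeConfig = field(default_factory=MethylomeConfig)

    @property
    def mutant_genotypes(self) -> list[str]:
        return [g for g in self.genotypes if g != self.wt_genotype]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        raw = json.loads(Path(path).read_text())
        m = raw.pop("methylome", {})
        for key in ("dmr_levels", "samples"):
            if key in m:
                m[key] = tuple(m[key])
        for key in ("gene_len_range",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(methylome=MethylomeConfig(**m), **raw)


@dataclass
class TruthTable:
    """Planted signals, keyed the way the callers report them."""

    expression: dict                      # gene_id -> body RPKM
    extensions: dict                      # genotype -> {gene_id -> planted RPKM}
    dmrs: pd.DataFrame                    # chrom, begin, end, context, n_sites, level_<sample>...

    def planted_genes(self, genotype: str) -> set[str]:
        return set(self.extensions.get(genotype, {}))


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(cfg: SimConfig, rng: np.random.Generator) -> GeneSet:
    """Lay genes along one chromosome with at least ``spacing`` bp between them.

    The first ``2*convergent_pairs`` genes are arranged as +/- pairs whose
    3' ends face each other closer than ``downstream_length``, so their
    downstream windows mutually overlap and each overlaps the partner gene.
    """
    lo, hi = cfg.gene_len_range
    genes: list[GeneModel] = []
    cursor = 2000  # 0-based cursor
    idx = 0

    def next_gene(strand: str, length: int, gap_after: int) -> GeneModel:
        nonlocal cursor, idx
        idx += 1
        g = GeneModel(f"g{idx:04d}", cfg.chrom, strand, cursor + 1, cursor + length)
        cursor += length + gap_after
        return g

    for _ in range(cfg.convergent_pairs):
        gap = int(rng.integers(50, min(450, cfg.downstream_length - 50)))
        genes.append(next_gene("+", int(rng.integers(lo, hi + 1)), gap))
        genes.append(
            next_gene("-", int(rng.integers(lo, hi + 1)), cfg.spacing + int(rng.integers(0, cfg.spacing_jitter + 1)))
        )
    while idx < cfg.n_genes:
        strand = "-" if rng.random() < cfg.frac_minus_strand else "+"
        gap = cfg.spacing + int(rng.integers(0, cfg.spacing_jitter + 1))
        genes.append(next_gene(strand, int(rng.integers(lo, hi + 1)), gap))

    chrom_len = cursor + 2000
    # MIR loci and miRNA targets: disjoint draws outside the convergent pairs
    pool = np.arange(2 * cfg.convergent_pairs, len(genes))
    if cfg.n_mir_loci + cfg.n_targets > pool.size:
        raise ValueError("not enough genes for the requested MIR loci and targets")
    special = rng.choice(pool, size=cfg.n_mir_loci + cfg.n_targets, replace=False)
    mir_idx = set(special[: cfg.n_mir_loci].tolist())
    target_idx = set(special[cfg.n_mir_loci:].tolist())
    final = [
        dataclasses.replace(
            g,
            kind="mir" if i in mir_idx else g.kind,
            is_mirna_target=i in target_idx,
        )
        for i, g in enumerate(genes)
    ]
    return GeneSet(genes=final, chrom_lengths={cfg.chrom: chrom_len})


def write_gff(genes: GeneSet, path: str | Path) -> None:
    """GFF3 with ##sequence-region pragmas; round-trips through read_annotation."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in sorted(genes.chrom_lengths.items()):
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in genes:
            ftype = "miRNA_primary_transcript" if g.kind == "mir" else "gene"
            fh.write(
                f"{g.chrom}\tsim\t{ftype}\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.id}\n"
            )


# ---------------------------------------------------------------------------
# alignments


def _nb_draw(rng: np.random.Generator, mu: float, dispersion: float) -> int:
    """Negative-binomial count with mean mu and variance mu + dispersion*mu^2."""
    if mu <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mu))
    n = 1.0 / dispersion
    return int(rng.negative_binomial(n, n / (n + mu)))


def make_extension_truth(cfg: SimConfig, genes: GeneSet, rng: np.random.Generator) -> TruthTable:
    """Draw per-gene expression and the per-mutant planted extension sets."""
    expression = {g.id: float(rng.lognormal(cfg.expression_log_mean, cfg.expression_log_sigma)) for g in genes}
    eligible = [g.id for g in genes if g.kind == "coding"]
    if cfg.n_extensions > len(eligible):
        raise ValueError("more planted extensions requested than eligible genes")
    extensions = {}
    for genotype in cfg.mutant_genotypes:
        chosen = rng.choice(np.array(eligible), size=cfg.n_extensions, replace=False)
        extensions[genotype] = {gid: cfg.extension_rpkm for gid in chosen.tolist()}
    return TruthTable(expression=expression, extensions=extensions, dmrs=pd.DataFrame())


def _uniform_reads(
    rng: np.random.Generator, begin: int, end: int, n: int, read_length: int
) -> np.ndarray:
    """Read start positions uniform in a window, reads kept inside [begin, end)."""
    hi = max(begin + 1, end - read_length)
    return rng.integers(begin, hi, size=n)


def simulate_alignments(
    cfg: SimConfig, genes: GeneSet, truth: TruthTable, rng: np.random.Generator
) -> list[AlignmentSet]:
    """One AlignmentSet per genotype x replicate.

    Expected counts are RPKM-denominated against the nominal library depth:
    a window of length L at RPKM r contributes NB-distributed counts with
    mean r * (L/1000) * (depth/1e6). Stored intervals cover only annotated
    loci and their downstream windows; ``total_mapped`` is the nominal
    genome-wide depth.
    """
    rl = cfg.read_length
    libraries: list[AlignmentSet] = []
    scale = (cfg.depth / 1e6) / 1000.0  # rpkm * length * scale = expected count
    for genotype, n_reps in cfg.genotypes.items():
        is_mut = genotype != cfg.wt_genotype
        planted = truth.extensions.get(genotype, {})
        for rep in range(1, n_reps + 1):
            starts: list[np.ndarray] = []
            strands: list[np.ndarray] = []
            for g in genes:
                clen = genes.chrom_length(g.chrom)
                parts: list[tuple[int, int, float]] = [
                    (g.begin0, g.end0, truth.expression[g.id])
                ]
                w = downstream_window(g, cfg.downstream_length, clen)
                if w.is_testable:
                    if g.id in planted:
                        down_rpkm = planted[g.id]
                    elif g.kind == "mir" and is_mut:
                        down_rpkm = cfg.mir_remnant_rpkm
                    else:
                        down_rpkm = cfg.leakage_rpkm
                    parts.append((w.begin, w.end, down_rpkm))
                if g.is_mirna_target and is_mut:
                    _, tail = target_end_windows(g, 200)
                    parts.append((tail.begin, tail.end, cfg.target_tail_rpkm))
                for begin, end, rpkm_val in parts:
                    n = _nb_draw(rng, rpkm_val * (end - begin) * scale, cfg.nb_dispersion)
                    if n:
                        starts.append(_uniform_reads(rng, begin, end, n, rl))
                        strands.append(np.repeat(g.strand, n))
            s = np.concatenate(starts) if starts else np.empty(0, dtype=int)
            intervals = pd.DataFrame(
                {
                    "chrom": cfg.chrom,
                    "begin": s,
                    "end": s + rl,
                    "strand": np.concatenate(strands) if strands else np.empty(0, dtype="U1"),
                }
            )
            libraries.append(
                AlignmentSet(f"{genotype}_rep{rep}", genotype, rep, intervals, cfg.depth)
            )
    return libraries


def write_alignments(libraries: list[AlignmentSet], outdir: str | Path) -> Path:
    """BED6 per library plus a manifest TSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for lib in libraries:
        bed = outdir / f"{lib.library_id}.bed"
        df = lib.intervals.copy()
        df["name"] = "read"
        df["score"] = 0
        df[["chrom", "begin", "end", "name", "score", "strand"]].to_csv(
            bed, sep="\t", header=False, index=False
        )
        rows.append((lib.library_id, lib.genotype, lib.replicate, bed.name, lib.total_mapped))
    manifest = outdir / "libraries.tsv"
    pd.DataFrame(rows, columns=["library_id", "genotype", "replicate", "path", "total_mapped"]).to_csv(
        manifest, sep="\t", index=False
    )
    return manifest


# ---------------------------------------------------------------------------
# methylome


def simulate_methylome(
    mcfg: MethylomeConfig, rng: np.random.Generator
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-sample allc tables plus the planted-DMR truth table.

    Background cytosines sit at jittered regular spacing per context with
    the same level in every sample. A planted region carries ``dmr_sites``
    extra cytosines of ``dmr_context``, and every cytosine inside it —
    whatever its context — methylates at the per-sample ``dmr_levels``, so
    the region's combined-context density truly differs between samples.
    One region is placed uniformly inside each of ``n_dmrs`` equal genome
    segments, so regions never overlap and their phase relative to the
    caller's tiling is uniform. Coverage is Poisson(mean_cov); mc is
    Binomial(cov, level).
    """
    if len(mcfg.dmr_levels) != len(mcfg.samples):
        raise ValueError("need one planted DMR level per sample")
    L = mcfg.genome_len

    # planted regions, one per genome segment
    regions = []
    if mcfg.n_dmrs:
        seg = L // mcfg.n_dmrs
        if seg <= mcfg.dmr_len + 200:
            raise ValueError("genome too small for the requested planted DMRs")
        for i in range(mcfg.n_dmrs):
            start = i * seg + int(rng.integers(100, seg - mcfg.dmr_len - 100))
            regions.append((start, start + mcfg.dmr_len))

    def in_region(p1: int) -> bool:
        return any(b < p1 <= e for b, e in regions)

    site_rows = []  # (pos, strand, context, level_per_sample tuple or None for background)
    for ctx, spacing in mcfg.site_spacing.items():
        base = np.arange(spacing, L - spacing, spacing)
        jitter = rng.integers(0, max(1, spacing // 2), size=base.size)
        pos = np.unique(base + jitter)
        if ctx == mcfg.dmr_context:
            # planted sites replace background sites of the same context
            for b, e in regions:
                pos = pos[(pos <= b) | (pos > e)]
        strand = rng.choice(np.array(["+", "-"]), size=pos.size)
        lvl = mcfg.background_level[ctx]
        for p, s in zip(pos.tolist(), strand.tolist()):
            planted = tuple(mcfg.dmr_levels) if in_region(p + 1) else None
            site_rows.append((p + 1, s, ctx, planted, lvl))
    truth_rows = []
    for b, e in regions:
        pos = np.sort(rng.choice(np.arange(b + 1, e + 1), size=mcfg.dmr_sites, replace=False))
        strand = rng.choice(np.array(["+", "-"]), size=pos.size)
        for p, s in zip(pos.tolist(), strand.tolist()):
            site_rows.append((int(p), s, mcfg.dmr_context, tuple(mcfg.dmr_levels), None))
        truth_rows.append((mcfg.chrom, b, e, mcfg.dmr_context, mcfg.dmr_sites, *mcfg.dmr_levels))

    site_rows.sort(key=lambda r: r[0])
    n = len(site_rows)
    samples: dict[str, pd.DataFrame] = {}
    for i, name in enumerate(mcfg.samples):
        levels = np.array([r[3][i] if r[3] is not None else r[4] for r in site_rows])
        cov = rng.poisson(mcfg.mean_cov, size=n)
        mc = rng.binomial(cov, levels)
        samples[name] = pd.DataFrame(
            {
                "chrom": mcfg.chrom,
                "pos": [r[0] for r in site_rows],
                "strand": [r[1] for r in site_rows],
                "context": [r[2] for r in site_rows],
                "mc": mc,
                "cov": cov,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "begin", "end", "context", "n_sites", *[f"level_{s}" for s in mcfg.samples]],
    )
    return samples, truth


def write_methylome(samples: Mapping[str, pd.DataFrame], outdir: str | Path) -> Path:
    """allc TSV per sample plus a sample manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, df in samples.items():
        p = outdir / f"allc_{name}.tsv"
        df.to_csv(p, sep="\t", header=False, index=False)
        rows.append((name, p.name))
    manifest = outdir / "methylomes.tsv"
    pd.DataFrame(rows, columns=["sample_id", "path"]).to_csv(manifest, sep="\t", index=False)
    return manifest


# ---------------------------------------------------------------------------
# one-call convenience


def simulate_all(cfg: SimConfig, outdir: str | Path) -> dict:
    """Generate and write every synthetic input; returns in-memory objects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genes = simulate_annotation(cfg, rng)
    truth = make_extension_truth(cfg, genes, rng)
    libraries = simulate_alignments(cfg, genes, truth, rng)
    mcfg = cfg.methylome
    if mcfg.chrom == cfg.chrom:
        mcfg = dataclasses.replace(mcfg, genome_len=genes.chrom_length(cfg.chrom))
    methylomes, dmr_truth = simulate_methylome(mcfg, rng)
    truth = dataclasses.replace(truth, dmrs=dmr_truth)

    write_gff(genes, outdir / "genes.gff3")
    (outdir / "mir_ids.txt").write_text("".join(f"{g.id}\n" for g in genes.mir_loci()))
    (outdir / "target_ids.txt").write_text("".join(f"{g.id}\n" for g in genes.mirna_targets()))
    manifest = write_alignments(libraries, outdir / "reads")
    meth_manifest = write_methylome(methylomes, outdir / "methylome")
    ext_rows = [
        (genotype, gid, rpkm_val)
        for genotype, d in truth.extensions.items()
        for gid, rpkm_val in sorted(d.items())
    ]
    pd.DataFrame(ext_rows, columns=["genotype", "gene_id", "planted_rpkm"]).to_csv(
        outdir / "extension_truth.tsv", sep="\t", index=False
    )
    dmr_truth.to_csv(outdir / "dmr_truth.tsv", sep="\t", index=False)
    cfg.to_json(outdir / "sim_config.json")
    return {
        "genes": genes,
        "truth": truth,
        "libraries": libraries,
        "methylomes": methylomes,
        "read_manifest": manifest,
        "methylome_manifest": meth_manifest,
    }
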
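"""End-to-end orchestration: simulate -> quantify -> call -> integrate -> report.

``run_all`` executes every stage on a synthetic experiment and writes a
machine-readable report carrying the same summary quantities the analysis
produces on real data: candidate and raw extension counts per mutant,
pairwise candidate overlaps, expressed pri-miRNA counts and category
histograms, DMR counts, and the strand-aware overlap summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

from . import __version__
from .dmr import DMRParams, call_dmrs, dmrs_to_table
from .extensions import (
    DEFAULT_PARAMS,
    RELAXED_PARAMS,
    call_extensions,
    calls_to_table,
    candidate_overlap,
    passed_ids,
    raw_extension_count,
)
from .overlap import (
    antisense_overlaps,
    antisense_span_count,
    dmr_extension_overlap,
    mutual_extension_overlaps,
    spans_from_calls,
)
from .quant import quantify, write_quant_table
from .remnants import (
    category_histogram,
    expressed_count,
    profiles_to_table,
    quantify_primirnas,
    quantify_target_ends,
)
from .simulate import SimConfig, simulate_all
from .windows import build_windows, write_bed6

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is the first argument."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, str(exc)) from exc
        return wrapped
    return deco


def run_all(
    cfg: SimConfig,
    outdir: str | Path,
    dmr_params: DMRParams = DMRParams(),
) -> dict:
    """Run every stage on a synthetic experiment; returns the report dict.

    Writes, under ``outdir``: the simulated inputs, the quantification
    table, per-genotype call tables and candidate BEDs, remnant and DMR
    tables, overlap pair tables, ``report.json`` and ``manifest.json``.
    The run is a pure function of the config (seed included).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def emit(name: str, path: Path) -> Path:
        outputs[name] = str(path.relative_to(outdir))
        return path

    sim = _stage("simulate")(simulate_all)(cfg, outdir / "sim")
    genes, truth, libraries = sim["genes"], sim["truth"], sim["libraries"]
    for name in ("genes.gff3", "mir_ids.txt", "target_ids.txt", "extension_truth.tsv", "dmr_truth.tsv"):
        emit(name, outdir / "sim" / name)

    windows = build_windows(genes, cfg.downstream_length)
    quant = _stage("quantify")(quantify)(windows, libraries)
    write_quant_table(quant, emit("quant.tsv", outdir / "quant.tsv"))

    wt = cfg.wt_genotype
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "n_genes": len(genes),
        "genotypes": dict(cfg.genotypes),
        "extensions": {},
        "venn": {},
    }
    calls_by_genotype = {}
    for mut in cfg.mutant_genotypes:
        calls = _stage("call-extensions")(call_extensions)(quant, wt, mut, genes, DEFAULT_PARAMS, cfg.downstream_length)
        relaxed_calls = call_extensions(quant, wt, mut, genes, RELAXED_PARAMS, cfg.downstream_length)
        calls_by_genotype[mut] = calls
        table = calls_to_table(calls)
        table.to_csv(emit(f"calls_{mut}.tsv", outdir / f"calls_{mut}.tsv"), sep="\t", index=False)
        spans = spans_from_calls(calls, genes, cfg.downstream_length)
        write_bed6(
            [w for w in build_windows(genes, cfg.downstream_length) if w.role == "downstream500" and w.gene_id in passed_ids(calls)],
            emit(f"candidates_{mut}.bed", outdir / f"candidates_{mut}.bed"),
        )
        report["extensions"][mut] = {
            "candidates": len(passed_ids(calls)),
            "candidates_relaxed": len(passed_ids(relaxed_calls)),
            "raw": raw_extension_count(quant, mut),
            "raw_new_only": raw_extension_count(quant, mut, wt=wt),
        }
        del spans

    muts = cfg.mutant_genotypes
    for i, a in enumerate(muts):
        for b in muts[i + 1:]:
            shared, fa, fb = candidate_overlap(calls_by_genotype[a], calls_by_genotype[b])
            report["venn"][f"{a}|{b}"] = {"shared": shared, f"frac_{a}": fa, f"frac_{b}": fb}

    first_mut = muts[0]
    profiles = _stage("remnants")(quantify_primirnas)(quant, wt, first_mut)
    profiles_to_table(profiles).to_csv(emit("primirna.tsv", outdir / "primirna.tsv"), sep="\t", index=False)
    category_histogram(profiles).to_csv(emit("primirna_hist.tsv", outdir / "primirna_hist.tsv"), sep="\t", index=False)
    target_pairs = quantify_target_ends(quant, wt, first_mut)
    profiles_to_table([p for pair in target_pairs for p in pair]).to_csv(
        emit("target_ends.tsv", outdir / "target_ends.tsv"), sep="\t", index=False
    )
    report["primirna"] = {
        "n_loci": len(profiles),
        "expressed": expressed_count(profiles),
        "genotype": first_mut,
    }
    report["targets"] = {"n_pairs": len(target_pairs)}

    dmrs = _stage("call-dmrs")(call_dmrs)(sim["methylomes"], dmr_params)
    dmrs_to_table(dmrs).to_csv(emit("dmrs.tsv", outdir / "dmrs.tsv"), sep="\t", index=False)
    passed_dmrs = [d for d in dmrs if d.passed]
    report["dmrs"] = {"joined": len(dmrs), "passed": len(passed_dmrs)}

    spans = spans_from_calls(calls_by_genotype[first_mut], genes, cfg.downstream_length)
    anti = _stage("overlap")(antisense_overlaps)(spans, genes)
    mutual = mutual_extension_overlaps(spans)
    dmr_ext = dmr_extension_overlap(passed_dmrs, spans)
    report["overlaps"] = {
        "antisense_pairs": len(anti),
        "antisense_spans": antisense_span_count(anti),
        "mutual_pairs": len(mutual),
        "dmr_extension_pairs": len(dmr_ext),
    }
    with open(emit("overlap_pairs.json", outdir / "overlap_pairs.json"), "w") as fh:
        json.dump(
            {"antisense": anti, "mutual": mutual, "dmr_extension": dmr_ext},
            fh, indent=2, sort_keys=True,
        )

    with open(emit("report.json", outdir / "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "dmr_params": dataclasses.asdict(dmr_params),
        "outputs": outputs,
    }
    missing = [p for p in outputs.values() if not (outdir / p).exists()]
    if missing:
        raise StageError("manifest", f"missing outputs: {missing}")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
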
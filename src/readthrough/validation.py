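"""Planted-signal recovery metrics on synthetic experiments.

These routines run the full generate -> quantify -> call chain under the
package's standard synthetic study conditions and score the calls against
the generator's truth tables: sensitivity and false-discovery fraction of
the extension caller, the null call rate, and recovery/null behaviour of
the DMR caller. They back both the test suite and the reproduction script.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .dmr import DMR, DMRParams, call_dmrs
from .extensions import DEFAULT_PARAMS, call_extensions, passed_ids
from .quant import quantify
from .simulate import (
    MethylomeConfig,
    SimConfig,
    make_extension_truth,
    simulate_alignments,
    simulate_annotation,
    simulate_methylome,
)
from .windows import build_windows


def extension_recovery(seed: int, n_extensions: int = 40, **cfg_overrides) -> dict:
    """Sensitivity and false-discovery fraction of the default filter.

    Runs the standard synthetic experiment (200 genes, planted mutant
    downstream RPKM 8 against wild-type leakage 0.05, 3 replicates per
    genotype, NB dispersion 0.1) and scores passed calls against the
    planted truth. With ``n_extensions=0`` the same run measures the null
    call rate.
    """
    cfg = SimConfig(seed=seed, n_extensions=n_extensions, **cfg_overrides)
    rng = np.random.default_rng(cfg.seed)
    genes = simulate_annotation(cfg, rng)
    truth = make_extension_truth(cfg, genes, rng)
    libraries = simulate_alignments(cfg, genes, truth, rng)
    quant = quantify(build_windows(genes, cfg.downstream_length), libraries)
    mut = cfg.mutant_genotypes[0]
    calls = call_extensions(quant, cfg.wt_genotype, mut, genes, DEFAULT_PARAMS, cfg.downstream_length)
    passed = passed_ids(calls)
    planted = truth.planted_genes(mut)
    true_pos = len(passed & planted)
    return {
        "n_genes": len(genes),
        "n_planted": len(planted),
        "n_passed": len(passed),
        "true_positives": true_pos,
        "sensitivity": true_pos / len(planted) if planted else float("nan"),
        "false_discovery_fraction": (len(passed) - true_pos) / len(passed) if passed else 0.0,
        "null_call_fraction": len(passed) / len(genes),
    }


def _overlaps_region(d: DMR, begin: int, end: int) -> bool:
    return d.begin < end and begin < d.end


def dmr_recovery(seed: int, params: DMRParams = DMRParams(), **mcfg_overrides) -> dict:
    """Recovery of planted DMRs (0.9 vs 0.05, 24 CG sites over 200 bp,
    coverage ~Poisson(20)) and whether every passed call hits a plant."""
    mcfg = MethylomeConfig(**mcfg_overrides)
    samples, truth = simulate_methylome(mcfg, np.random.default_rng(seed))
    passed = [d for d in call_dmrs(samples, params) if d.passed]
    recovered = sum(
        1
        for r in truth.itertuples()
        if any(_overlaps_region(d, r.begin, r.end) for d in passed)
    )
    stray = [
        d for d in passed
        if not any(_overlaps_region(d, r.begin, r.end) for r in truth.itertuples())
    ]
    return {
        "n_planted": len(truth),
        "n_passed": len(passed),
        "recovered": recovered,
        "sensitivity": recovered / len(truth) if len(truth) else float("nan"),
        "all_passed_overlap_planted": not stray,
        "n_stray": len(stray),
    }


def dmr_null_zero_fraction(
    seed: int,
    n_runs: int = 200,
    genome_len: int = 50_000,
    params: DMRParams = DMRParams(),
) -> dict:
    """Fraction of null simulations (identical level distributions,
    binomial noise only) yielding zero passed DMRs."""
    base = MethylomeConfig(n_dmrs=0, genome_len=genome_len)
    root = np.random.default_rng(seed)
    zero = 0
    for _ in range(n_runs):
        samples, _ = simulate_methylome(base, np.random.default_rng(int(root.integers(2**31))))
        if not any(d.passed for d in call_dmrs(samples, params)):
            zero += 1
    return {"n_runs": n_runs, "zero_fraction": zero / n_runs}
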
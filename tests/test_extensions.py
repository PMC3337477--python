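"""The four-parameter extension filter: composition, traces, monotonicity."""

import math

import numpy as np
import pandas as pd
import pytest

from readthrough.annotation import GeneModel, GeneSet
from readthrough.extensions import (
    DEFAULT_PARAMS,
    RELAXED_PARAMS,
    ExtensionCall,
    ExtensionFilterParams,
    call_extensions,
    candidate_overlap,
    passed_ids,
    raw_extension_count,
)


def quant_from_rpkm(per_gene):
    """per_gene: {gene_id: {genotype: [rpkm per replicate]}} -> quant table."""
    rows = []
    for gid, by_geno in per_gene.items():
        for geno, reps in by_geno.items():
            for i, v in enumerate(reps, 1):
                rows.append((gid, "downstream500", geno, i, int(round(v * 10)), v))
    return pd.DataFrame(rows, columns=["gene_id", "role", "genotype", "replicate", "count", "rpkm"])


@pytest.fixture
def genes():
    return GeneSet(
        [
            GeneModel("g1", "chr1", "+", 1001, 2000),
            GeneModel("g2", "chr1", "+", 5001, 6000),
            # g3's downstream window (9001..9500 1-based) overlaps the MIR locus
            GeneModel("g3", "chr1", "+", 8001, 9000),
            GeneModel("mirA", "chr1", "-", 9301, 9600, kind="mir"),
        ],
        {"chr1": 20000},
    )


class TestCallExtensions:
    def test_planted_like_gene_passes(self, genes):
        q = quant_from_rpkm({"g1": {"WT": [1.0, 0.9, 1.1], "fry1": [6, 5, 7]}})
        (call,) = call_extensions(q, "WT", "fry1", genes)
        assert call.passed
        assert call.fold == pytest.approx(6.0)
        assert call.p < 0.1
        assert all(v for v in call.filter_trace.values() if v is not None)

    def test_identical_genotypes_fail_on_fold(self, genes):
        q = quant_from_rpkm({"g1": {"WT": [6, 5, 7], "fry1": [6, 5, 7]}})
        (call,) = call_extensions(q, "WT", "fry1", genes)
        assert not call.passed and call.fold == pytest.approx(1.0)
        assert call.filter_trace["fold"] is False

    def test_mir_overlap_fails_non_pri_mirna(self, genes):
        q = quant_from_rpkm(
            {
                "g3": {"WT": [0.1, 0.1, 0.1], "fry1": [6, 5, 7]},
                "mirA": {"WT": [0.1, 0.1, 0.1], "fry1": [6, 5, 7]},
            }
        )
        calls = {c.gene_id: c for c in call_extensions(q, "WT", "fry1", genes)}
        assert not calls["g3"].passed and calls["g3"].filter_trace["non_pri_mirna"] is False
        assert not calls["mirA"].passed and calls["mirA"].filter_trace["non_pri_mirna"] is False

    def test_strict_inequality_at_fold_five(self, genes):
        q = quant_from_rpkm({"g1": {"WT": [1.0, 1.0], "fry1": [5.0, 5.0]}})
        (call,) = call_extensions(q, "WT", "fry1", genes)
        assert call.fold == pytest.approx(5.0) and not call.passed

    def test_infinite_fold_when_wt_silent(self, genes):
        q = quant_from_rpkm({"g1": {"WT": [0, 0, 0], "fry1": [6, 5, 7]}})
        (call,) = call_extensions(q, "WT", "fry1", genes)
        assert math.isinf(call.fold) and call.passed

    def test_both_zero_fails(self, genes):
        q = quant_from_rpkm({"g1": {"WT": [0, 0], "fry1": [0, 0]}})
        (call,) = call_extensions(q, "WT", "fry1", genes)
        assert not call.passed and math.isnan(call.fold)

    def test_single_replicate_skips_p_filter(self, genes, caplog):
        q = quant_from_rpkm({"g1": {"WT": [1.0], "fry1": [6.0]}})
        with caplog.at_level("WARNING"):
            (call,) = call_extensions(q, "WT", "fry1", genes)
        assert call.passed and call.filter_trace["p"] is None
        assert "p filter skipped" in caplog.text

    def test_missing_genotype_errors(self, genes):
        q = quant_from_rpkm({"g1": {"WT": [1, 1, 1]}})
        with pytest.raises(ValueError, match="absent"):
            call_extensions(q, "WT", "fry1", genes)


def random_quant(rng, genes, n=30):
    per_gene = {}
    for i in range(n):
        gid = f"g{i:03d}"
        per_gene[gid] = {
            "WT": list(rng.lognormal(-1, 1.5, size=3)),
            "fry1": list(rng.lognormal(0, 2, size=3)),
        }
    return quant_from_rpkm(per_gene)


def _no_mir_genes(n=30):
    return GeneSet(
        [GeneModel(f"g{i:03d}", "chr1", "+", 10000 * i + 1, 10000 * i + 2000) for i in range(n)],
        {"chr1": 10000 * n + 10000},
    )


class TestFilterMonotonicity:
    def test_stricter_params_give_subset(self, rng):
        genes = _no_mir_genes()
        for _ in range(10):
            q = random_quant(rng, genes)
            strict = passed_ids(call_extensions(q, "WT", "fry1", genes, DEFAULT_PARAMS))
            higher_fold = passed_ids(
                call_extensions(q, "WT", "fry1", genes, ExtensionFilterParams(min_fold=10.0))
            )
            lower_p = passed_ids(
                call_extensions(q, "WT", "fry1", genes, ExtensionFilterParams(max_p=0.01))
            )
            assert higher_fold <= strict and lower_p <= strict

    def test_relaxed_preset_is_superset(self, rng):
        genes = _no_mir_genes()
        for _ in range(10):
            q = random_quant(rng, genes)
            strict = passed_ids(call_extensions(q, "WT", "fry1", genes, DEFAULT_PARAMS))
            relaxed = passed_ids(call_extensions(q, "WT", "fry1", genes, RELAXED_PARAMS))
            assert strict <= relaxed


class TestRawCount:
    def test_definition(self):
        q = quant_from_rpkm(
            {
                "a": {"fry1": [0, 0], "WT": [0, 0]},
                "b": {"fry1": [0.4, 0.4], "WT": [0, 0]},
                "c": {"fry1": [2.2, 2.2], "WT": [1.0, 1.0]},
            }
        )
        assert raw_extension_count(q, "fry1") == 2
        # "new transcript" reading additionally requires silent wild type
        assert raw_extension_count(q, "fry1", wt="WT") == 1

    def test_all_zero(self):
        q = quant_from_rpkm({"a": {"fry1": [0, 0]}})
        assert raw_extension_count(q, "fry1") == 0

    def test_equals_positive_count_oracle(self, rng):
        genes = _no_mir_genes()
        q = random_quant(rng, genes)
        oracle = q[(q.genotype == "fry1")].groupby("gene_id")["rpkm"].mean().gt(0).sum()
        assert raw_extension_count(q, "fry1") == oracle


class TestCandidateOverlap:
    def _calls(self, ids):
        return [ExtensionCall(i, 0, 0, 10, 0.01, True) for i in ids]

    def test_basic_set_arithmetic(self):
        shared, fa, fb = candidate_overlap(self._calls("abc"), self._calls("bcd"))
        assert (shared, fa, fb) == (2, pytest.approx(2 / 3), pytest.approx(2 / 3))

    def test_disjoint(self):
        assert candidate_overlap(self._calls("ab"), self._calls("cd")) == (0, 0, 0)

    def test_containment(self):
        shared, fa, fb = candidate_overlap(self._calls("ab"), self._calls("abcd"))
        assert fa == 1.0 and shared == 2

    def test_empty_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            assert candidate_overlap([], self._calls("ab")) == (0, 0, 0)
        assert "empty" in caplog.text
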
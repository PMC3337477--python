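# Methods

`readthrough` implements a genome-wide screen for transcripts that escape
3′ surveillance: polymerase-II read-through products downstream of
annotated gene 3′ ends (as seen when 5′→3′ exoribonuclease activity is
lost, e.g. in *Arabidopsis* *xrn* mutants or in *fry1*, where accumulated
PAP inhibits the XRNs), pri-miRNA 3′ remnants left after hairpin excision,
3′ cleavage fragments of miRNA targets, and — as a companion epigenomic
read-out — differentially methylated regions (DMRs) between methylomes.

## Window geometry

All internal coordinates are 0-based half-open; GFF3/GTF input (1-based
inclusive) and BED output are converted only at the I/O boundary, which
removes off-by-one drift between modules.

* **Downstream window** (default 500 nt): immediately 3′ of the annotated
  transcript-unit terminus, on the gene's own strand. The gene's single
  annotated span defines the 3′ end; isoform-level ends are not resolved.
  Windows are truncated (and flagged) at chromosome edges; zero-length
  windows are excluded as untestable. Overlapping annotations each keep
  their own window — no deduplication. The 500-nt default reflects that
  most observed read-through products are shorter than ~800 nt.
* **pri-miRNA window**: the annotated MIR span extended 500 nt past its 3′
  end. Annotated MIR gene models typically stop at the hairpin, so the 3′
  remnant falls outside the span; the pad captures it.
* **Target head/tail windows** (default 200 nt): the first and last
  stretch of a miRNA-target transcript in transcription order, clipped to
  the gene span. Comparing head vs tail separates uncleaved mRNA signal
  from the accumulating 3′ cleavage fragment.

## Quantification

A read counts toward a window when ≥1 bp of its interval overlaps it and
(by default) it lies on the window's strand; read-through products are
continuations on the gene's strand, so same-strand counting is the
default. Any-overlap (rather than fully-contained or 5′-end-in-window)
was chosen as the simplest deterministic rule; the oracle tests pin its
behaviour exactly. Abundance is RPKM = count / (window kb × million
uniquely mapped reads), with the denominator the library-wide total, and
the four-category binning (≤0.2, (0.2,1], (1,10], >10) is used for
profile summaries. The BAM adapter counts a spliced read if any aligned
block overlaps the window.

## Extension calling

Per gene, fold change and means are computed on per-replicate downstream
RPKM (not raw counts), and the p-value is a two-sided pooled-variance
Student t-test on the same per-replicate values — the literal reading of
"Student t-test"; Welch and one-sided variants are deliberately not the
default. Filters (all strict inequalities):

* fold (mutant mean / wild-type mean) > 5 — with a silent wild type the
  fold is +∞ and passes any finite threshold (no pseudocount; these are
  exactly the "new transcript" cases), and both-zero genes fail;
* mutant mean RPKM > 1;
* t-test p < 0.1 — skipped, with a warning, when either genotype has
  fewer than two replicates;
* non-pri-miRNA: the gene is not a MIR locus and its downstream window
  does not overlap one on either strand (this filter exists to keep
  hairpin-remnant signal out of the read-through list).

The relaxed preset (fold > 2, no p filter) always yields a superset of
the default preset's calls; this monotonicity is tested. The "raw" count
is the number of genes with any mutant downstream signal (mean RPKM > 0);
a stricter "new only" reading (mutant > 0 and wild type = 0) is exposed
as an option. Zero-variance replicate groups receive degenerate p ∈ {0,1}
rather than NaN so the filter pipeline stays total.

## DMR calling

Per context (CG, CHG, CHH): fixed non-overlapping 100-bp tiles anchored
at coordinate 0 are scanned for ≥10 differential cytosines; a cytosine is
differential when covered ≥3× in every sample and its per-sample level
spread is ≥0.1 (the per-site "difference" definition is not fully
specified in the field's tooling, so both knobs are exposed parameters).
Candidate tiles are tested with a Kruskal–Wallis test over per-site
levels across samples (chi-square approximation; an exact-permutation
mode exists for tiny inputs), joined when within 100 bp of each other
(Fisher's method combines member p-values; tiling rather than sliding
windows is recovered by this joining step), and Benjamini–Hochberg
adjusted once across all joined regions from all contexts pooled — a
single genome-wide FDR. Regions pass at adjusted p < 0.01 **and** an
8-fold spread in methylation density — coverage-weighted Σmc/Σcov over
cytosines of all three contexts in the region — between the least and
most methylated sample (min density 0 with positive max gives fold +∞).
Strands are pooled; symmetric CG pairs are not merged.

## Overlap integration

Extension spans are the (possibly truncated) downstream windows of passed
calls, taken at their postulated ~500-nt length with no coverage-based
end refinement. Three queries: opposite-strand gene overlaps (any
opposite-strand gene touching the span except its own parent; no distance
cap beyond the span), mutual overlaps between opposite-strand spans of
convergent genes, and strand-agnostic DMR∩span intersection. All use ≥1 bp
half-open overlap; the indexed implementation is tested against a
quadratic all-pairs scan and for exact strand-mirror symmetry.

## Synthetic data

The generator emulates the data shapes the analysis consumes, not
sequence content: reads are fixed-length (42 nt, a typical GAIIx cycle
count) single-end intervals with no splicing or errors.

Defaults (the standard study conditions of the test suite): 200 genes of
length U[800, 3000] with ≥1 kb spacing, half on each strand, 8 MIR loci,
10 miRNA targets; wild type and mutants with 3 replicates; nominal depth
5×10⁶ uniquely mapped reads per library; gene-body expression lognormal
(ln RPKM ~ N(2, 1)); replicate counts negative-binomial with dispersion
0.1 (the standard RNA-seq overdispersion model); planted mutant
downstream RPKM 8 against background leakage RPKM 0.05 in every genotype;
planted pri-miRNA remnant RPKM 4 and target 3′-fragment RPKM 5 in
mutants. Planted extension sets are drawn independently per mutant
genotype, so between-mutant Venn overlaps are informative. An optional
convergent-pair layout places opposite-strand genes with facing 3′ ends
closer than 500 bp to exercise the overlap queries.

Methylomes: background cytosines at jittered spacing (CG 20 bp, CHG
15 bp, CHH 8 bp) with sample-identical levels 0.30/0.10/0.05; coverage
Poisson(20); mc Binomial(cov, level). A planted DMR spans 200 bp and
carries 24 CG sites; every cytosine inside it, whatever its context,
methylates at the per-sample planted levels (0.9 vs 0.05), so the
region's combined-context density genuinely separates the samples. The
200-bp/24-site geometry guarantees ≥10 differential sites fall in one
fixed 100-bp tile regardless of the region's phase relative to the
tiling, which a 100-bp plant cannot; regions are placed one per equal
genome segment so they never overlap and their tile phase is uniform.

What passing these tests does **not** show about real data: no mapping
ambiguity, positional coverage bias, splicing, annotation error, or
bisulfite non-conversion is modelled, and planted signals are uniform
within their windows. Recovery rates here are upper bounds on field
performance.

## Problem sizes and numerics

The recovery benchmarks use 200 genes / 40 planted extensions and a
100-kb methylome / 20 planted DMRs; the null control for the DMR caller
uses 200 independent 50-kb simulations — sizes at which every property
under test is already exercised at scale while a full run stays
interactive. Zero p-values entering Fisher's method are clamped to the
smallest positive float (with a warning). Fold change with a zero
denominator is +∞ when the numerator is positive and undefined
(auto-fail) otherwise. All randomness flows from a single integer seed
through `numpy.random.default_rng`; reruns are byte-identical.
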
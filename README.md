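# assocnet

A toolkit for scored protein–protein association networks and the analyses
that surround them: probabilistic evidence-channel score combination,
power-aware gene-set overrepresentation analysis, network clustering with
automatic cluster naming, and benchmark-based calibration of directed
regulatory confidence scores.  It is aimed at computational biologists who
work with confidence-scored interaction networks (functional, physical or
directed regulatory) and gene-set collections, and who need the statistical
machinery behind such resources as a standalone, scriptable library.

## What it computes

**Channel combination.** Evidence for a protein pair arrives through seven
channels (genomic neighborhood, gene fusion, phylogenetic co-occurrence,
co-expression, experiments, curated databases, text mining), each giving a
subscore *sᵢ* ∈ [0, 1].  With a prior *p* (baseline probability that a
random pair is associated), the combined confidence is a prior-corrected
noisy-OR under channel independence:

    sᵢ′ = max(0, (sᵢ − p) / (1 − p))
    S   = p + (1 − p) · (1 − ∏ᵢ (1 − sᵢ′))

Channels can be enabled/disabled and the combined score recomputed; physical
and regulatory sub-networks are checked for containment in their functional
parent at equal-or-higher scores.

**Overrepresentation analysis.** Each term (gene set) of effective size *m*
is tested against a query of size *n* drawn from a background of size *N*
with the one-sided hypergeometric tail P(X ≥ k); p-values are
Benjamini–Hochberg corrected within each category.  Before testing, the
*viability filter* removes terms whose best-case p-value
p_min(m) = P(X ≥ min(m, n)) exceeds α — they cannot possibly be significant,
and excluding them from the correction increases power for everything else
without ever losing a rejectable term.  Results carry *strength* =
log₁₀(observed/expected) and *signal* = the weighted harmonic mean of the
observed/expected ratio and −log₁₀(FDR), plus Jaccard redundancy filtering,
average-linkage similarity grouping and dot-plot export.

**Clustering and naming.** Networks are clustered either by MCL (stochastic
flow with expansion/inflation on the column-stochastic score matrix) or by
k-medoids on most-probable-path distances (edge length −ln score), with the
cluster budget spread over disconnected components largest-first.  Each
cluster is then named by enrichment signal: up to three descriptions
(primary/secondary/tertiary), falling back to canonical gene names.

**Calibration.** Raw directed-evidence scores are benchmarked against a
gold standard per category (regulation, up/downregulation, transcriptional
regulation, phosphorylation): sliding-window precision along the score
ranking, isotonic (pool-adjacent-violators) regression into a monotone
calibration curve, and interpolation to map any raw score to a confidence.

All inputs can be generated synthetically (`assocnet.synth`) with known
ground truth: planted-partition networks whose channel subscores recombine
exactly, term collections rich in tiny noise terms, contaminated queries
and separable gold standards with an analytic posterior.

## Worked example

`examples/02_enrichment.py` plants one 20-gene term among 500 noise terms
in a 100-gene universe and queries with a 20% contaminated version of it:

```
universe 100 genes, query 20 genes (16 from the planted term)
viable term sizes at alpha 0.05: 2..87 (smaller/larger terms cannot reach significance and are not tested)
245 of 501 terms tested after the viability filter
top 3 terms by enrichment signal:
  PLANTED:0000   obs=16 expected= 4.00 fdr=3.55e-09 strength=0.60 signal=5.43
  NOISE:00361    obs= 3 expected= 0.60 fdr=8.64e-01 strength=0.70 signal=0.13
  NOISE:00124    obs= 2 expected= 0.40 fdr=1.00e+00 strength=0.70 signal=0.00
```

The filter halves the number of tests (single-gene noise terms cannot reach
α = 0.05 when n/N = 0.2), and the planted term dominates the signal ranking:
16 observed vs 4 expected (strength 0.60 = log₁₀ 4) at FDR 3.6·10⁻⁹.  The
other examples demonstrate channel combination (`01`), clustering and
naming with perfect module recovery on the default fixture (`03`), and
calibration, where the fitted curve tracks the analytic posterior to a mean
absolute error of ≈0.006 on 10,000 predictions (`04`).

A thin CLI mirrors the library:
`assocnet simulate|combine|enrich|cluster|describe|calibrate|check`
(see `assocnet --help`); every run writes a `config.json` echo of its
effective parameters.

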
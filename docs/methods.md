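# Methods

## Scope and data model

`methlink` analyses a paired multi-tissue methylome/transcriptome design:
one RRBS coverage file per tissue (per-CpG methylated/unmethylated counts),
one gene × tissue FPKM matrix, gene models (GTF), CpG-island intervals
(BED), and exon-skipping junction counts. All internal coordinates are
0-based half-open; GTF is converted from 1-based closed on load, BED is
taken as is. Alignment, methylation calling, transcript assembly and
enrichment analysis are out of scope: the package starts from quantified
counts and ends at statistical calls and TSV/JSON exports.

## Annotation

The promoter is the 2 kbp (`upstream_bp`) window strictly upstream of the
TSS, excluding the TSS base itself and truncated at position 0. One TSS per
gene (the gene-level extremal coordinate); promoters of neighbouring genes
are not clipped against each other. CGI shores are the 2 kbp flanks of a
CGI. An analysis unit is any (CGI, gene) pair whose CGI intersects the
gene's promoter by ≥ 1 bp (`min_overlap_bp`); a CGI spanning k promoters
yields k units. Feature labels (promoter, gene body, CGI, shore,
intergenic) are non-exclusive, `intergenic` applying only when nothing else
does.

## Methylation quantification

A site's level is 100·m/(m+u) percent. Sites below 10× depth (`min_depth`)
are discarded; a sample is dropped entirely when its mean CpG depth is
below 10× (`min_mean_depth`), mirroring the common RRBS QC in multi-tissue
panels. A CGI's representative value per tissue is the **median of its
per-site percent levels** (even counts: mean of the central pair), missing
when fewer than `min_sites` (default 1) sites support it — never encoded as
0. Calls on the two strands of a CpG dinucleotide are kept as separate
sites; `merge_strands` offers the pooled view but is not the default, since
per-site medians are insensitive to the choice at typical densities. The
TSS/TES trend profile uses fixed-width flank bins (2 kbp) and
length-normalised gene-body bins, strand-oriented; bins without sites are
missing.

Hypo/hyper methylation state uses inclusive cutoffs at 20 %/80 %
(`hypo_max`, `hyper_min`). These are configuration, not biology: published
analyses use the terms without defining cutoffs, and nothing downstream
depends on them except density summaries.

## Differential methylation

With one sample per tissue, each shared CpG position is tested by
two-sided Fisher's exact test on the 2×2 table of methylated/unmethylated
counts: the p-value sums hypergeometric point probabilities not exceeding
that of the observed table (relative tolerance 1+1e-7, the classical
convention). Benjamini–Hochberg FDR ≤ 0.05 is applied over all sites shared
by the pair after depth filtering (that shared set is the BH family). No
minimum methylation difference is imposed by default (`min_diff = 0`); the
customary 25-point cutoff is available. Fisher is conservative under the
null, so the empirical type-I rate at p ≤ 0.05 sits below 0.05. The
implementation deduplicates tables and caches the hypergeometric pmf per
margin configuration, which makes the all-pairs tissue screen (~10⁶ tables)
run in seconds; BH is delegated to statsmodels.

## Expression

The FPKM filter removes genes with row sum < 3 — the interpretation of the
ambiguous published phrasing ("not equal to FPKM row sum 3") as a
low-expression floor, since a strict equality filter is meaningless for
continuous FPKM. Tissue–tissue correlation is Pearson with p from the
t-transform (n−2 df). A tissue-specific gene (TSG) satisfies
(max + 1)/(min + 1) ≥ 16 across tissues (pseudocount 1 guards zero FPKM;
the pairwise criterion reduces exactly to this max/min form). Selected
genes are z-scored per row with the sample (n−1) standard deviation; rows
[0, 10] map to ±0.7071. Clustering resolves the contradictory phrase
"Euclidean distance and ward linkage based k-means" as **Ward-initialised
k-means**: Ward agglomeration cut at k = 12 seeds the centroids, then
standard k-means refines to convergence (tol 1e-6, ≤ 300 iterations) —
deterministic given the data, and invariant to row order. The DEG network
summary consumes an externally produced symmetric tissue-pair count table;
DEG calling itself (a negative-binomial RNA-seq model) is out of scope.

## Splicing

For a cassette exon, ψ = (I/2)/(I/2 + S), I = IJC_up + IJC_dn inclusion
junction reads and S skipping reads: inclusion is supported by two
junctions per event, hence the halving. This is the junction-count
estimator; effective-length weighting (as in likelihood-based DEU tools)
needs read-length metadata that quantified junction tables do not carry.
Cells below 10 junction reads are missing. Switch-like exons have ψ ≤ 0.3
in one tissue and ψ ≥ 0.7 in a *different* tissue (both bounds inclusive).
Differential exon usage between two conditions is a two-sided Fisher's
exact test on [round(I_A/2), S_A; round(I_B/2), S_B] (round half to even)
with BH ≤ 0.05 — appropriate for one sample per condition, in place of a
replicate-based likelihood model.

## The GSM screen

Per unit, tissues with both a methylation value and an FPKM value are
paired (pairwise-complete); units with fewer than `min_tissues = 8` such
tissues are excluded and counted. Expression enters as log₂(FPKM+1) by
default (`log_transform`), matching the scale on which such relationships
are usually displayed; a raw-FPKM mode exists. Classification uses the raw
two-sided p: **gsm** iff r < 0 and p ≤ 0.05, **gsm_high** iff additionally
p ≤ 0.001. A BH-adjusted column is written but deliberately not used for
classification — the screen is a published-threshold filter, not an FDR
procedure. Constant vectors yield a missing result, never r = 0. The run
report also carries the pooled correlation over all unit–tissue pairs and
coarse density summaries; with a small fraction of truly coupled units the
pooled value is expected to sit near zero (slightly negative), which is why
it is reported but never used for selection.

## Correlation network and MCL

Nodes are CGI methylation profiles; edges connect pairs with
pairwise-complete Pearson r > 0.85 (≥ 3 shared tissues), weight r; isolated
nodes are dropped. MCL runs on the column-stochastic adjacency with
self-loops at each node's maximum incident weight (standard practice when
the original tool's preprocessing is undocumented): alternate expansion
(matrix squaring) and inflation (entry-wise power 1.3, column
renormalisation), pruning entries < 1e-5, until the largest entry change
falls below 1e-6 (≤ 200 iterations). Clusters are read off attractor rows;
attractors sharing flow form one cluster; a node attracted to several
clusters goes to the larger flow mass, ties to the smallest node id. In the
degenerate strong-inflation regime where the limit has no self-attracting
diagonal (periodic flow), clusters fall back to connected components of the
residual flow support. The result is deterministic and invariant to node
order and to uniform edge-weight scaling.

## Synthetic data

The generator emulates the study design end to end with one integer seed;
identical config + seed gives byte-identical files.

* **Annotation** — genes packed on synthetic chromosomes with ≥ 6 kbp
  gaps (no overlapping genes, 2–6 exons); `cgi_promoter_fraction` (default
  0.75 of 4,000 CGIs) placed to intersect a distinct gene's promoter, the
  rest mid-gap, clear of all promoters. The full-scale preset therefore
  yields ~3,000 units.
* **Methylome** — 20 tissues, 6 of them at mean depth 5× to exercise the
  sample QC (14 qualify). CpG sites cluster inside CGIs (8–14 per island,
  mimicking MspI enrichment) plus sparse background sites. Depth is
  Poisson(12) per site; calls are Binomial(depth, π). Null CGIs draw one
  baseline π from a bimodal beta mixture — hypo Beta(1,12), hyper
  Beta(12,1.5), and a 10 % mid component Beta(20,20) reproducing the
  sub-peak near 50 % seen in real RRBS densities — with small tissue
  (sd 0.02) and site (sd 0.03) jitter. Planted GSM CGIs instead vary
  uniformly over π ∈ [0.05, 0.95] across tissues. Planted DMS positions
  among the background sites separate a designated tissue pair by 80
  percentage points.
* **Expression** — planted silencing link log₂(FPKM+1) = 8 − 6·π + ε,
  ε ~ N(0, 1.17), giving realized per-unit |r| ≈ 0.8; 12 tissue-specific
  blocks of 60–200 genes each receive a +6 log₂ spike in one tissue
  (≥ 16-fold, so they pass TSG selection); all other genes draw a
  tissue-independent log-normal profile (gene mean ~ N(3, 1.5), tissue
  sd 0.6 — modest variability typical of non-specific genes, keeping
  16-fold crossings rare among nulls).
* **Junctions** — per event and tissue, depth ~ Poisson(100), inclusion
  ~ Binomial(depth, ψ), the doubled inclusion count split binomially into
  the two inclusion junctions. Planted switch exons are near-completely
  included (ψ ∈ [0.85, 0.98]) except in 1–4 tissues where they are
  near-completely skipped (ψ ∈ [0.02, 0.15]) — "switch-like" meaning
  near-complete on both sides; planted differential-usage events separate
  the designated condition pair by Δψ = 0.6; null events hold a constant
  ψ ∈ [0.25, 0.75].

What the generator does **not** model: genomic sequence composition,
bisulfite conversion error, M-bias, overdispersed (beta-binomial) counts,
correlated tissue structure among null genes, transcript-level isoform
complexity, and batch effects. Passing tests therefore demonstrate
correctness and calibration of the estimators and screens under the stated
sampling model, not robustness to those real-data artefacts.

## Numerical choices

Fisher p-values absorb summation noise at the top (sums ≥ 1 − 1e-12 report
exactly 1); Pearson results within 1e-12 of |r| = 1 report p = 0. Medians
of even site counts average the central pair. DEU tables round half to
even. All stochastic steps consume `numpy.random.default_rng` streams
derived from the seed, with one fixed stream per generator stage so each
stage is reproducible in isolation. Pipeline stages communicate through
their TSV outputs, so a resumed run is bit-for-bit identical to a fresh
one.

## Problem sizes

The test suite and the acceptance script run everything at the scale the
package is designed for: the full-scale synthetic preset (3,400 genes,
4,000 CGIs → 3,000 units, 20 tissues), 10⁴ null sites for the type-I
check, 1,000 events at 10⁴× junction depth for ψ calibration, and the
complete grid of 2×2 tables with margins ≤ 30 (245,025 tables) for oracle
equivalence.

## Known limitations

* One sample per tissue: Fisher-based DMS/DEU tests capture sampling noise
  only; biological replication would require beta-binomial or
  likelihood-ratio models that are deliberately out of scope.
* The GSM screen's raw-p thresholds do not control FDR across ~3,000
  units; at p ≤ 0.05 a ~2.5 % one-sided false-call floor is expected by
  construction, and callers should treat the gsm class as a candidate
  list (the q_bh column, or the p ≤ 0.001 hard filter, is the defensible
  selection for downstream claims).
* CGI annotations are assumed disjoint (true of UCSC-style island tracks);
  overlapping islands are rejected rather than resolved.
* MCL is the canonical algorithm; it is not guaranteed to reproduce any
  particular GUI tool's preprocessing of the same graph.
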
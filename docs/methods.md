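# Methods

`cachexnet` re-implements, as a tested library, the statistical pipeline
used to integrate paired mRNA and miRNA expression profiles from a
two-group bulk RNA-seq study of wasting skeletal muscle (tumour-bearing
vs control mice), together with the histology quantification that
accompanies it. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic-data generator
does and does not emulate.

## Count model and differential expression

Counts are modelled as negative binomial with a mean/dispersion
parameterization, variance `mu + alpha * mu^2`. Normalization is
median-of-ratios: for each sample, the size factor is the median over
features (nonzero in every sample) of the ratio of the count to the
feature's geometric mean across samples, rescaled so the factors have
geometric mean 1. Per-sample fold changes are ratios of normalized
counts to the control-group mean, with a pseudo-count `eps = 1.0`
normalized count on both sides (the source analyses are silent on zero
handling; a symmetric pseudo-count bounds the ratios).

The two-group test is a Wald-type statistic on
`log2((mean_case + eps)/(mean_control + eps))` with a delta-method
standard error under NB sampling and a pooled moment estimate of the
dispersion, floored at `alpha_min = 1e-8` for Poisson-like features.
This is intentionally not a re-implementation of any particular DE
package: there is no dispersion shrinkage across features, no outlier
refitting, no LFC shrinkage. What the downstream stages need is a
calibrated DE call at 4-vs-6 sample sizes, and two choices matter for
that:

- **Reference distribution.** The moment variance estimate carries
  roughly `n1 + n2 - 2` residual degrees of freedom. With a plain
  normal reference the test runs anticonservative at these sample sizes
  (empirical type-I near 0.09 at nominal 0.05 on null NB data); with a
  Student-t reference at `df = n1 + n2 - 2` it is calibrated (0.05
  within Monte-Carlo error, every seed inside [0.03, 0.07]). The t
  reference is the default; `reference="normal"` is available.
- **Significance field.** DEG calling uses inclusive thresholds
  `max(FC, 1/FC) >= 1.5` and significance `<= 0.05`, with BH q-values
  as the default significance field and raw p as an option
  (`use_fdr=False`, `--raw-p`). Both conventions appear in this kind of
  analysis. Note that genes whose response is confined to a sample
  subgroup carry a large, real within-case variance; at 10 samples
  their q-values rarely clear 0.05 even when the raw p does, so
  subgroup-structured analyses are run with the raw-p rule (as in the
  pipeline demo configuration).

Benjamini–Hochberg is the exact step-up definition
(`q_(i) = min_{j>=i} p_(j) m / j`, capped at 1), verified in tests
against a brute-force implementation and against statsmodels.

## Expression stability and sample structure

DEG expression is z-scored per gene (population SD; zero-variance rows
map to zeros with a warning) and clustered by k-means with Euclidean
distance, random initialization, and a best-of-`n_init` restart policy
(default 100 in library calls; 10,000 is configurable to match the
upstream protocol — the objective is already stable long before that).
Cluster labels are renumbered by descending mean log2 fold change so
that "cluster I" is always the most up-regulated block; the upstream
labels are otherwise arbitrary.

Expression stability of a gene is the percent coefficient of variation
of its per-sample fold changes within the case group,
`%CV = 100 * SD/mean` with sample SD (`ddof=1`; the small case-group n
makes the unbiased scale estimate the right default, while z-scores use
the population convention — both are configurable).

The near-control case subgroup ("cluster A") is reconstructed as
follows: average-linkage hierarchical clustering of the case samples on
Euclidean distance over z-scored DEG expression; of the two top-level
case subtrees, the one whose centroid is nearest the control centroid
is the subgroup; DE is then re-run on subgroup-vs-control and
intersected with the full DEG list to give the uniformly regulated set.
The upstream description names only Euclidean distances, so the linkage
and the subtree criterion are this package's reconstruction — one
defensible reading, stated as such.

## Promoter motif enrichment

Promoters are the -300..+50 window around the TSS (350 nt), extracted
strand-aware with 0-based half-open arithmetic; minus-strand windows
are `[tss - downstream, tss + upstream)` reverse-complemented, and
windows that run off a contig are N-padded and flagged. Each promoter
is scored by the best log-odds hit of the PWM over both strands and all
offsets, min-max rescaled to [0, 1] by the matrix's worst/best
attainable sums (PFMs get a 0.1 pseudocount per cell; N positions score
the column's background expectation). Enrichment of a foreground set is
a one-sided z-test on the mean best-hit score,
`z = (mean_fg - mean_bg) / (sd_bg / sqrt(n_fg))`, the Pscan-family
statistic. Two consequences of that form:

- The background is treated as a reference *population*. The test is
  calibrated when the background is much larger than the foreground
  (the regime the genome-wide promoter repertoire provides); with a
  background the same size as the foreground the null variance is
  understated by about a factor of two. Calibration checks therefore
  use background pools ~20x the foreground.
- Backgrounds are CpG-matched: for each foreground promoter, one pool
  promoter with CpG dinucleotide fraction within ±0.02 is sampled
  without replacement (tolerance configurable; tight enough to matter,
  loose enough to succeed on realistic pools).

Occurrence fractions ("% of sequences with >= 1 site") use a best-hit
score cutoff of 0.8, configurable. Significance is declared at
p < 0.01, one-sided for over-representation.

## Gene-set enrichment

Flat hypergeometric over-representation: `p = P(X >= k)` for a term of
size K in a universe of size N with a DE list of size n overlapping in
k genes, BH-corrected across tested terms (k >= 1, K >= 3). The
universe defaults to the detected-gene set of the experiment — the
standard expression-aware background — not the genome; it is
configurable. Reported per term: fold enrichment `(k/n)/(K/N)`,
percent of the term present (`100 k/K`), and the up/down split of the
term's DE members. Term grouping/kappa networks are out of scope.

## miRNA–target integration

Candidate pairs are the union over per-source prediction tables,
restricted to DE miRNAs, with a validated-targets table treated as one
more source (validated pairs are not required to also be predicted).
Identifiers are harmonized case-insensitively with an optional alias
table; unmatched rows are dropped and counted. "Inversely correlated
expression" is implemented as its operational form — the miRNA and the
gene both carry DE calls with opposite directions — rather than a
sample-level correlation coefficient. The surviving pairs form a
bipartite graph; miRNA pairs with overlapping target sets get an edge
weighted by the Jaccard coefficient `|A∩B|/|A∪B|` (zero-overlap edges
suppressed). Exports: edge TSV, GraphML, SIF. Subnetworks induced on a
gene set admit user-supplied protein-interaction edges among genes.

## Histology

Micrographs are binarized either at a fixed threshold or by Otsu's
method; RGB input is first reduced to a red-dominance channel
`R - (G+B)/2`, appropriate for Picrosirius-red stain. The stained-area
score is the foreground fraction divided by an externally counted cell
density (PRA/CD). Tissue disorganization is the box-counting fractal
dimension: boxes on a geometric ladder (powers of 2 by default, powers
of 3 for carpet fixtures), grid anchored at the origin with no offset
averaging so the estimator is deterministic; D is the least-squares
slope of log N(s) vs log(1/s), with the fit's R² reported. A constant
N(s) (single pixel) returns D = 0 exactly. Group comparisons use the
two-tailed equal-variance t-test.

## Synthetic-data generator

The generator emulates the study's statistical structure so that every
stage is testable without external data. Defaults are the study
conditions: 4 control vs 6 case samples; NB counts with dispersion
0.05; per-sample library sizes log-uniform in [5e5, 2e6] to exercise
size-factor estimation; ~10% DE genes at a 3-fold mean effect
(|log2FC| = 1.585) split into four blocks (up/down x uniform/variable)
sized 386:101:157:364 after the study's four stability clusters; 18 of
300 miRNAs DE (13 up, 5 down) and drawn well above the >32-read
expression floor; planted miRNA-target pairs always with opposite
effect signs; decoy prediction pairs placed only on non-DE genes so
the anti-correlation filter must remove all of them; promoters of 350
nt i.i.d. bases at GC 0.42 with the motif consensus planted in
up-regulated genes at rate 0.8; binary images of known dimension
(filled square, Sierpinski carpet, thresholded smoothed noise with a
known foreground fraction).

Uniform-class genes draw their per-case-sample log2FC with SD 0.15,
variable-class with SD 0.8. In *subgroup mode* the variable-class
heterogeneity is structured instead of noisy: three case samples
(L2–L4) respond at 30% of the nominal effect while the responders get
amplitude `lfc_mean + lfc_sd_variable`; this reflects that
variably regulated genes in such studies show larger, sample-restricted
fold changes, and it makes the subgroup geometrically identifiable.
A single global seed feeds deterministic per-generator child streams,
so any input can be regenerated independently and byte-identically.

What the generator does **not** emulate: gene-length or GC biases,
correlated genes (co-expression modules beyond the planted blocks),
overdispersion trends in the mean, realistic promoter composition or
CpG islands, miRNA seed-match biology, or optical artefacts in
micrographs. Passing tests therefore certify the statistical machinery
under the stated model, not performance on any particular real dataset.

## Problem sizes in tests and the acceptance script

Routine tests run on 300–1,000-gene simulations; calibration checks use
5,000 null genes per seed, 20 seeds for stability/subgroup rates, and
2,000–5,000 null motif tests; pipeline determinism runs a 300-gene
bundle twice and compares bytes. These sizes give Monte-Carlo error
well inside the asserted tolerances while keeping the default suite in
the low minutes on one CPU.

## Known limitations

- The DE test is a calibrated simplification; effect-size estimates are
  unshrunken and noisy for low-count features.
- The subgroup ("cluster A") procedure and the Pscan-style statistic
  are reconstructions of under-specified upstream steps; both are
  documented design choices, equivalent in form rather than bit-exact.
- The %CV stability measure is undefined at zero mean fold change;
  pseudo-counts keep means positive, but near-zero means still inflate
  %CV.
- Hypergeometric enrichment assumes exchangeable genes; correlated
  gene sets (co-expression) will appear anti-conservative, as in any
  flat over-representation analysis.
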
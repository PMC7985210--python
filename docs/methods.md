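# Methods

This note documents the models, defaults, and numerical choices behind
`krasnet`, and what the synthetic benchmarks do and do not demonstrate.

## Trinucleotide channels and the KRAS allele map

Substitutions are represented on the strand where the mutated base is a
pyrimidine: a purine-reference event is reverse-complemented, flanks swapped
and complemented, before classification. Channel order is fixed and
lexicographic in (reference pyrimidine, alternate base, 5' flank, 3' flank)
with C before T, giving the conventional C>A … T>G blocks; catalogs written
by one run are therefore interchangeable with any other.

KRAS is transcribed from the reverse genomic strand. Rather than depend on a
reference genome, the package stores three 15-nt coding-strand windows
covering codons 10–14, 59–63, and 144–148 of the KRAS CDS. Because channel
identity is strand-invariant under pyrimidine collapsing, whether contexts
are read from the transcribed or untranscribed strand is immaterial; we use
the coding strand. Enumerating all nine single-nucleotide changes of each
hotspot codon under the standard genetic code yields the allele→channel map:
every hotspot missense allele maps to at least one channel, and alleles
reachable by two distinct substitutions (Q61H via CAA>CAC or CAA>CAT) map to
two. Indels and multi-nucleotide events are excluded from spectra (they are
retained in mutation matrices); input records must carry their own flanking
bases.

## Signature discovery and model selection

Discovery runs scikit-learn NMF (Frobenius loss, multiplicative updates,
tolerance 1e-6, at most 5000 iterations) from `n_restarts` random
initializations per candidate k. The pooled, L1-normalized signature vectors
are clustered into k groups (k-means on L2-normalized vectors, so Euclidean
distance orders like cosine distance) and scored by mean silhouette width
under cosine distance — a restart-stability measure. The chosen k minimizes
the median reconstruction error among candidates whose silhouette is within
0.05 of the best. The rationale: stability alone cannot separate k from k+1
when both are perfectly stable (with noiseless separable mixtures the
silhouette is ~1.0 for several k while the error collapses only at the true
rank), so the rule takes the most expressive model that is still as stable
as the stablest one. Consensus signatures are cluster centroids renormalized
to probability vectors; signatures contributing less than 5% of all
mutations in a pooled NNLS refit are dropped. Discovery is deterministic
given (seed, n_restarts).

Exposures are fit per sample by nonnegative least squares over an allow-list
of signatures (all discovered, by default; a per-cancer restriction and an
artifact-exclusion list are configuration). The attribution probability of a
signature for a given mutation channel is the exposure-weighted channel
weight normalized over signatures; it is scale-invariant per sample, so raw
and fractional exposures give identical attributions (asserted numerically in
the tests), and a zero denominator (no active signature can produce the
channel) raises rather than returning zeros.

## Allele-frequency prediction

Per-sample allele probabilities use the sample's own genome-wide channel
frequencies — not cohort-pooled counts — matching the per-tumor framing of
the prediction; the sample's own KRAS hotspot SNV is excluded from its
spectrum (one mutation; negligible except at very low burdens). No
trinucleotide-opportunity correction is applied: the quantity is the raw
frequency of the causative change, not an opportunity-normalized rate.
Alleles with several causative channels sum their channel frequencies before
normalization over the candidate set (alleles at ≥3% of KRAS-mutant samples;
a pan-cancer mode unions candidate sets across cancers).

Predicted frequencies are means over samples with percentile-bootstrap 95%
CIs (default 10,000 resamples, seeded). Each allele is tested marginally with
a two-cell (allele / not-allele) χ² against its predicted frequency, BH
adjustment across alleles; the pooled multi-cell alternative would answer a
different question (global spectrum fit) and is not what "for each allele"
implies. Coverage of the percentile bootstrap was measured at ~93–95% for
n=500 samples in the test suite's simulation.

## Comutation analysis

**Hypermutants.** A two-component Gaussian mixture on log10(burden+1)
defines the cutoff as the smallest burden whose posterior probability of the
high component exceeds 0.5. A mixture fit on unimodal or effectively discrete
burdens happily splits the bulk in half, so the fit is declared degenerate —
and a configured top-fraction quantile (default 17%) is used instead —
unless the components are separated by at least two pooled standard
deviations. Burden should be genome-wide mutation count, not the row sum of
a small gene panel.

**Increased comutation** uses the one-sided hypergeometric enrichment tail
(identically Fisher's exact test) per (allele, gene), with the filters:
overall gene frequency ≥1%, and ≥3 comutation events or ≥10% comutation
frequency among allele carriers; edges require p < 0.01. Targeted panels may
be pooled here.

**Reduced comutation** uses the row–column exclusivity test on exome/genome
samples only (burden margins are meaningless for targeted panels). The
allele indicator is appended as a column and the whole binary matrix is
permuted with both margins fixed by curveball trades: pick two rows, swap a
random subset of their symmetric difference. Defaults: burn-in 5x the number
of 1s, thinning 1x between draws, 10,000 draws; the Markov chain tracks the
exclusivity statistic incrementally so all eligible genes (frequency ≥2%,
≥10 exclusive events) share one chain. The reported p uses the +1 correction
with ties counted as ≥ observed — deliberately conservative, hence never
anti-conservative but *super*-uniform under the null on a discrete statistic.
For sampler calibration the test also offers randomized tie-breaking
(observed placed uniformly among its permutation ties), under which the
p-value is exactly uniform when the sampler is correct; the test suite uses
the randomized form for its Kolmogorov–Smirnov uniformity check and
separately asserts that the conservative default keeps P(p ≤ α) at or below
α. End-to-end pipeline runs use fewer draws (2,000) with thinning 200 to
keep the synthetic fixture's runtime at desk scale; these are configuration,
not statistical constants.

**Network assembly** keeps all p < 0.01 edges; edges touching a curated gene
set (KRAS physical interactors, pathway members, known cancer genes —
supplied as configuration lists) must additionally pass BH FDR < 0.25 within
each such subset, and an edge in several sets is kept if any of them passes.

## Dependency screen

Cell lines with multiple activating KRAS mutations or an activating
BRAF/EGFR/NRAS mutation are removed; allele groups need ≥3 lines. Genes are
dropped when a simple regression of dependency on the gene's own expression
has p < 0.05 *and* R² ≥ 0.4 (the conjunction matters: a significant but weak
fit keeps the gene), or when dependency splits by the gene's own mutation
status (rank-sum p < 0.05). Screening is one-way ANOVA (p < 0.01) followed
by Student's t of each group versus all other lines pooled — matching a
single FDR-annotated contrast per allele — with BH over all (gene, group)
tests and hits at adjusted p < 0.05; an all-pairs alternative is available
behind a flag. Hits are clustered by Ward linkage on Euclidean distance of
z-scored profiles, cut at k=4 by default; Ward is chosen for compactness and
determinism (the linkage is not dictated by the screening procedure itself).

Power at the compound threshold is bounded: with four groups of six lines
and a single-group shift of exactly 2 noise-SD, the ANOVA noncentrality is
λ = 18 and the α=0.01 power is 0.72, so benchmarks at that effect size
measure ~72–80% sensitivity — the test suite records this measured value; a
3-SD shift is recovered in ≥95% of replicates.

## Mediation models

The design for a (target gene, allele) pair contains the target's
expression, the target's own mutation indicator, indicators for each
comutation partner, and the allele indicator contrasting the allele against
other KRAS-mutant lines; WT lines are excluded so the contrast matches the
screen's allele-vs-allele framing. Indicators need ≥3 mutant and ≥3 WT
lines; identical columns are merged into one predictor named by
concatenation (merging is idempotent and preserves the column space).
Covariates are standardized, the intercept is unpenalized, and the
expression covariate is penalized like the rest — adjustment is by
inclusion, not special-casing. The elastic-net mixing parameter is gridded
over {0.75, 0.80, …, 1.0} (L1-dominated by construction); for each mixing
value a 50-point log-spaced penalty path from the null-model penalty is
scored by 5-fold cross-validation (leave-one-out when lines < folds), and
the sparsest penalty within one standard error of the CV minimum is
refitted on all lines. The 1-SE rule is what makes the pure-noise case
return an empty model in ≥90% of replicates while a planted partner effect
(score shift −1.0, noise 0.1, 24 mutant lines) is assigned to the partner —
with the allele coefficient at zero — in ≥80%.

## Synthetic data: what it emulates, and what it does not

The cohort generator draws per-sample exposures from a Dirichlet prior,
burdens from a lognormal (median ~100 SNVs, emulating exome scale; optional
hypermutant component ~10x higher), channel counts from the
exposure-weighted catalog, and assigns KRAS alleles with probability
proportional to each sample's own causative-channel frequency times an
optional per-allele selection-bias multiplier — bias 1 is the pure
mutational-process null used for calibration. Flanking bases of emitted MAF
records are determined by the channel on the pyrimidine strand; there is no
genome-composition model of flank availability, no clonality structure, no
copy number, and no sequencing error. The mutation-matrix generator uses a
logistic model (gene-frequency baseline + shared per-sample burden offset +
planted allele x gene log-odds), which produces margin-correlated matrices
but not pathway structure. The screen generator adds allele shifts, partner
shifts (partner mutations anti-correlated with the allele, emulating reduced
comutation), expression slopes, and Gaussian noise. Passing benchmarks on
these generators therefore demonstrates calibration and recovery under the
stated statistical structure — not performance on real cohorts with
covariate-dependent mutation rates, subclonality, or panel heterogeneity.

A note on bias recovery: after per-sample renormalization a multiplier b on
an allele with probability p produces an observed/predicted ratio of
E[bp/(1+(b−1)p)]/E[p] < b, approaching b only for small, tightly
concentrated p; the recovery benchmark therefore plants the bias on an
allele whose causative channel is rare in the generating catalog.

## Determinism and sizes

Every stochastic step takes an explicit seed; the pipeline derives all stage
seeds from one configured seed and writes a manifest with the configuration
checksum and per-artifact SHA-256s, so reruns are byte-identical. Default
end-to-end fixture sizes — 200-sample cohort, 600-sample mutation matrix, 24
cell lines, 2,000 permutation draws — were chosen to exercise every stage
with detectable planted effects in minutes on a single CPU; statistical
primitives keep their full-scale defaults when called directly.

## Known limitations

- The row-column exclusivity chain is exact in distribution but Monte-Carlo:
  p-value resolution is 1/(n_perm+1), and heavy thinning trades accuracy for
  time on large matrices.
- The hypermutant mixture assumes a roughly lognormal burden; heavy
  discreteness (small panels) routes to the quantile fallback by design.
- The NMF model selection assumes the scanned k range brackets the true
  rank; silhouette stability degrades gracefully but is not a proof of rank.
- Mediation fits are associational; merged predictors are unidentifiable by
  construction and reported as a single named group.
- Expression filtering uses a simple linear model per gene; nonlinear
  expression-dependency relationships pass the filter.
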
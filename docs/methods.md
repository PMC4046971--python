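# Methods

This note documents the statistical models implemented in `ipscvar`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Study design and notation

The pipeline targets a panel design in which several somatic tissues
(fibroblast, keratinocyte, endothelial progenitor cells) are collected from
the same donors, reprogrammed into iPSC lines, and profiled by bulk RNA-seq
together with the parental adult cultures and embryonic stem cell lines.
The default layout has 47 samples: 18 adult (6 fibroblast, 3 keratinocyte,
9 EPC; three passages per culture), 25 iPSC lines (9 fibroblast-derived,
6 keratinocyte-derived, 10 EPC-derived) from 4 donors (S2, S5, S7 male;
S4 female), 4 ESC samples from two lines, and 2 sequencing batches. The
assignment of donors to tissues inside those marginal counts is not fully
determined by the published totals; the generator fixes one assignment
(fibroblast: S2, S4; keratinocyte: S2; EPC: S2, S5, S7; analogous for the
iPSC lines) and keeps it stable so the rank structure of every design
matrix is reproducible.

Expression is quantified as FPKM (fragments per kilobase of exon per
million mapped fragments) and analysed on the log2(FPKM + 1) scale; the
pseudocount of 1 is configurable.

## Variance-component model

Per gene *j*, expression across samples is

y_j = b1 + Z2 b2 + Z3 b3 + Z4 b4 + Z5 b5 + ε

with independent Gaussian random effects: b2 over the five cell-class
levels, b3 over iPSC tissue of origin, b4 over donor-within-cell-class,
b5 over batch. The D matrices are diagonal with structured sharing:
the three adult levels of b2 share δ²₂₁ and the two pluripotent levels
share δ²₂₂; b4 splits into a donor variance for adult samples (δ²₄₁) and
one for iPSC samples (δ²₄₂). ESC lines come from donors outside the panel
and carry no donor effect (their Z4 rows are zero). Residuals are either
homoscedastic (one σ²), heteroscedastic by cell class (model 1:
adult/iPSC/ESC) or by tissue-resolved group (model 2: seven σ²).

The contribution of component *k* is summarized as intraclass correlation,
%VE = δ²ₖ/(δ²ₖ + σ²_rel), where σ²_rel is the (sample-count-weighted)
residual variance of the samples the component acts on. The components are
not constrained to sum to 100%.

**Pooling and scaling.** Genes are centered — the intercept is profiled
out exactly by evaluating the likelihood on an orthonormal basis of the
centered subspace — and all genes are rescaled by the *median per-gene
standard deviation*. Scaling each gene to exactly unit variance was
considered and rejected: a gene's empirical SD contains its own realized
random-effect draws, so dividing by it systematically shrinks the
components with few levels (donor, adult tissue). In simulation this
attenuated donor VE by 0.04–0.06; the common median scale removes the bias
(measured |bias| ≤ 0.016, median |error| ≤ 0.013 on the 47-sample design
at 2,000 genes) while still putting the shared variance parameters on an
interpretable typical-gene scale. Per-gene precision weighting (the τ_j of
the precision module) would be a further refinement; it is not applied in
the pooled fit.

**Estimation** is direct maximum likelihood: L-BFGS-B on log-variance
parameters with analytic gradients, ≥ 5 restarts (one fixed start plus
seeded random starts), convergence tolerance 1e-8, parameters bounded in
[1e-10, 1e4]. The pooled likelihood only needs the 47×47 cross-product
matrix of the standardized data, so a fit takes well under a second.
Non-convergence in every restart raises with the optimizer trace — tiny
gene sets (e.g. the 13 mitochondrial genes) are expected to fail rather
than return silently. Dropping a component for the confounding contrast
(`refit_excluding`) refits with that block removed and reports paired %VE.

## Negative-binomial outcome classification

For one somatic tissue the triple (adult A, derived iPSC I, ESC E) is
compared per gene under five mean constraints: invariant (q_A = q_I = q_E),
correctly reprogrammed (q_I = q_E), transcriptional memory (q_A = q_I),
aberrant (q_A = q_E), and complex (all free). Counts are NB with
median-of-ratios size factors and a per-gene dispersion α estimated by
within-class method of moments, shrunk 70/30 toward a fitted DESeq-like
trend α(μ) = a0/μ + a1, floored at 1e-8, and held fixed across the five
fits so likelihood ratios are comparable. Class means are fitted by
Fisher scoring on log q (vectorized across genes).

Each alternative is tested against the null by a LR χ² with df equal to
its extra mean parameters (1, 1, 1, 2). Because the complex hypothesis
nests the others, raw likelihood always prefers it; classification
therefore uses the minimum p-value, with the df penalty making the rule
non-degenerate. p-values are compared on the log scale (`chi2.logsf`) —
at strong effects `sf` underflows to exactly zero and would otherwise tie
every alternative. Exact ties break toward the larger LR. Complex genes
are sub-classified as partial memory (PTM) when the fitted iPSC mean lies
strictly between adult and ESC, else partial aberrant (PAR).

**Permutation FDR.** Class labels are permuted across samples (size
factors stay attached to samples); the FDR estimate at threshold t is
(mean permuted rejections)/(observed rejections), clipped to [0, 1].
Dispersions are re-estimated under each permuted labeling: the observed
statistics use dispersions estimated within the observed grouping, and
reusing them for permuted groupings makes the permuted minimum p-values
stochastically larger than the observed ones even on null data (measured
estimate ≈ 0.75 of the realized null FDR). The monotonized (running-min)
curve yields per-gene q-values and the operating threshold t*; as a point
estimate of FDR at a single threshold the running minimum is biased low,
so the direct clipped ratio is reported for calibration. Significant genes
additionally require a ≥ 1.5-fold (inclusive) change between the fitted
iPSC and ESC means; tables count {AR, PAR, TM, PTM} × {activation,
silencing}, with direction defined by q_I vs q_E.

**Category proportions.** Transcriptome-wide proportions π over
{IE, CR, TM, AR, CX} are estimated by an empirical-Bayes mixture EM on
per-gene marginal likelihoods. The default weights are Wakefield-style
asymptotic Bayes factors: each alternative's extra parameters are
summarized by estimated log-mean contrasts with Fisher-information
variances, and a N(0, 1) prior (natural-log scale, ≈ 1.44 log2-fold units)
per contrast gives a closed-form Bayes factor against the null. A proper
marginal likelihood has null expectation 1, so null genes cannot inflate
the rare categories. The cruder penalized-likelihood weights
exp(ll − k/2·log n) remain available (`method="bic"`) but exp(χ²/2) has a
divergent null mean and overstates rare alternatives by a few percent
(measured ~0.03 at 10,000 null-dominated genes vs ≤ 0.01 for the Bayes
factors). The EM objective is asserted non-decreasing at every iteration;
convergence is Δ < 1e-8.

**Isoform ratios.** The same five-hypothesis machinery applies to the
fraction of a gene's most abundant isoform among its top two, with a
beta-binomial likelihood. The concentration parameter is estimated once
per gene under the unconstrained fit and held fixed. Only genes where two
quantifiers agree on the top-two isoform ranking are tested; the rest are
excluded and counted.

## Allele-specific expression and imprinting

Per (sample, gene), phased read counts are summed over heterozygous SNPs
(paternal/maternal is a label carried through from the input phasing,
never inferred). Allelic imbalance AI = paternal/(paternal+maternal) with
a Clopper–Pearson 95% CI; entries under 20 reads (configurable) are
excluded. Imbalance is tested by the exact two-sided binomial test
against 0.5. Imprinting status: mono-allelic iff AI ≥ 0.9 or ≤ 0.1 with
the CI excluding 0.5; bi-allelic iff the CI lies inside (0.2, 0.8); else
ambiguous — the numeric cutoffs are declared defaults, not published
values. Loss of imprinting is flagged when the adult tissue is
mono-allelic and a majority of derived iPSC lines are bi-allelic.
Adult–iPSC concordance is the Pearson r² of AI over genes testable in
both compartments, iPSC lines averaged with coverage weights.
Reference-mapping bias correction is out of scope; counts are taken as
given.

## eQTL replication

Lead eSNPs ascertained externally are consumed as a table (gene, SNP,
high-expression allele, ascertainment p, per-donor dosage); ascertainment
itself is out of scope. With four donors only pooled statistics are
meaningful and no per-gene p-values are produced. Three signatures:

* **Directional concordance** — donor-averaged expression and dosage are
  z-scored per gene and pooled; a noiseless additive effect gives r = 1
  exactly, and flipping the recorded high-expression allele negates r
  exactly.
* **Allelic imbalance** — per-gene high-haplotype read fractions in
  heterozygous donors, one-sample t against 0.5 (degenerate zero-variance
  input returns t = 0, p = 1 at the null value).
* **Variance explained** — per-gene OLS R² of donor means on dosage. With
  n = 4 the null mean R² is ≈ 1/3, so the raw mean is reported against a
  permutation-derived null mean along with the calibrated excess
  (mean − null)/(1 − null). The stratified contrast refits the mixed model
  on the strongest-k vs weakest-k ascertained genes and compares donor VE.

## Read-pair QC filter

A fragment passes iff (at least one mate has MAPQ > 10, no indel in its
alignment, and ≤ 3 mismatches by NM) and the mates are on the same
chromosome with |TLEN| in [150 bp, 1 Mb] (inclusive). "Quality" is read
as mapping quality; spliced-alignment N operations are not gaps (introns
are expected in RNA-seq), only I/D are. TLEN = 0 on the same chromosome
fails the insert rule (0 < 150). Rejection reasons partition the input
exactly, with a fixed precedence: trans-chromosomal → insert → quality;
reads without a mate in the stream count as unpaired. A missing NM tag is
an error unless a side-band mismatch table is supplied. Coordinates are
1-based inclusive throughout (SAM/VCF convention).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the panel's design exactly (sample counts, donor
nesting, two batches) and plants known truth for every downstream
estimate: per-gene random-effect draws on the log2 scale, NB counts with
a DESeq-like dispersion trend α(μ) = a0/μ + a1 (defaults a0 = 2,
a1 = 0.01), log-normal size factors (sd 0.1) exercising normalization,
baseline log2 FPKM ~ N(5, 1.5²), gene lengths log-normal around 1.5 kb,
~20 M fragments per library. Default variance parameters put the true
intraclass correlations at donor-iPSC 0.38, donor-adult 0.42, origin
0.04, iPSC-vs-ESC 0.01, batch 0.02, adult-tissue 0.50 against unit
residual — the regime the pipeline is built to detect. One global seed
fans out to per-component child streams via `SeedSequence.spawn`, so each
sub-simulation is independently reproducible and bit-stable.

Three-way triples default to n = (6, 9, 4) samples and mean depth 500;
complex genes place the iPSC mean halfway inside (PTM truth) or halfway
outside (PAR truth) the adult–ESC interval, signs random. The eQTL
generator draws donor dosages at MAF 0.3 (redrawing monomorphic genes)
and scales the effect so the planted variance fraction is exact on the
realized dosages (non-genetic donor noise is orthogonalized against
dosage); consequently the mean donor-level R² equals the planted
fraction directly. A confounded companion design nests two donors per
origin with no sharing, which makes donor covariance absorbable by the
origin component once donor is dropped — the confounding contrast.

Not emulated: raw reads and alignment artifacts, reference-mapping bias
in allelic counts, splice-graph structure (isoform counts are drawn at the
gene level), GC bias (available separately in the normalization module's
own tests), population structure, and real heavy-tailed per-gene variance
heterogeneity (genes share variance parameters within a run). Passing
tests therefore demonstrate correctness and calibration of the estimators
under the declared generating model, not robustness to every artifact of
real RNA-seq.

## Numerical choices and problem sizes

Tolerances: mixed-model optimizer ftol 1e-8; EM convergence 1e-8 with a
monotonicity assertion; NB mean fits iterate Fisher scoring to 1e-12 with
step clipping at ±4 log units; dispersions floored at 1e-8; τ precision
capped at its 99th percentile; complete-linkage ties broken by
lexicographic sample order; GC bins are 25 equal-count bins with a cubic
regression spline of df 5 (one interior knot), empty bins merged.

The bundled test suite and the reproduction script run at reduced but
statistically adequate sizes — typically 800–10,000 genes and 5–20
simulation seeds per property, 50–100 permutations for FDR — chosen so
every recovery check retains comfortable margins (e.g. VE recovery is
tested at 2,000 genes over 20 seeds where the measured median error is
≈ 0.01 against a 0.05 bound).

## Known limitations

* The pooled mixed model assumes a shared covariance across genes after a
  robust common rescaling; strong per-gene variance heterogeneity in real
  data would call for τ-weighted pooling.
* BIC-style mixture weights are retained only as a fallback; their rare-
  category estimates are upward-biased by design.
* The χ² reference for the LR tests is asymptotic; at n = (6, 9, 4) the
  per-alternative p-values are uniform to KS resolution at 10,000 genes,
  but smaller triples may need permutation calibration of the minimum p.
* With four donors, every eQTL statistic is pooled; the module refuses to
  emit per-gene inference by construction.
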
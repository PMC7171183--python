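# Methods

This note documents the models, estimators and design choices behind
`mhc_escape`, in the spirit of a statistical methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Scope and data model

The package starts from a gene × sample matrix of integer read counts
(exon-level counting is assumed upstream) together with sample metadata:
patient, biopsy timepoint (PRE = pre-treatment, RES = responding
on-treatment, PROG = progressing on-treatment, the latter annotated as
innate or acquired resistance), and the best immune-related response
(irRC) class. Patients with CR or PR are responders; SD or PD,
non-responders; a patient with at least one progressing or new lesion *and*
at least one responding lesion is flagged as a heterogeneous response.
Gene identifiers are case-sensitive HGNC symbols; no synonym resolution is
attempted (deterministic behavior; alias mapping is a preprocessing
concern).

## Normalization

**TMM scale factors.** For each sample against a reference column (the
sample whose upper quartile of nonzero counts-per-million is closest to the
cohort mean; ties go to the lowest index), genes expressed in both samples
contribute a log-ratio M and average abundance A. After discarding the top
and bottom 30% of M and 5% of A (two-sided rank trims), the surviving
M-values are averaged with inverse asymptotic-variance weights
`(N−y)/(Ny)` summed over both samples, and the factor is 2 to that mean.
Factors are rescaled to geometric mean 1. These are the original TMM
defaults; the implementation agrees with a brute-force evaluation of the
formula to 1e-10 and with edgeR's `calcNormFactors` to 8 decimals in the
cross-check tests.

**log₂-CPM.** Exactly `log2((count + 0.5) / (libsize·factor + 1) × 1e6)`.
The 0.5/1 pseudocounts keep zeros finite and the transform monotone.

**Precision weights.** Per-gene residual standard deviations from a
group-means fit on the log-CPM scale are square-rooted and regressed by
lowess (span 0.5, 3 robustness iterations) on average log₂ count; the trend
evaluated at each observation's fitted count, raised to the −4 power, is
the observation's inverse-variance weight. Extrapolation beyond the trend's
support is flat. Whether weights propagate into the CYT-matched contrast is
a flag (`use_voom_weights`, default on in the pipeline); the responder
contrast always supports them.

**FPKM** (`count / (kb · millions of reads)`) is recomputed from counts and
user-supplied gene lengths; it is the conventional input scale for ssGSEA
and deconvolution. **Gene centering** (subtracting each gene's cohort mean)
reproduces the documented input preparation of the external TIDE score.

## Enrichment

**ssGSEA.** For one sample, genes are ordered by decreasing expression
(ties broken lexicographically by gene id for determinism). The enrichment
score is the sum over all rank positions of the difference between the
weighted in-set ECDF and the unweighted out-of-set ECDF. The in-set step of
the gene at position *i* (from the top) is weighted `(N−i+1)^α`, normalized
so in-set weights sum to 1 — i.e. the top-ranked gene carries weight `N^α`,
matching the original ssGSEA code. α defaults to 0.25 (the original
publication's value); 0.75 (a later GenePattern default) is one config key
away. No sample-wise rescaling of the raw ES is applied by default
(a min–max flag exists); the IPRES score Z-scores downstream anyway.

Note a structural property: for α > 0 the rank-position weighting makes the
expected ES of a *random* gene set positive (the top of the list is
up-weighted for the in-set ECDF only). This bias is inherent to ssGSEA as
published, is exactly zero at α = 0, and is pinned against an independent
combinatorial oracle in the tests.

**Preranked GSEA.** The classic weighted Kolmogorov–Smirnov running sum
over a user-ranked statistic (in-set increments ∝ |stat|, out-of-set
decrements 1/(N−k)); the ES is the extreme deviation. Because the input is
a single ranked vector, the only available null is gene-set resampling:
random same-size sets are drawn (seeded) and the observed ES is referred to
the same-sign tail of the null; NES divides ES by the mean |null ES| of
matching sign; q-values are Benjamini–Hochberg across sets. Sets of all
in-set statistics equal to zero fall back to equal increments.

## Signature scores

Defined verbatim from their sources: CYT = mean(GZMA, PRF1) on the
normalized log scale; CD8A−CSF1R = their difference; the 18-gene immune
score = ssGSEA of the configured 18-gene set; IPRES = mean over its sets of
per-set Z-scored (n−1 denominator) ssGSEA scores; IMPRES = the number of
configured checkpoint-gene pair inequalities satisfied, ties scoring
nothing by default (strict inequality is the conservative reading;
configurable). The 18-gene, IPRES-set and IMPRES-pair lists ship as
editable configuration (YAML / GMT / 3-column TSV), not constants, because
their sources publish them separately; the synthetic cohorts use stand-in
lists over the simulated immune program. ssGSEA-based scores consume the
FPKM matrix when one is supplied, else log₂-CPM; the choice is recorded in
the run manifest. TIDE and deconvolved CD8⁺ fractions are merged as
optional external columns.

**Inflamed classification.** A tumor is inflamed iff its CYT score ≥ the
minimum CYT among RES lesions. The one-sided rule is primary (the reference
range is anchored at its lower end); a two-sided variant (≤ max as well) is
available by flag.

## CYT-matched HLA-A stratification

All unordered pairs of PRE and PROG tumors (the union; a PRE×PROG-only mode
exists) are screened: CYT similarity is `min/max ≥ 0.9` — the symmetric,
slightly more permissive reading of a 0.9–1.1 ratio window — and the HLA-A
transcript difference must exceed two-fold strictly (|Δlog₂| > 1). CYT
ratios are taken on the score scale as-is; nonpositive CYT values are an
error with an explicit additive-shift escape hatch, since a ratio criterion
is undefined there. Candidates are sorted by descending |Δlog₂ HLA-A| (ties
lexicographic) and swept greedily, accepting a pair only if neither member
is already used; this is the simplest deterministic reading of rank-ordered
selection into disjoint pairs (the greedy matching is guaranteed at least
half the maximum-cardinality matching, which the tests check). Within each
pair the lower-HLA-A member is labeled `low`. Selected pairs are re-validated
against both criteria post hoc.

## Moderated-t differential expression

Per feature, a (weighted) least-squares two-group fit gives the mean
difference (log₂ fold change), residual variance s²_g on d_g = n−2 df, and
the contrast variance v = 1/Σw₁ + 1/Σw₂. Across features, log s²_g moments
are matched to a scaled-F distribution: the empirical variance of
log s²_g minus trigamma(d_g/2) determines d₀ via the inverse trigamma
(Newton iteration); s₀² follows from the mean via digamma. When no excess
spread remains, d₀ = ∞ and s₀² is the arithmetic mean of the variances.
The moderated statistic divides the difference by
√(s̃²·v), s̃² = (d₀s₀² + d_g s²_g)/(d₀+d_g), referred to Student t with
d₀+d_g df (normal at d₀ = ∞; d₀ = 0 reproduces the ordinary two-sample t
and is the documented "no moderation" setting). p = 0 underflow is floored
at machine tiny before BH adjustment. Robust (outlier-variance) prior
fitting is not implemented. The same machinery applies to ssGSEA score
matrices (no weights); with fewer than 50 sets the moment fit is unstable
and the code falls back to no moderation.

The matched-pair contrast is analyzed unpaired by default (the plain
two-group description of the analysis); d₀, s₀² and the t-statistics agree
with limma's `eBayes` to 8 decimals in the cross-check tests.

## ROC evaluation

AUC is the Mann–Whitney U scaled by n₁n₀ with ties counting ½ — the
probability a random responder outscores a random non-responder. The
primary 95% CI is the Hanley–McNeil normal interval clipped to [0,1]; a
Wilson score interval on the rank proportion is available and labeled,
because the cited commercial "hybrid Wilson/Brown" application to AUC is
undocumented. The p-value versus AUC = 0.5 is the tie-corrected normal
approximation to U, two-sided. Orientations are fixed a priori per
signature (higher immune activity → responder; IPRES and TIDE are
resistance scores and enter negated) and recorded — never flipped post hoc,
so AUCs below 0.5 are reportable. Groupwise Pearson/Spearman correlations
require ≥ 3 samples per group; correlation matrices carry BH-FDR over their
off-diagonal p-values, with constant rows reported as missing. Cell-type
fraction tables are aggregated subset→major-type by exact summation.

## Flow cytometry

Inputs are gated-population summary tables (gating is interactive
instrument-side work and out of scope). The melanoma/TIL HLA-ABC ratio uses
geometric-mean MFI of the two populations from the same dissociate — the
infiltrating lymphocytes act as an internal staining control — and a tumor
is called downregulated iff ratio < 0.65, strictly; the threshold is a
parameter, not a derived constant. Stained/unstained relative expression
uses median MFI (the two statistics are explicit fields so mixing is
detectable), and cytokine induction is the treated/vehicle fold. Flow–
transcript concordance is the Spearman correlation between the ratio and
HLA-A log₂-CPM over samples with both measurements.

## Synthetic cohort generator

The generator emulates the *statistical structure* the analysis assumes,
with the study's design constants as defaults: 44 PRE + 6 RES + 29 PROG
biopsies, 15 PRE + 16 PROG flow dissociates, a flow/transcript Spearman
target of 0.67, and a +3.7 log₂ SNAI1 shift in the de-differentiated state
(the fold change the matched contrast is expected to recover).

Counts are negative binomial (variance μ + φμ², gamma–Poisson; φ = 0.2,
a typical between-patient biological CV² for clinical bulk RNA-seq) around
per-gene baselines drawn log-uniformly over [1, 10⁴]. Named marker genes
get biologically sensible ranges instead: MHC-I transcripts (HLA-A/B/C,
B2M) from [500, 5000] — they are among the most abundant mRNAs in tumor
tissue — and the immune/EMT/melanocytic markers from [50, 1000]. Sequencing
depth varies lognormally (σ = 0.3).

Three latent structures are planted, driven by one seeded generator in a
fixed draw order (baselines, depths, infiltration, de-differentiation,
counts, response labels, flow noise — so identical configs are
byte-identical):

* **Infiltration**: a standard-normal per-sample score shifts the immune
  genes (GZMA, PRF1, CD8A, CSF1R and the immune program block) by
  `infiltration_effect` log₂ per unit (default 1.0, a calibration choice).
  RES lesions draw their score from the top quartile so that a CYT
  reference range exists for the inflamed classifier. Responder labels for
  PRE samples follow a logistic link with configurable log-odds
  (`response_association`; 0 gives label independence — the null cohort).
* **De-differentiation**: a binary state (fraction 0.3 by default) that
  shifts HLA-A/B/C/B2M by −2 log₂, SNAI1 by +3.7, the other EMT genes
  (AXL, NGFR, TAGLN, SERPINE1, BGN) by +2, and the melanocytic lineage
  genes (MITF, TYR, DCT, MLANA) by −2. A binary state rather than a
  continuum keeps recovery tests crisp.
* **Flow coupling**: a Gaussian copula couples the melanoma/TIL ratio to
  the rank of the sample's simulated HLA-A count at the target Spearman ρ
  (the latent Pearson r is `2·sin(πρ/6)` so the rank correlation is hit in
  expectation). The ratio marginal is lognormal with median 0.8 and
  log-σ 0.54, placing roughly a third of dissociates below the 0.65
  threshold.

What the generator does **not** emulate: read-level noise, gene–gene
correlation beyond the planted programs, batch effects, GC/length biases,
tumor purity variation, or longitudinal within-patient correlation.
Passing tests therefore demonstrate the correctness and calibration of the
*procedures* under the assumed model, not the reproduction of the clinical
cohort's numbers, which require the controlled-access patient data.

A separate helper draws per-gene variances from the hierarchical
scaled-inverse-χ² model (σ²_g ~ d₀s₀²/χ²(d₀), s²_g ~ σ²_g·χ²(d)/d) for
prior-recovery tests.

## Numerical choices and degenerate inputs

Ties: expression ties break by gene id; candidate-pair ties by
lexicographic pair id; reference-sample ties by lowest index; IMPRES ties
score nothing. Zero counts are excluded from pairwise M/A computation
(M undefined at zero). Zero-variance gene sets are an error in Z-scoring
(named in the message). Constant rows in correlation matrices are missing,
not errors. Weights must be strictly positive; lowess predictions are
floored at 1e-6 before the −4 power. BH q-values are clipped to [0,1] with
enforced monotonicity.

## Problem sizes

The test and acceptance workloads are sized for quick, stable statistics:
100 random 200×6 matrices for the TMM oracle; 20 sets × 50 samples for the
ssGSEA brute-force comparison; 1000 resampled sets × 1000 permutations for
preranked null uniformity; 20 000 genes for moderated-t type-I error and
5000 for prior recovery; 1000 null cohorts of n = 44 for ROC calibration;
50 seeded study-sized cohorts (400 genes) for end-to-end planted-effect
recovery; n = 200 dissociates for flow-concordance recovery. The
acceptance script uses the same designs at reduced replicate counts.

## Known limitations

No robust variance prior; no multi-factor or paired designs beyond the
two-group contrast (a paired mode for the matched analysis is future work);
no leading-edge reporting or phenotype-permutation GSEA; no FCS parsing,
compensation or gating; TIDE and deconvolution are external inputs by
design. The exact parameterization used by the original ssGSEA service
version is not published, so ssGSEA correctness is established against
internal oracles and worked examples rather than third-party score values.
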
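# Methods

## Scope and data model

`iopanel` analyzes gene-level absolute read counts from a targeted
~398-plex immune-oncology amplicon panel: 395 human genes spanning
immune-function, infiltrating-cell-marker, tumor-antigen and
tumor-marker categories, of which ten are housekeeping (HK) controls,
plus one no-template-control (NTC) library per run. Upstream read
mapping and counting are out of scope; the count matrix is the input.
The panel definition file may place the HK genes inside or outside the
395 (the panel format expresses either), since panel descriptions are
ambiguous on this point; the synthetic panel counts them inside.

## QC gate

A sample is admitted when mapped reads ≥ 200,000 (inclusive), on-target
ratio strictly > 0.50, and ≥ 6 HK genes detected (nonzero counts).
Boundary conventions matter at panel scale and are tested explicitly:
exactly 200k passes, exactly 50.0% fails, exactly 6 HK genes passes. The
verdict enumerates every failed criterion rather than short-circuiting.

## nRPM normalization

Three steps per admitted sample:

1. *Background subtraction.* `max(count − NTC, 0)` per gene. The clamp
   at zero is a deliberate choice: nRPM must be non-negative for the log
   transform, and a background estimate exceeding the sample count
   carries no usable signal.
2. *HK ratios.* Each HK gene's **absolute** (pre-subtraction) count is
   divided by its baseline RPM from replicate reference cell-line runs.
   Using the raw HK readout while target genes are background-subtracted
   is intentional — it follows the normalization scheme's definition
   exactly, and at HK expression levels the background is negligible.
3. *Scaling.* The sample's normalization ratio is the median of its HK
   ratios (midpoint convention for even counts); nRPM divides the
   background-subtracted counts by it. An HK gene with zero counts
   contributes a ratio of 0 to the median — the ≥6-detected QC rule is
   the guard against a majority of dropouts. A sample whose median ratio
   is 0 cannot be scaled and is excluded with a warning.

The scheme is exactly depth-equivariant: multiplying all of a sample's
counts by c (with zero NTC) scales HK ratios and background-subtracted
counts equally, leaving nRPM unchanged. This is verified to 1e-12
relative, and the full arithmetic is checked elementwise-exactly against
an independently coded formula-by-formula oracle.

The baseline HK RPM profile is a required input and is never recomputed
(the reference cell-line replicate runs that define it are external to
the package); the synthetic generator fabricates a self-consistent one.

## Differential expression

Expression is log2(nRPM + pseudocount); the pseudocount defaults to 1
nRPM (configurable) so zeros map to 0 rather than −∞.

The per-gene test is a moderated t. For an unpaired contrast the
coefficient is the difference of group means with the pooled two-group
variance (d_g = n_a+n_b−2); a paired contrast is fit as a one-sample
test on within-patient differences (d_g = n−1), the blocked linear model
appropriate for tumor/adjacent pairs. Empirical-Bayes shrinkage squeezes
each s²_g toward a common prior s₀² on d₀ df, with (d₀, s₀²) estimated
by moment-matching the log sample variances to a scaled F distribution:
the mean and variance of log s²_g are linear in digamma/trigamma terms,
so the fit reduces to one trigamma inversion (Newton iteration). When
the moment equation has no positive solution the prior df is infinite
(represented as 1e6) and every variance shrinks fully to s₀². The
moderated t uses d₀+d_g df. Limits: d₀=0 reproduces the ordinary t
(verified to 1e-10); d₀→∞ gives a pooled-variance z-like statistic. The
implementation is cross-checked against an independently coded oracle
(different root-finder, loop-based statistics) to 1e-8 and against the
Bioconductor reference implementation of the same estimator to 1e-6 on a
shared fixture.

Genes with zero residual variance in a contrast are excluded from
hyperparameter estimation and reported with p = NA, uncalled; degenerate
variances would otherwise poison the moment fit.

Fold change is computed on the log2 scale as the difference of group
means and reported with the signed convention `±2^|Δ|`, so
|fold change| ≥ 2 ⇔ |log2 FC| ≥ 1. The DEG rule is |FC| ≥ 2 (inclusive)
AND p < .05 (strict), on raw p-values; no multiplicity correction enters
the call, but Benjamini–Hochberg q-values are emitted for information.
Swapping contrast groups negates t and log2 FC and leaves p and the DEG
set unchanged.

DEG-list intersections are exact Venn partitions (2 or 3 sets) with
lexicographic ordering inside regions, checked against brute-force
membership enumeration. Classical pooled-variance Student's t-tests are
provided for per-gene group annotations; degenerate zero-variance input
returns (0, 1) for equal means and (±∞, 0) otherwise, flagged.

## Signatures and association

A signature score is the unweighted mean of log2 nRPM over a gene
class; it is exactly affine-equivariant (shifting every member by c
shifts the score by c). The default four classes ship as editable
definitions with the named members (checkpoint: CD274, PDCD1LG2, IDO1;
lymphocyte infiltration: PTPN7, IL10RA, GZMK, CD52, CD2, CCR5, CCL5;
TCR coexpression: GPR18, IL7R, CD3G, CD3D, CD8B; type II interferon:
CXCL10, CIITA, IRF1, PSMB9); real panel classes may be larger.

Association is one logistic regression per signature (not a joint
model): binary primary-cancer origin ~ score + age + gender, plain MLE
with two-sided Wald p for the score term. The outcome coding is always
explicit (e.g. lung = 1 vs breast = 0); no default mixes a third cancer
type in. Gender is a single indicator and age enters in years
untransformed; inference on the score is invariant to relabeling gender
or affinely rescaling age. With ~25-sample cohorts quasi-complete
separation is likely; the default deliberately does **not** switch
estimators silently — it flags non-convergence and reports the direction
of separation. A Jeffreys-prior (Firth) penalized fit, implemented as
penalized Newton iteration with hat-value corrections, is available via
`method="firth"` for finite estimates under separation.

The PCA embedding is computed on gene-centered (optionally
unit-variance-scaled, off by default) log2 nRPM restricted to a gene
set, with a deterministic sign convention (each component's
largest-magnitude loading is positive); verified against an independent
eigendecomposition of the sample covariance to 1e-8.

## Synthetic cohorts

The generator realizes the assumptions the analysis implicitly makes,
with the default cohort mirroring the target study design: 25 patients
(12 lung, 6 breast, 7 colorectal; published ages, genders and
prior-treatment flags), 13 of them with a paired adjacent-tissue sample
(10 lung, 3 breast) — 38 samples plus one NTC.

* Gene baselines b_g ~ N(8, 2) on the log2-count scale; HK baselines
  N(9.5, 0.3) with near-zero biological noise (sd 0.05), reflecting
  high, stable control expression.
* Counts are negative binomial (dispersion 0.05 by default; Poisson at
  0) around 2^(b_g + lib_s + u_{g,patient} + effects + ε), with log2
  library factors lib_s ~ N(0, 0.3) and residual biological noise
  ε ~ N(0, 0.4) for target genes.
* Patient pairing is a per-gene random intercept u_{g,patient} ~
  N(0, 0.5) shared by both tissues of a patient and absent from HK
  genes: it creates within-pair correlation gene by gene (making the
  paired design strictly more powerful than unpaired) without shifting
  a sample's global amplitude.
* Background: per-gene rates ~ Gamma(2, 2.5) (mean 5 counts) drive both
  the NTC column and an additive Poisson term in every sample, so
  background subtraction is exercised with a correlated, imperfect
  estimate.
* Planted effects are log2 mean shifts on (gene set × sample stratum):
  the default plants +2 on three tumor-marker genes and −2 on six
  adhesion/regulation genes in tumors vs adjacent tissue, and +1.5 on
  all four immune classes in lung-derived tumors — the magnitude regime
  the |FC| ≥ 2 calling rule targets. Every effect is emitted in a truth
  TSV; benchmarks consume the truth record, never generator internals.
* QC stats: mapped reads are the count total divided by the on-target
  ratio (U(0.85, 0.95)) and by the gene-assignment fraction
  (U(0.55, 0.7)) — mapped reads exceed gene-assigned counts because
  duplicates and off-amplicon reads map but are not counted.
* Identical seeds give byte-identical outputs; all randomness flows
  from `numpy` seed sequences spawned from the single config seed.

What the generator does **not** emulate: FFPE degradation gradients,
GC/amplicon efficiency bias, batch effects beyond library size, and
compositional coupling between genes. Passing benchmarks therefore
demonstrate correctness of the analysis under its own assumptions, not
robustness to those artifacts on real tissue data.

## Validation surface and problem sizes

`scripts/acceptance.py` (and the mirror tests) recompute, from a single
seed: elementwise-exact oracle agreement of normalization on twenty
395×10 matrices; depth equivariance at scale factors 0.5/2/10; the
8-row QC truth table; moderated-t analytic limits, plus null calibration
on 50 replicates of 200-gene 2×5 null data (type-I error inside the 99%
binomial band around 0.05); planted-DEG recovery at 10 pairs with 20
genes at |log2 effect| 2 and within-pair noise ≈ 0.5 (sensitivity ≥ 90%,
FPR ≤ 7%); 100 random Venn triples against brute force; signature-score
exactness and affine equivariance to 1e-12; and logistic recovery on 200
cohorts of n = 500 with true score log-odds 1.0 (mean coefficient within
±0.2, 95% CI coverage ≥ 93%). These sizes keep the full run under ten
seconds while leaving each statistical check comfortably powered.

An ingest path accepts an externally supplied expression matrix in place
of the simulator. Because deposited panel matrices may already be on the
nRPM scale, the pipeline applies a detection heuristic — per-sample
medians of HK ratios all within 15% of 1 indicate already-normalized
data — and skips normalization accordingly.

## Known limitations

* The moderated-t implementation covers two-group (paired/unpaired)
  contrasts, not arbitrary design matrices.
* Between-run batch correction beyond the HK-ratio scheme is out of
  scope, as is any count-level precision weighting (voom/edgeR-style).
* Gene-set enrichment statistics are not computed; DEG-list Venn
  intersections are the only set-level analysis.
* The Firth fallback reports Wald-type intervals; profile-penalized
  likelihood intervals are not implemented.
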
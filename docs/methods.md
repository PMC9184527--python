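# Methods

This note documents the statistical models implemented in `breedscan`, the
assumptions behind them, what the synthetic-data generator does and does not
emulate, and the numerical and design choices that were genuinely open.

## Data model

The unit of analysis is an *era panel*: hybrids released over a span of
decades, genotyped at biallelic SNPs (additive coding 0/1/2 copies of the
alternative allele; missing calls allowed), with year-of-release metadata,
plus a multi-environment trial table of grain number (GN, m⁻²) and yield
(kg ha⁻¹) per hybrid × experiment, trait covariates at the genotype level
(vegetative duration in equivalent days at 20 °C, silk number, rh_PAD — the
relative canopy depth of the layer holding half the leaf area, and the
normalized ear-layer intercepted light), and per-experiment environmental
indices (mean soil water potential Ψ in MPa, intercepted radiation R_int in
MJ m⁻²). All genomic intervals are 0-based half-open; VCF input is converted
on read.

## Quality control and relationship matrices

SNPs with minor allele frequency strictly below 0.05 (computed over
non-missing calls) or missing in strictly more than 20 % of hybrids are
removed; remaining missing calls are imputed with the per-SNP modal genotype
(ties toward the smaller count). Modal imputation is deterministic and
adequate at ≤ 20 % missingness; no haplotype model is used. QC is
idempotent.

The GRM is VanRaden method 1 (columns centered at 2p̂, cross-product scaled
by Σ2p̂(1−p̂) over polymorphic SNPs); IBS is the mean of (2 − |cᵢ − cⱼ|)/2.
Nei diversity per hybrid group is mean 2p̂(1−p̂) with the small-sample factor
2n/(2n−1). Genotype PCA centers columns (scaling by √(2p̂(1−p̂)) is optional
and off by default, documented because either convention is common); PC1's
sign is fixed to correlate positively with year. LD pruning is greedy within
50-SNP windows stepping by 5, dropping the later SNP of any pair with
r² > 0.2; parameters are conventions, exposed as arguments.

## Environmental scenarios

Nine covariates (light, Tmin, Tmax × three phenological phases) are
standardized, projected on principal components retaining ≥ 90 % of
variance, and clustered by PAM (BUILD then SWAP, Euclidean distance, ties
broken toward the lowest experiment index so the result is deterministic).
With k = 3 the clusters are named cool/warm/hot by ascending mean Tmax.
Water class is thresholded separately: WW strictly above −0.1 MPa, WD
otherwise — the boundary value itself is assigned to WD. New experiments get
the temperature class of the nearest medoid in the stored PCA basis.
Whether water status should enter the clustering itself was open; it is
implemented as a separate threshold per the two-step description of the
scenario definition.

## Genotype means, gain, variance partition, factorial regression

BLUEs come from y = hybrid (fixed) + experiment (random intercept) + ε
fitted by REML. The likelihood is profiled on the ratio λ = σ²_exp/σ²_ε via
the eigendecomposition of the experiment incidence Gram matrix and optimized
by bounded scalar search to 10⁻⁸ on log λ (checked against
`statsmodels.MixedLM` in the tests). Groups with fewer than two experiments
fall back to arithmetic means with a warning. Genetic gain is the OLS slope
of the BLUE on year with a two-sided t test.

The GN partition uses sequential (type-I) sums of squares in the written
model order — covariates (if any), year, hybrid, scenario, experiment,
year × scenario — converted to proportions of the total corrected SS.
Type-I is the default because the model is a nested "partitioned into"
narrative; order sensitivity is inherent and surfaced (reversing the order
moves attribution but not the residual). Forward selection and backward
elimination at F-test α = 0.05 are optional; backward never removes a term
whose marginal rank is zero (e.g. year under the hybrid factor), so
attribution in the written order is preserved. α = 0.05 is a convention; no
other threshold is documented for this procedure.

Factorial regression adds genotype-specific slopes on centered Ψ and R_int
on top of the main-effects model, each block admitted by an F test at
α = 0.05. Because the panel-mean slope is aliased with experiment main
effects, the interaction block uses sum-to-zero coding on the hybrid axis:
β₁ and β₂ are *deviations from the panel-mean sensitivity*. Contrasts
between genotype groups are unaffected by this identification choice.

## Bayesian networks

Scenario-specific genotype means (centered/scaled) are scored with the BGe
marginal likelihood using a minimally informative normal-Wishart prior:
prior mean zero, α_μ = 1, Wishart imaginary sample size α_w = n_vars + 2,
prior scale T = α_μ(α_w − d − 1)/(α_μ + 1)·I. These are the standard
minimal-information choices for a score described only as "non-informative".
The per-family score is the ratio of joint-subset marginal likelihoods; the
tests verify equality across Markov-equivalence classes on all 543 four-node
DAGs and agreement with an independently coded matrix-normal/Wishart closed
form.

Search is TABU over add/delete/reverse moves with a visited-structure tabu
list (length 10), taking the best non-tabu move even when not improving and
returning the best structure seen; ties break on lexicographic move order so
the search is deterministic given the column order. Constraints: arcs into
year of release are blacklisted, as are arcs from grain number to traits
determined during the vegetative and flowering periods; the constraint list
is user-editable. Bootstrap averaging learns each of B = 500 row-resamples,
tabulates arc strengths (fraction of networks containing the arc in either
direction) and directions, and keeps arcs above a data-driven threshold that
minimizes the L1 distance between the empirical strength CDF and an
idealized 0/1 CDF; a fixed threshold (e.g. 0.5) is available. If majority
orientations conflict into a cycle, the weakest arcs in the cycle are
dropped. A consensus network across scenarios is the arc intersection of the
per-scenario averaged networks. Predictive ability is 10× repeated 5-fold
CV of each node on its fitted linear-Gaussian parents; root nodes report
NaN.

## Selection scans

*Temporal mixed-model scan.* Year of release is the response, allele count
the regressor: year = μ + b·x + u + ε with u ~ N(0, σ²_g K), K the GRM.
The null model (b = 0) is fitted once by REML on the eigendecomposition of
K (+10⁻⁸ ridge); every SNP is then tested by GLS with the null variance
ratio held fixed — the EMMAX approximation, standard and orders of magnitude
faster than per-SNP REML, with an exact per-SNP mode behind a flag (the
exact mode re-estimates the ratio from the SNP-inclusive model and tests at
that ratio). Wald-type two-sided p values use the t distribution on
n − p − 1 df; with K = I the scan reproduces per-SNP OLS exactly. The
flagging threshold is −log₁₀ p > 3.5.

*XtX-style differentiation scan.* The published Bayesian XtX is an external
MCMC method; this package implements a moment-based analogue that preserves
its defining property — allele-frequency differentiation standardized by the
genome-wide covariance structure. Per group g ∈ {old, recent},
z_g = (p̂_g − π̂)/√(π̂(1−π̂)) with π̂ the pooled frequency; Ω̂ = cov(z_old,
z_recent) over an LD-pruned SNP subset; XtX = zᵀΩ̂⁺z. Because pooled
centering makes n_old·z_old = −n_recent·z_recent an identity, Ω̂ has rank 1
and the Moore–Penrose pseudo-inverse (not the inverse) whitens on its
support; the statistic is invariant to allele recoding and zero when group
frequencies coincide. Monomorphic pooled SNPs score 0 and are flagged
uninformative. The top ⌈0.05 %⌉ of informative SNPs are flagged (order
statistics, stable tie-break). This substitution — frequentist moment
analogue for the Bayesian MCMC statistic — is deliberate and is the one
methodological replacement in the package.

Flagged SNPs from either scan (union by default; intersection available)
become 1-bp intervals merged within 500 kb per chromosome into RUS; how
flagged SNPs become regions is not standardized anywhere, so both knobs are
parameters and region names record the contributing methods.

## Colocalization enrichment

The null redraws, m = 100,000 times, one random region per QTL with the same
length: chromosome chosen with probability ∝ (length − l + 1), start uniform
over valid positions; random regions may overlap each other and the original
QTL positions (no exclusion — the simplest null consistent with
length/number matching). Overlap is half-open (abutting intervals do not
overlap) and each query region counts at most once; the vectorized counter
is checked against a brute-force all-pairs oracle on fuzzed inputs. The
permutation p is (b+1)/(m+1) with b the number of null values ≥ the observed
count (one-sided enrichment by default, depletion by flag); a chi-square of
observed vs null-mean expected is reported alongside because both summaries
are conventional, with the permutation p primary. An optional monotone
bp↔cM map supports genetic-scale matching; physical scale is the default.
The same null drives the old-vs-recent allele-frequency-shift contrast
(mean |Δp̂| over SNPs inside the region union).

## Allelic effects

`predict_field_effects` is a pure lookup of per-scenario effects per field,
with per-QTL min/max/mean/SD over fields; per-QTL means are exactly the
scenario-frequency-weighted convex combinations of the table's effects
(tested as an identity). `favorable_freq_shift` computes favorable-allele
frequencies (the allele with positive effect in cool/WW) in the n oldest and
n most recent hybrids, groups formed by stable sort on year with ties broken
by hybrid id; frequencies use non-missing calls only. Effect summaries are
unweighted over fields (no yield weighting is documented for this summary).

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the rest of the package is validated against.

* **Panel.** 60 hybrids with years evenly spanning 1950–2015; 20,000 SNPs
  placed uniformly on 10 maize-scale chromosomes. Neutral frequencies follow
  a two-ancestry Balding–Nichols model (F = 0.08, ancestral frequencies
  Beta(0.55, 0.55)) whose mixing weight is logistic in year (midpoint 1996,
  scale 1.5 yr — a late, fairly abrupt germplasm shift). These values were
  calibrated once so the realized panel reproduces the documented era-panel
  statistics: PC1–year R² ≈ 0.70 and mean pairwise IBS ≈ 0.72 after QC.
  50 selected loci get logit-linear frequency trends of 0.05 yr⁻¹.
  Genotypes are binomial(2, p); missingness is MCAR at 2 %.
* **Environments.** Scenario temperature means are cool/warm/hot =
  Tmin 15/17/18 °C, Tmax 25/28/30 °C with small phase offsets; phase light
  sums scale mildly with warmth; Ψ is drawn above −0.1 MPa (WW, mean −0.05)
  or below (WD, mean −0.4). Within-scenario dispersion (0.6 °C, 8 %
  relative light) is not documented anywhere and was set once so that the
  planted scenario classes are recoverable by the clustering stage, which is
  the premise of scenario typing. 26 experiments over the six scenarios by
  default.
* **Trial.** GN = intercept + year trend + scenario effect + experiment
  deviation + scenario-specific year slopes (the year × scenario
  interaction) + QTL scenario effects + G×E noise + residual; yield =
  GN × grain weight (0.30 g) × 10. The year trend (101 kg ha⁻¹ yr⁻¹ of
  yield by default) is mediated through a known trait DAG — year → vegetative
  duration → GN, year → silk number → GN, year → rh_PAD → ear-layer light →
  GN — with shares 20/20/48 % and 12 % direct; the trend contributed by
  trending QTL frequencies is compensated in the direct term so the total
  realized gain equals the configured value. Variance components
  (genetic 1.4·10⁵, experiment-within-scenario 2.0·10⁵, G×E 4·10⁴, residual
  4·10⁴ GN²; per-scenario slope SD 7 GN yr⁻¹) were calibrated once so the
  realized sequential partition matches the documented study-scale shares
  (year ≈ 74 % of the genetic SS, scenario ≈ 76 % of the environmental SS,
  year × scenario ≈ 1 % of the total). Constitutive QTLs sit at planted
  trending loci, adaptive QTLs at neutral loci; the default effect table has
  three scenario-stable QTLs (0.10–0.24 t ha⁻¹, mean ≈ 0.18) and three
  sign-flipping ones (−0.16 to +0.17 t ha⁻¹).
* **Not emulated.** Linkage disequilibrium between loci (positions are
  independent draws, so LD pruning exercises only the window mechanics, not
  realistic haplotype structure); pedigree; spatial field trends (the BLUE
  stage has one random factor, not a spatial surface); weather time series
  (phase summaries are the primitive); phenology (phase boundaries are
  inputs). Consequently, passing tests demonstrate the estimators recover
  planted structure of the kind described — they do not validate behaviour
  under strong LD, spatial confounding, or missingness that is informative.

Everything is bit-reproducible from `SimConfig.seed`; each stage draws from
an independent child stream so stages can be re-run in isolation.

## Numerical choices and degenerate inputs

REML ratio search is bounded on log λ ∈ [−12, 12] with boundary checks; a
ratio at the lower bound is reported as zero genetic variance. Constant
responses raise rather than fit. GRMs get a 10⁻⁸ ridge before
eigendecomposition. Monomorphic SNPs: excluded from the GRM denominator
(warning), uninformative in XtX, untestable (p = 1) in the GLS scan.
Empty region sets give observed = 0 and p = 1 with a flag, not an error.
PAM, TABU and all tie-breaks are deterministic (lowest index /
lexicographic), so identical inputs give identical outputs irrespective of
seeds; seeds control only genuinely stochastic stages (simulation,
bootstrap, permutation, subsampling).

## Problem sizes

The bundled validation runs use a 60-hybrid × 20,000-SNP main panel and a
200-hybrid × 10,000-SNP panel for scan power, 26–84 experiments for the
trial analyses, 500-bootstrap network averaging, and 10⁴–10⁵ permutations
for the enrichment nulls. These sizes keep the full test suite and the
acceptance script in the minutes range on a single CPU while leaving every
statistical property measurable; all are parameters, and nothing in the
implementation caps larger inputs.

## Known limitations

Sequential SS attribution depends on term order (by design, surfaced in the
API). The factorial-regression sensitivities are identified as deviations,
not absolute slopes. The XtX analogue shares the spirit, not the posterior,
of the Bayesian statistic: its null scale is set empirically by the
top-quantile rule rather than by a sampling distribution. The BLUE stage
ignores spatial structure within experiments. Bootstrap model averaging
learns each resample with the same deterministic search, so averaging
reflects data resampling only, not search multimodality.
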
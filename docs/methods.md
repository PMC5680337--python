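# Methods

## The experiment being modelled

A diversity panel of inbred accessions (default 300; the machinery is
sized for a few hundred) is grown under low irradiance (LL) and switched
to high irradiance (HL).  Φ_PSII — the light-use efficiency of
photosystem II electron transport, a dimensionless quantum yield in
[0, 1] — is imaged three times per day (9.00, 11.30, 14.30 h; the
photoperiod starts at 8.00 h) for two LL days and four HL days: 18 time
points, three replicate plants per accession.  All schedule constants
are parameters of `MeasurementSchedule`.

## Synthetic data generator

**Genotypes.** Balding–Nichols structure: each SNP draws an ancestral
frequency p ~ U(0.1, 0.9); each of `n_subpops` subpopulations draws its
frequency from Beta(p(1−F)/F, (1−p)(1−F)/F) with F = Fst (default 0.1,
3 subpopulations — mild continental structure).  Accessions are fully
homozygous (dosage 0/2), matching a selfing species; heterozygous draws
are optional.  SNPs below the MAF threshold (default 0.05) are redrawn,
so a simulated panel is born filtered.  Positions are uniform per
chromosome (5 chromosomes of 30 Mb).

**Phenotypes.** For plant r of accession i at time point t

    Φ_irt = μ(t) + Σ_q a_q(t)·x_iq + g_i(phase(t)) + e_irt

with one polygenic draw g ~ N(0, σ²_g K) per phase (LL/HL responses are
distinct genetic traits; within a phase the polygenic effect is
persistent), and i.i.d. Gaussian residuals.  Heritability is defined on
accession means, matching a GWAS run on accession means: the generator
solves σ²_g = h²·V and σ²_e = r(1−h²)·V per phase, where V is the
target accession-mean variance (defaults 4×10⁻⁴ in LL, 2.5×10⁻³ in HL —
small variation before stress, substantial after) and r the replicate
count.  `qtl_effect_for_pve` converts a requested fraction of
accession-mean variance into a per-allele effect via a² = pve/(1−pve) ·
V / Var(x).  Values are clipped to [0, 1]; under defaults clipping
touches < 1% of records (asserted in tests).

**Baseline curve μ(t).** Piecewise: constant 0.78 in LL; at HL onset a
drop of 0.22 followed by exponential recovery of 60% of the drop with a
30 h half-life; a 0.01 dip after the first slot of each day.  The
within-day component is a free modelling choice (no numeric within-day
dynamics are available to constrain it); all constants are arguments.
QTL temporal profiles are step functions: LL-only, early-HL (HL days
1–2), late-HL (HL days 3–4), constitutive — effects are exactly zero
outside the active set.

**What the generator does not emulate:** temporal autocorrelation of
residuals within a day, spatial/imaging artefacts, linkage
disequilibrium beyond what population structure induces (SNPs are drawn
independently), selection, and genotype-by-environment interaction
finer than the phase split.  Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to those real-data features.

## Kinship and heritability

Kinship is VanRaden-type: per-SNP standardized dosages Z (missing
mean-imputed), K = ZZ′/m, rescaled to mean diagonal 1 so the variance
ratio δ is comparable across panels, plus a 10⁻⁶ ridge for positive
definiteness.

Broad-sense H² per time point comes from one-way random-effects ANOVA
among accessions: H² = (MS_A − MS_W)/(MS_A + (r̄−1)MS_W) with r̄ the
harmonic-mean replicate count (tolerates unbalance), truncated to
[0, 1].

Narrow-sense h² is REML in the single-kernel model y = μ1 + g + e.  K
is eigendecomposed once; the restricted likelihood profiled over μ and
σ²_g is one-dimensional in δ = σ²_e/σ²_g and is maximized on a
100-point log grid over [10⁻⁵, 10⁵] followed by bounded Brent
refinement (the grid protects against the flat likelihoods of
near-zero-heritability traits; a boundary flag marks optima at the grid
edge).  h² = 1/(1+δ).  The spectral likelihood agrees with a dense-
matrix evaluation to 10⁻⁸ (tested).  Estimates around a true
accession-mean h² of 0.4 average ≈ 0.37–0.40 at n = 300: the small
downward shift comes from estimating K from the same finite SNP panel
and from boundary truncation, and is well inside the ±0.05 validation
band.

## Single-trait scan

Default is the EMMAX approximation: δ is estimated once under the null
and fixed; y, the intercept and every SNP are rotated by U′ and
weighted by (λ_i+δ)^(−1/2); each SNP is then ordinary weighted least
squares, tested by F with (1, n−2) df using the per-SNP residual
variance — better calibrated than a Wald χ² at moderate n.  A
`stat="chi2"` Wald variant using the null-model variance exists; it is
the statistic to which the multi-trait model reduces at one trait, and
the two scans then agree to optimizer precision.  `mode="exact"`
re-estimates δ per SNP by REML.

The approximation is excellent in the bulk (median |Δlog₁₀p| < 0.01 vs
per-SNP REML at n = 200) but individual SNPs strongly aligned with
population structure can deviate by a few tenths of a log unit at small
n; this worst-case behaviour shrinks with n and is why `exact` mode
exists.  Missing dosages are mean-imputed per SNP so n is constant
across SNPs; p-values are floored at 10⁻³⁰⁰ before log₁₀.  λ_GC is the
median association χ² over the χ²₁ median; QQ coordinates use the
i/(n+1) convention.

## Derived traits and the MTMM

Genotypic means are accession × time-point averages restricted to one
phase, optionally z-scored per column; principal-component traits come
from the SVD of the column-centred matrix with each component's sign
fixed so its largest-magnitude loading is positive (reproducible across
LAPACK implementations).  Curve parameters per plant, from HL points
only, with time in hours since the irradiance step (the natural unit
for a rate; day indices would hide the within-day spacing):

- max_slope = max (Φ(t₂)−Φ(t₁))/(t₂−t₁) over HL pairs on different days,
- early_recovery = max Φ on HL day 2 − min Φ on HL day 1,
- late_recovery = max Φ on HL days 3–4 − max Φ on HL day 2,

then accession means.  All three are invariant to adding a constant to
Φ.

The MTMM is vec(Y) ~ N(1μ′, V_g ⊗ K + V_e ⊗ I), p ≤ 6 traits.  On the
eigenbasis of K the rows become independent p-vectors with covariance
λ_iV_g + V_e, so the restricted likelihood (μ profiled by GLS) is cheap
to evaluate; V_g and V_e are parameterized by Cholesky factors with
log-diagonals and maximized numerically (Nelder–Mead, then a Powell
polish).  This direct optimization replaces EM/AI-REML iterations: at
desk-scale trait counts it is simpler and its objective is identical.
With the null covariances fixed, each SNP's p effects are estimated by
GLS jointly with the mean and tested by Wald χ² with p df (one null
fit for the whole scan, as in the single-trait approximation).  At
p = 1 the null fit is delegated to the single-trait spectral REML, so
the reduction to the single-trait scan is exact.  Null Wald statistics
match χ²₃ (KS p > 0.01 at 1000 SNPs, tested).

## QTL calling and temporal classes

A SNP is called when −log₁₀p ≥ 4 at ≥ 3 LL time points or ≥ 3 HL time
points (phases never pooled).  Windows of ±100 kb (±20 kb variant)
around called SNPs merge when overlapping *or touching*; the interval's
top SNP is its maximal −log₁₀p (ties to the smaller position); numbering
is genome-wide by chromosome then position.  Classification uses the
top SNP's significant time-point set: LL (only the LL rule met), LL+HL
(both), and among HL-only QTLs earlyHL / lateHL when all HL hits fall
within / after the first `hl_day_split` HL days (default 2 of 4), else
persistentHL.  The day split is an explicit operationalization of
"early" vs "late" — no numeric rule exists to inherit — and is a
parameter.  Judging significance on the top SNP alone matches the
per-SNP heat-map view; an any-SNP-in-window option is deliberately not
the default.

## Candidates and follow-up

A gene is a candidate when its body intersects a QTL interval (1-based
inclusive; intersection rather than containment maximizes agreement
with "genes within the window").  Five criteria: ontology match;
co-expression max r² strictly > 0.8; rosette expression; literature
function; and a polymorphism in the gene whose allele-frequency
difference between the top and bottom 15 accessions (ranked by mean
HL-phase Φ_PSII; boundary ties broken by accession id) is ≥ 0.6.  The
0.6 gap is this package's quantitative stand-in for "segregates between
the extreme groups" — any threshold must be chosen, and it is exposed
as a parameter.  Score ≥ 3 of 5 ⇒ priority.

Haplotypes are identical dosage strings over a region among accessions
with complete calls; groups at frequency > 0.04 are kept and compared
by pairwise two-sided t-tests (Welch by default — haplotype groups are
unbalanced almost by construction; pooled-variance is available).  No
multiplicity correction by default (a Bonferroni option exists).

Quantitative complementation: per-plant response = mean HL − mean LL
Φ_PSII; two-way fixed-effects ANOVA (statsmodels OLS, type-II sums of
squares — robust to mild imbalance from plant loss); the maternal ×
tester-allele interaction is the test.  qPCR: technical replicates
averaged per biological sample; expression = 2^−(Ct_target −
mean(Ct_ref1, Ct_ref2)) (geometric-mean reference normalization, the
ΔCt model with assumed efficiency 2); fold change = HL expression over
the genotype's LL average; one-way ANOVA across genotypes.  Amplifi-
cation-efficiency calibration is out of scope.

## Numerical and reproducibility choices

- Seeds: every generator is a pure function of its arguments including
  the seed; the pipeline derives per-stage substreams from one master
  seed via crc32(stage name) → SeedSequence spawn keys, so a JSON
  manifest re-run is bit-identical (hash-verified in tests).
- Degenerate inputs: monomorphic panels are rejected for kinship;
  constant SNP columns get p = 1 with a `tested=False` flag; the
  interaction ANOVA refuses cells with < 2 plants; t-test groups
  reduced below 2 phenotyped members are dropped with a warning.
- Validation problem sizes (n = 300 accessions, 1000–2000 SNPs, 50–100
  Monte-Carlo replicates) were chosen so every distributional check has
  sharp expectations while a full validation run stays around a minute;
  all sizes are arguments of the experiment functions.

## Known limitations

- No covariates or fixed-effect PCs in the scan (kinship is the only
  confounding control); no dominance or multi-kernel variance models.
- SNPs are simulated without LD, so window-merging behaviour on real
  panels (where LD decay varies by locus) is exercised only through
  the synthetic geometry of called-SNP positions.
- The MTMM is limited to 6 traits and one kinship; no G×E decomposition
  beyond the V_g/V_e split.
- LD-adaptive window sizing and live annotation-database queries are
  deliberately out of scope; evidence comes from a supplied table.
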
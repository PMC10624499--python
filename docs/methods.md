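# Methods

## Statistical model

Two-sample summary-data MR treats each genetic variant *j* as an
instrumental variable. The observed quantities are the variant-exposure
association β̂_Xj with standard error se_Xj (from one GWAS sample) and the
variant-outcome association β̂_Yj with se_Yj (from a second, non-overlapping
sample), aligned to a common effect allele. The working model is

    β̂_Xj ~ N(γ_j, se_Xj²),   β̂_Yj ~ N(Γ_j, se_Yj²),   Γ_j = θ·γ_j + α_j

with θ the causal effect of one SD of exposure (on the log-OR scale for
binary outcomes), γ_j the true variant-exposure effect, and α_j a direct
(horizontally pleiotropic) effect. IVW assumes α_j = 0; MR-Egger allows a
nonzero mean α under InSIDE (instrument strength independent of direct
effects); the GLS variants allow corr(β̂_Yj, β̂_Yk) = r_jk from linkage
disequilibrium. Estimation errors are assumed independent between the two
samples (the two-sample design).

## Estimators and inference

All estimators are closed-form weighted/generalized least squares, written
out from the normal equations (statsmodels is used only as an independent
cross-check in the test suite):

| method | estimand | dof for Q |
|---|---|---|
| Wald ratio | β̂_Y/β̂_X, se = \|se_Y/β̂_X\| (first-order delta) | — |
| IVW | origin regression, weights 1/se_Y² | J − 1 |
| IVW (correlated) | GLS with Ω_jk = se_Yj·se_Yk·r_jk | J − 1 |
| MR-Egger (± correlated) | adds intercept; variants recoded to β̂_X ≥ 0 | J − 2 |
| MVMR-IVW | K-exposure weighted regression, no intercept | J − K |

Two effects models are available and explicit everywhere. `fixed` uses the
model-based se with normal inference. `multiplicative_random` (the pipeline
default, the conservative choice) inflates the se by max(1, √(Q/dof)) and
uses t inference with the Q degrees of freedom. The Egger intercept is
always tested with t (J − 2). The applicability ladder — Wald at J = 1, IVW
from J = 2, Egger from J = 3 — is enforced by the pipeline with notes
rather than errors, since real per-gene arms routinely mix all three.
Odds-ratio transforms (exp of beta and CI bounds) happen only in the
reporting layer and forest tables, never inside estimation.

The β̂_X ≥ 0 orientation recoding for Egger propagates sign flips into the
LD matrix (r_jk → s_j·s_k·r_jk) in the correlated variant. All estimators
are invariant to simultaneous sign flips of (β̂_Xj, β̂_Yj), i.e. to allele
recoding.

## Selection chain

Per analysis arm: p-value thresholding (strict p < α, default 5e-8) →
cis-window extraction (gene body ± 5 kb, inclusive ends) or MHC exclusion
(chr6:24,000,000–35,000,000, GRCh37, inclusive; both overridable) → greedy
LD clumping → harmonization → Steiger filtering → strength metrics →
estimation → heterogeneity → per-family BH-FDR. Audit counts at every stage
are non-increasing by construction and written with each run.

Clumping repeatedly takes the smallest-p remaining variant and discards
remaining variants with r² strictly above the threshold against it
(0.01 for trait arms, 0.4 for cis-eQTL arms in the study design this
package emulates). Ties on p break deterministically by chromosome,
position, then variant ID. LD is always consumed precomputed; the package
never derives it from genotypes.

Steiger filtering compares per-variant variance explained computed by the
t-statistic identity R² = F/(F + n − 2) on both sides and drops variants
with R²_Y > R²_X (strict; ties retained). For binary outcomes the same
formula is applied on the log-OR scale — an observed-scale approximation,
flagged in output metadata. An optional Fisher-z significance test for the
R² difference is available behind a flag but off by default, since the
plain comparison is the documented procedure.

## Harmonization

Exposure and outcome records are intersected on variant ID and resolved
per variant: exact allele match (kept), effect/other swap (outcome beta
negated, eaf reflected), strand complement (then the same two rules).
Palindromic variants (A/T, C/G) cannot be disambiguated by alleles alone:
they are dropped when either frequency is missing or within the ambiguity
window of 0.5 (default 0.08, i.e. eaf ∈ [0.42, 0.58], a standard
convention), and otherwise accepted only when the two frequencies fall on
the same side of 0.5 after the candidate alignment — the package never
silently guesses strand. Indel alleles bypass palindromic and strand logic
(exact/swap matching only). Every decision is logged in a per-variant audit
table. A corollary worth knowing: a palindromic variant whose frequency sits
inside the ambiguity window is dropped even when a dataset is harmonized
against itself.

## Data conventions

Coordinates are 1-based inclusive throughout; BED gene panels are converted
at read time. P-values of exactly 0 are floored at 1e-300 to keep
downstream logs finite. Missing effect-allele frequency is tolerated at
read time; operations that need it (palindromic checks, frequency-based R²)
fail loudly rather than impute. Written tables use shortest round-trip
float formatting, so write→read reproduces every numeric field bit-for-bit
and identical runs produce byte-identical outputs.

Ω repair for the GLS estimators: eigenvalues below 1e-8·λ_max are floored
there with a warning counting clipped modes, and a conditioning error is
raised if the spectrum is degenerate beyond repair. At the r² < 0.4 pruning
used for cis arms Ω is well-conditioned in practice; the repair exists so
synthetic stress tests have defined behavior.

## The simulator

`simulate_study` draws maf_j ~ U(maf_range), γ_j from `gamma_dist`, α_j per
pleiotropy regime, sets Γ_j = θ·γ_j + α_j, and adds two-sample estimation
noise with se = 1/√(2·n·maf·(1 − maf)) on the standardized scale (binary
outcomes: same form on the log-OR scale with n_y as effective sample size).
Under `("ar1", rho, block_size)` the within-block noise correlation is
rho^|j−k| and exactly that matrix is emitted as the study's LD matrix.
Reverse-causation variants have their primary effect on the outcome with
induced exposure effect θ_rev·Γ_j (θ_rev defaults to θ). Everything is
reproducible bit-for-bit from the config seed.

Default parameter choices, with rationale:

- `gamma_dist = ("truncnormal", 0, 0.05, 0.03)`: effect sizes N(0, 0.05²)
  truncated at |γ| > 0.03, the approximate genome-wide detectability limit
  (z ≈ 5.45 times a typical se) at the default n = 1e5 — so simulated
  instruments actually pass the p < 5e-8 filter they are subjected to. The
  implied mean F statistic (~130–190) matches what large lipid-GWAS
  instrument sets report.
- `maf_range = (0.05, 0.5)`: common variants, the regime where the
  1/√(2n·maf(1−maf)) se approximation is appropriate.
- Directional pleiotropy is oriented to the exposure-increasing allele:
  α_j = sign(γ_j)·δ_j with δ_j ~ N(μ, sd²). Direction is only meaningful
  relative to an allele orientation, and this is the orientation MR-Egger
  fits under; with a symmetric γ distribution an unoriented mean would
  cancel after recoding and "directional" pleiotropy would be
  indistinguishable from balanced.
- An InSIDE violation adds a γ-proportional component to α
  (`inside_strength`, default 0.1).

What the simulator does *not* emulate — and hence what passing tests do not
establish about real data: winner's curse from discovery/replication
splits, sample overlap between the two GWAS, population stratification,
non-collapsibility and case-control scale subtleties of binary traits
beyond the log-OR approximation, LD structure richer than block-AR(1), and
real allele/strand annotation errors (the generator emits clean A/G
variants unless asked for palindromic ones).

## Monte-Carlo operating characteristics

At the default study conditions (J = 100, n = 1e5 per sample) the test
suite and `scripts/acceptance.py` verify: 95% CI coverage within [93%, 97%]
at θ = 0.2; IVW type-I error within [3.5%, 6.5%] under balanced pleiotropy;
Egger-intercept recovery of the directional mean μ within Monte-Carlo
error; and Steiger filtering removing ≥ 90% of reverse and ≤ 10% of forward
variants. Problem sizes (1,000–2,000 replicates; 100–200 for the
per-arm sweeps) were chosen as the smallest giving Monte-Carlo standard
errors well inside the bands being checked.

One operating characteristic is worth stating precisely: the mean IVW
estimate carries the first-order weak-instrument attenuation
θ·F̄/(1 + F̄) ≈ θ·(1 − 1/F̄), because exposure effects enter the weights'
regressor measured with noise. At mean F ≈ 185 this is a relative bias of
≈ 0.5% — negligible for practical inference (and invisible to the coverage
check), but large compared with the Monte-Carlo se of a 1,000-replicate
mean, so exact mean-recovery assertions at that replicate count fail by
design rather than by defect. The acceptance suite reports the measured
mean unadjusted.

## FDR families

BH-FDR is applied to the primary (Wald/IVW) p-values only, within families
declared explicitly in the run configuration (`fdr_family`). Whether, say,
cholesterol-pathway and Rho-GTPase gene arms form one family or two is an
analysis decision the config must state; both are expressible and nothing
is pooled implicitly.

## Known limitations

- The GLS estimators require the user-supplied LD matrix to refer to the
  same population and allele coding as the outcome GWAS; the package can
  check symmetry and conditioning but not provenance.
- R² via F/(F + n − 2) on the log-OR scale (binary traits) is an
  observed-scale approximation; liability-scale conversion is out of scope.
- No proxy-variant lookup: variants absent from the outcome GWAS are
  dropped at harmonization (and counted in the audit).
- Weighted-median, mode-based and outlier-robust estimators (e.g.
  MR-PRESSO) are deliberately not implemented.
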
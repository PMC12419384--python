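# Methods

## Scope and design

`lipidmr` implements two inference arms that are usually run together in
drug-safety genetic epidemiology:

1. **Drug-target two-sample Mendelian randomization.** Genetic variants near
   a drug's target gene, associated with the drug's biomarker (LDL-C or
   triglycerides), serve as instruments for lifelong pharmacological
   modulation of that target; their effects on an outcome GWAS estimate the
   causal effect of the exposure on the outcome.
2. **Spontaneous-report disproportionality analysis.** Drug-by-event 2×2
   report counts yield ROR/PRR/χ² statistics and a conjunctive signal rule.

Both arms run end to end on synthetic inputs with known ground truth, which
is how the package is validated.

## Two-sample MR model

The structural model behind all estimators and the generator is

    β_gy,j = θ · β_gx,j + α_j + ε_j,

with β_gx,j the variant's effect on the exposure, β_gy,j its effect on the
outcome, θ the causal effect of interest, α_j a direct (pleiotropic) effect,
and ε_j mean-zero noise with the outcome GWAS standard error. Both GWAS
effects are observed with normal measurement error at their reported SEs;
the two samples are independent.

### Instrument selection

Per target gene, in this fixed order: (1) cis filter — variants on the
gene's chromosome within `window_bp` (default 100,000) of its boundaries,
ends inclusive; (2) significance filter — exposure p strictly below
`p` (default 5×10⁻⁸); (3) strength filter — per-SNP F = (β/se)² strictly
above `f` (default 10); (4) greedy LD clumping at `r2` (default 0.001):
rank by ascending p (ties by position, then SNP id), accept the best
remaining SNP, discard everything correlated above threshold with an
accepted SNP. Running the two marginal filters before clumping makes the
clump's accepted set the final analysis set, and the greedy pass equals the
rank-lexicographically smallest maximal independent set (the property the
exhaustive-search test asserts). The per-SNP F as squared z is used because
sample size and variance explained are not always available; when `eaf` and
`n` are present an R²-based variant (`f_statistic_from_r2`) is provided.

LD is consumed as a precomputed sparse r² table; the package never touches
genotype data.

### Harmonization

Exposure and outcome records are joined on rsID (positions are used only for
cis-filtering). Outcome alleles equal to the exposure's are kept as-is;
swapped alleles negate the outcome beta and mirror its allele frequency;
strand-complement pairs are translated first. Palindromic variants (A/T,
C/G) are kept only when both allele frequencies are known, both fall outside
[0.42, 0.58] (configurable), and both sit on the same side after alignment;
otherwise they are dropped, the conservative convention when strand cannot
be proven. Indels and multi-allelic rows are rejected at read time. Every
decision is recorded in an `action` audit column; dropped rows never enter
estimation.

### Estimators

* **Wald ratio** (single SNP): β_gy/β_gx, first-order SE σ_y/|β_gx|, with an
  optional second-order term adding the exposure uncertainty.
* **IVW**: weighted mean of ratios with w_j = β_gx,j²/σ_y,j², identical to
  weighted regression through the origin. Fixed-effect SE (Σw)^(-1/2) is the
  default headline estimate; the multiplicative random-effects SE
  (inflated by max(1, √(Q/(n−1)))) is always reported alongside when n ≥ 2.
* **Cochran Q**: Σ w_j (ratio_j − β̂)², χ²_{n−1}; not applicable below two
  instruments.
* **MR-Egger**: instruments oriented so β_gx ≥ 0 (needed for intercept
  identifiability), then weighted LS of β_gy on β_gx with intercept, weights
  1/σ_y². SEs carry the multiplicative overdispersion factor
  max(1, √(RSS_w/(n−2))); p-values use the t distribution with n−2 df (the
  established convention for this estimator), while CI bounds use the
  1.959964 normal quantile like every other method. Under constant per-SNP
  outcome SEs the intercept test is exactly the OLS t-test and is calibrated,
  which the balanced-pleiotropy type-I experiment confirms empirically.
* **Weighted median**: interpolated ratio at cumulative normalized IVW
  weight 0.5; SE by parametric bootstrap (both betas redrawn at their SEs,
  weights recomputed, SD over 1000 seeded draws).
* **Weighted mode**: argmax of a normal-kernel weighted density of the
  ratios on a 512-point grid spanning [min−3h, max+3h], bandwidth
  h = factor × 1.4826 × weighted MAD (factor default 1). Zero MAD (majority
  weight on one ratio) returns that ratio. Bootstrap SE as for the median.
* **MR-PRESSO**: observed global RSS uses leave-one-out IVW fits; the null
  distribution redraws outcome betas around their leave-one-out predictions
  and refits, 1000 replicates by default; global and per-SNP p-values are
  empirical ranks (hence bounded below by 1/(n_sim+1)), per-SNP p-values
  Bonferroni-corrected by the SNP count, flags at corrected p < 0.05, and
  the corrected estimate is IVW on the unflagged set. The distortion test is
  not implemented; the global and outlier tests cover the reported fields.
  Requires ≥ 4 instruments.
* **Leave-one-out**: IVW with each SNP removed, plus a flag for "all CIs
  exclude zero on the same side".

Estimators below their instrument minimum (3 for Egger/median/mode, 4 for
MR-PRESSO, 2 for Q and leave-one-out) return a not-applicable result (None /
NaN) rather than raising; a single-instrument target therefore yields a
Wald/IVW row with the other methods blank, mirroring how single-SNP targets
appear in published tables.

### Pipeline conventions

* Bonferroni familes are counted over drug classes tested (default: the
  number of configured targets, 6 in the standard layout); headline
  significance is the IVW p-value strictly below α/n. Other estimators are
  sensitivity analyses.
* Direction labels for continuous outcomes: significant negative β =
  adverse (lower cognitive score), significant positive = protective,
  otherwise null.
* The binary positive-control arm runs the same battery on log-odds-scale
  outcome statistics and exponentiates to odds ratios; the instrument
  validity verdict requires every target's IVW OR CI to lie below 1.
* Per-target failures (no instruments surviving a named stage, no SNP
  overlap) are carried as failed entries without aborting the run.
* All stochastic components (bootstraps, PRESSO simulations, generators)
  take explicit seeds; a full re-run with the same config writes
  byte-identical files.

## Disproportionality analysis

Counting unit is the report-drug pair by default (spontaneous-report
extracts are drug-rowed); a unique-report option exists and differs exactly
when one report names several drugs. ROR uses the Woolf log-scale CI; zero
cells raise by default, with Haldane–Anscombe 0.5-correction opt-in, so
counts are never altered silently. χ² is the 2×2 Pearson statistic with
Yates correction by default (both values are reported). The signal rule is
conjunctive: PRR ≥ 2 AND χ² ≥ 4 AND lower ROR bound > 1, boundaries
inclusive on the first two and strict on the third.

## Synthetic-data generator

The generator emulates the statistical structure of the real inputs at desk
scale, with defaults chosen once as the study conditions:

* 10 SNPs per target locus; true exposure effects uniform on (0.06, 0.15)
  SD per allele — uniform rather than normal so instrument strength is
  controlled by the range endpoints, and straddling the F = 10 boundary is
  a one-line change when the strength filter itself is under test.
* Per-SNP standard errors 0.005 for both GWAS, the scale implied by
  standardized-trait GWAS of a few hundred thousand samples; 0.015 for the
  binary positive-control outcome (case-control scale). SEs are constant
  across SNPs, which also makes the Egger intercept test exactly calibrated.
* Allele frequencies uniform on (0.1, 0.9); allele pairs non-palindromic
  unless requested; roughly 30% of outcome rows are emitted with swapped
  allele order (beta negated, frequency mirrored) so harmonization is
  exercised on every run.
* Pleiotropy: `balanced` draws α ~ N(0, σ_α), `directional` uses |N(0, σ_α)|
  (InSIDE holds by construction in both). Outliers shift chosen SNPs'
  outcome betas by a multiple of their SE. Block LD is realized directly in
  the emitted r² table.
* Exposure and outcome noise use independent sub-streams of the seed
  (two-sample independence); a second outcome file (the positive control)
  uses a further sub-stream so it shares the structural layer but not the
  noise. A `noise_free` mode suppresses the noise draws while keeping the
  SE columns positive, giving exact-ratio degenerate datasets for identity
  tests.
* Report tables: five drugs with uniform shares, 100,000 reports, 2%
  background event rate; the target drug's event probability solves the
  odds relation so the expected 2×2 has exactly the requested reporting OR.

What the generator does **not** emulate: sample overlap between the two
GWAS, LD-induced correlation of the summary statistics themselves (LD
affects selection only), allele-frequency-dependent SEs, winner's-curse
selection bias, MedDRA coding structure or duplicated FAERS reports.
Passing tests therefore demonstrate correctness of the estimators and
selection logic under the stated model, not robustness to those real-data
pathologies.

## Numerical choices and edge cases

* Normal quantile 1.959964 for every 95% CI.
* Clumping ties broken by position then rsID, making results invariant to
  input row order.
* Significance and F filters are strict inequalities (P < threshold,
  F > threshold), matching the stated selection rules.
* Reader rejects rows with non-ACGT or identical alleles, se ≤ 0, p outside
  (0,1], position < 1, or unparseable numerics; it aborts when more than 10%
  of rows fail.
* `pvalue_from_estimate` recovers the SE from a 95% CI width and returns the
  implied two-sided normal p — used to audit published beta + CI rows.
* Empirical p-values from simulations are rank-based, (1 + #{≥ obs})/(n+1).

## Validated operating characteristics

The test suite and `scripts/acceptance.py` recompute (rather than assert
from memory): exact agreement of IVW/Egger with independent weighted
normal-equations fits and of ROR/PRR/χ² with brute-force 2×2 oracles at
1e-10; greedy clumping against exhaustive search on loci of up to 10 SNPs;
IVW bias and CI coverage at θ = 0.3 over 500 datasets; Egger-intercept
type-I error over 1000 balanced-pleiotropy replicates; MR-PRESSO detection
of a 5-SE planted outlier over 100 seeds together with the per-clean-SNP
false-flag rate (the per-dataset "any clean SNP flagged" rate is higher,
since a planted outlier contaminates the leave-one-out fits the clean SNPs
are judged against — an inherent property of the outlier test); and
signal-rule recovery of a true-OR-3 drug over 200 report tables. The
replicate counts above were chosen to keep the whole validation suite
within a few minutes on one CPU while leaving Monte-Carlo error well inside
the asserted bands.

## Known limitations

* No multivariable MR, Steiger filtering, contamination-mixture or CAUSE
  estimators; no MR-PRESSO distortion test.
* No proxy-SNP lookup for instruments missing from the outcome GWAS; they
  are dropped and reported.
* No genome-build liftover and no reference-panel LD computation; LD must be
  supplied.
* No openFDA client, MedDRA mapping, or Bayesian disproportionality
  (BCPNN/EBGM).
* Target-gene curation (which genes proxy which drug class) is supplied as
  configuration, not derived.
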
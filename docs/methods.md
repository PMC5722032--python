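# Methods

## Setting and data model

Two-sample summary-data Mendelian randomization uses, for each genetic
instrument j, the per-allele association with the exposure (β̂Xj, se_Xj)
from one GWAS and with the outcome (β̂Yj, se_Yj) from another. A record
also names the *effect allele* (the allele whose dosage the coefficient
refers to), the *other allele*, and optionally the effect allele frequency
(EAF). All effects are held on the additive scale internally; odds ratios
are ln-transformed on ingest, and the caller must declare whether supplied
SEs are on the log or natural scale (converted by the delta method,
se_ln ≈ se/OR) because GWAS sources are inconsistent and the package will
not guess.

Only biallelic SNPs with A/C/G/T alleles are accepted; indels and
multi-base alleles are rejected at ingest with line-numbered diagnostics,
since the matching algebra below is defined on single-nucleotide pairs.
EAF columns printed as percentages are detected (any value > 1) and
converted to proportions. chr:pos identifiers are accepted with a warning:
several variants can map to one position, and silent identifier collisions
are a known failure mode of manual harmonization.

## Harmonization procedure

Given an exposure dataset and an outcome dataset, the pipeline applies, in
order:

1. **LD-proxy substitution.** An instrument absent from the outcome GWAS
   can be replaced by a variant in high LD with it. The preferred mode
   replaces the target with the proxy's own records *in both datasets*
   (no phasing assumption; the proxy is analysed as itself). The
   alternative, outcome-only mode adopts the proxy's outcome record under
   the target's identity; this needs the *signed* allelic correlation r
   between the proxy's and target's effect alleles, and flips the adopted
   record when r < 0. Because partial LD only makes the alleles *typically*
   co-occur, this mode warns that phase is assumed. Proxies with
   r² < 0.8 (configurable) are not applied; the skip is logged and the
   target is later dropped with an explicit reason.
2. **Direction standardization.** Exposure records with β̂X < 0 are
   flipped so each instrument's effect allele is the exposure-increasing
   allele. Flipping means: swap the alleles, negate β, leave the SE, and
   complement the EAF (1 − EAF). This is required by MR-Egger and eases
   interpretation; records with β̂X exactly 0 are left with a warning,
   since no exposure-increasing allele exists. The operation is
   idempotent.
3. **Allele matching.** For each variant, the outcome record is expressed
   in the exposure's coding:
   - identical ordered allele pair → no action;
   - effect/other swapped → flip the outcome;
   - pair equal to the complemented exposure pair (same or swapped order)
     → the studies reported opposite strands: complement the symbols, then
     flip if also swapped;
   - **palindromic pairs (A/T, C/G)** read identically from both strands,
     so symbols carry no orientation information at all — even a
     symbol-identical palindromic pair may be miscoded. These bypass
     symbol logic entirely and are oriented by EAF concordance: writing
     both physical orientations in the exposure's symbols (the opposite
     orientation has β negated and EAF complemented), the one whose EAF
     lies on the same side of 50% as the exposure EAF is kept. When either
     EAF is missing, or either lies within the ambiguity window
     (default 0.5 ± 0.08, i.e. [0.42, 0.58]), the variant is dropped.
   - anything else → dropped as an irreconcilable allele pair.

   Failures are data, not exceptions: every variant yields an action code
   (`none`, `flip_outcome`, `strand_complement`,
   `strand_complement_and_flip`, `palindrome_resolved_by_eaf`) or a
   `dropped` entry with a machine-readable reason, and the full log is part
   of the output bundle so readers can audit the process. A palindromic
   pair whose reported orientation already agrees is labelled `none` rather
   than `palindrome_resolved_by_eaf`; this keeps the pipeline idempotent
   (harmonizing its own output yields all actions `none`), which the test
   suite asserts.

Key tunables (all recorded in the run manifest):

| parameter | default | meaning |
|---|---|---|
| `palindrome_maf_window` | 0.08 | half-width of the EAF ambiguity band around 0.5; field guidance says only "substantially below 50%", so the value is a convention, not a derivation |
| `palindrome_policy` | `keep_resolved` | resolve unambiguous palindromes by EAF, drop ambiguous; `drop_ambiguous` is an alias (same behaviour); `drop_all` discards every palindrome |
| `standardize_direction` | on | exposure-increasing effect alleles |
| `allow_strand_complement` | on | attempt opposite-strand reconciliation (non-palindromic only) |
| `require_eaf_for_palindromes` | on | drop palindromes lacking EAF; off assumes a shared strand |
| proxy `min_r2` | 0.8 | minimum LD strength for accepting a proxy |

An opt-in cross-check (`confirm_with_eaf`, off by default) warns when the
major/minor classification of a symbol-matched non-palindromic variant
disagrees between datasets; it never overrides symbol matching, because
frequencies are the weaker evidence. Grossly discordant EAFs on matched
variants are likewise surfaced by QC rather than acted on.

## Quality control

- **EAF correlation** before vs after harmonization (Pearson, frequencies
  as proportions, ≥ 3 shared variants). Unharmonized coding randomizes the
  orientation of each point, pushing the correlation toward zero; after
  correct harmonization the two studies' frequencies of the *same* allele
  should correlate strongly. On the built-in worked example the values are
  −0.003 and 0.98.
- **SE regression** (OLS of one dataset's SEs on the other's). Regression
  is preferred over correlation because a sample-size difference shifts
  SEs systematically (slope ≠ 1) without breaking linearity.
- **Typo audit**: for each shared variant, |β|, SE and minor-allele
  frequency — all invariant to allele orientation — are compared at a
  relative tolerance (default 1e-6, suited to printed-precision data;
  widen for heavily rounded sources). A variant flagged here differs in
  ways no legitimate re-coding can produce. Variants whose effect alleles
  differ are reported separately as orientation mismatches: legitimate,
  but they must be reconciled. With case-control data, EAFs estimated in
  controls are preferable when available; that cannot be enforced from
  summary statistics and remains a documentation note.

The aggregate report (counts of drops by reason, proxies used, the
correlations and regression, per-variant flags) serializes to JSON and
plain text.

## Estimators

With w_j = β̂Xj²/se_Yj² and ratio estimates θ̂_j = β̂Yj/β̂Xj,
se(θ̂_j) = se_Yj/|β̂Xj| (first-order delta method; exposure-side
uncertainty ignored, the standard two-sample approximation):

- **IVW (fixed effect)**: θ̂ = Σ β̂Xj β̂Yj/se_Yj² ÷ Σ β̂Xj²/se_Yj², with
  se = (Σ w_j)^(−1/2) — algebraically the w_j-weighted mean of the ratios.
  Cochran's Q = Σ w_j (θ̂_j − θ̂)² is reported with a χ² p-value. With one
  variant, IVW equals the Wald ratio exactly. No heterogeneity adjustment
  is applied; the fixed-effect choice is flagged in output metadata.
- **Random effects**: DerSimonian–Laird pooling of the θ̂_j with
  τ² = max(0, (Q − (k−1)) / (S₁ − S₂/S₁)), S_m = Σ (1/se²)^m; reduces to
  fixed-effect pooling when τ² = 0.
- **MR-Egger**: weighted least squares of β̂Yj on β̂Xj with intercept,
  weights 1/se_Yj². The slope is the causal estimate under InSIDE; the
  intercept estimates average directional pleiotropy. The fit refuses to
  run unless all β̂Xj ≥ 0, because the intercept is meaningless without a
  consistent instrument orientation.
- **Rescaling**: dividing exposure coefficients *and* SEs by a factor
  re-expresses the causal estimate per that many original exposure units
  (e.g. per 10 mmHg); the outcome dataset is never rescaled.

Confidence intervals are normal-approximation estimate ± z₀.₉₇₅·se;
second-order ratio corrections are out of scope. Exponentiation to odds
ratios happens only at presentation. A regression-through-the-origin
allele-score approximation used in some published analyses is not
re-derived; IVW serves in its place, which the package documents in its
output (the two agree closely in practice).

## Synthetic data generator

The simulator emulates a clumped-instrument two-sample design: independent
instruments (no LD among them), |β̂Xj| uniform on (0.1, 0.5) with random
sign (the reported effect allele is arbitrary), EAF uniform on
(0.05, 0.95), and β̂Yj = c + θ β̂Xj plus independent normal noise. SEs
follow the GWAS pattern se ∝ 1/√(2p(1−p)), normalized to `exposure_se`
(default 0.01) and `outcome_se` (default 0.05) at p = 0.5 — strong
instruments, as genome-wide-significant hits are. The outcome cohort's EAF
gets small sampling noise (sd 0.01) around the exposure cohort's.

Faults are injected into the outcome table only, mutually exclusively per
variant: allele swaps (a flip of the reported record — legitimate
alternative coding, not an error in the data), strand flips (symbols
complemented, numbers untouched), and removals, which trigger generation of
a non-palindromic LD proxy present in both tables with configurable signed
correlation (default +0.95). Palindromic variants are assigned at a
configurable rate; their "unambiguous" EAFs are drawn outside (0.40, 0.60)
— a 0.02 margin beyond the default ambiguity window so cross-cohort noise
cannot cross the boundary — and "ambiguous" ones inside (0.44, 0.56).
Typos multiply one record's β or SE by 3 (detectable above audit
tolerance). Every corruption, and the action a correct harmonization must
take for every variant, is written to a truth log; the generator's base
associations depend only on the seed and palindrome settings, so fault
fractions can vary without perturbing the underlying effects.

What the simulator does *not* model — and therefore what passing tests do
not establish about real data: LD between instruments, winner's-curse bias
in instrument selection, sample overlap between the two GWAS, population
stratification or frequency differences between ancestry groups, and
weak-instrument bias (instruments are strong by construction). It
validates the harmonization and estimation machinery, not the MR
assumptions.

## Numerical and design choices

- Problem sizes in the test suite: 50 instruments per simulated dataset,
  500 replicates for the unbiasedness check and 1000 for the 95% CI
  coverage check of IVW — enough for Monte-Carlo error of about ±0.7
  percentage points on coverage.
- Ratio with β̂X = 0 is refused (undefined); β̂Y = 0 gives a zero estimate
  with the usual SE.
- Degenerate QC inputs (fewer than 3 shared variants, zero variance) raise
  a specific error when the statistic is called directly, and are reported
  as `null` in the aggregate report so one undefined diagnostic does not
  abort a run.
- Table IO is exactly round-tripping (repr-precision writes,
  round-trip float parsing); the missing-data marker is `NA`.
- One proxy per target; duplicate targets are a format error.
- The worked-example fixture carries the proxy's exposure-GWAS row in the
  exposure dataset (the proxy was available in both GWAS); its signed
  correlation (+0.95) is a synthetic stand-in consistent with "high LD",
  as the published table prints none.

## Known limitations

- Strand reconciliation relies on allele symbols and EAF only; no reference
  genome or genotype panel is consulted, and signed proxy correlations must
  be supplied by the user (e.g. from a 1000 Genomes panel for the right
  ancestry).
- Weighted-median/mode estimators, MR-PRESSO, multivariable MR and
  one-sample designs are out of scope.
- The EAF-concordance rule for palindromes inherits its reliability from
  the ambiguity window: a true frequency near 50% in either study can
  still produce a confident but wrong orientation if both estimates land
  on the same wrong side; the window default (0.08) trades instrument loss
  against that risk and should be widened for small reference cohorts.
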
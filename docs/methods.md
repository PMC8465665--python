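# Methods

This note documents the statistical procedures implemented in `pairedcoda`,
the defaults that matter, the numerical choices, and what the synthetic
data used for validation does and does not emulate.

## Design and data model

The unit of analysis is a subject observed at two timepoints (before/after)
in one of two arms (intervention/control).  Counts are a taxa × samples
matrix of non-negative integers; metadata carries subject pairing, group,
timepoint and the covariates age, gender, BMI, weight and (for the
intervention arm) plant-based meals per week.  Pairing QC excludes any
sample below a configurable minimum depth (default 1000 reads — the one
real-world failure this guards against had 7 reads) *together with its
paired sample*, so all paired analyses see complete pairs only.

Lineages use the 7-rank prefixed dialect (`k__;p__;...;s__`).  Rank
aggregation sums member counts and conserves per-sample totals exactly; an
empty rank token pools under `<nearest classified ancestor>_unclassified`,
so e.g. an unclassified genus within the Tenericutes order ML615J-28
becomes `ML615J-28_unclassified`.

## Compositional treatment

Counts are closed to proportions per sample.  Before any log-ratio step:

1. **Prevalence filter** — keep taxa whose relative abundance exceeds 1%
   (strictly) in at least 5 samples (both configurable).
2. **Bayesian-multiplicative zero replacement.**  Two methods:
   - *CZM*: every zero becomes `delta` (default `0.65/depth` per sample).
   - *GBM* (default): a data-driven geometric prior — the prior expectation
     of part *j* is the across-sample geometric mean of the 0.5-padded
     proportions, with per-sample prior strength `sqrt(depth)` (the
     square-root prior family), so a zero is imputed as
     `t_j * s/(depth + s)`.
   In both, non-zero parts are rescaled by the common factor
   `1 − Σ(imputed)`, so **ratios between observed parts are preserved
   exactly**; imputed values are capped at 65% of the sample's smallest
   observed proportion, keeping them strictly below every observed part.
   Bit-parity with any particular R implementation is not a goal; the
   multiplicative-preservation and below-minimum properties are the
   contract, and they are tested exactly.

All log-ratio machinery uses natural logs; compositions are validated to
1e-9 and distances compared in tests at 1e-8.  Alpha diversity (below)
independently uses base-2 logs.

## Diversity

Rarefaction subsamples each sample to a common depth (default 3000 reads)
without replacement via multivariate hypergeometric draws; samples below
the target are dropped with a warning.  Shannon diversity is reported in
bits (base 2, a parameter); Chao1 uses the classic estimator
`S_obs + F1²/(2·F2)` and switches to the bias-corrected form
`S_obs + F1(F1−1)/(2(F2+1))` when no doubletons are observed.  Bray–Curtis
and the Aitchison distance (Euclidean in clr coordinates) feed a classical
PCoA (double-centred Gram matrix eigendecomposition).  Negative eigenvalues
— expected for Bray–Curtis — are reported to the caller and their axes
discarded; explained fractions divide by the positive-eigenvalue total, so
they sum to at most 1.

## Tests

- **PERMANOVA** partitions the total sum of squared distances by a factor;
  `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)` (999 permutations by
  default).  For before/after comparisons *within* one group the default is
  **restricted permutations**: timepoint labels are permuted only within
  subject, which respects pairing.  Free permutation is available; both
  modes are exposed because the original within-group analyses do not
  state which was used.  Empirical null rejection of the restricted mode is
  5.0% at α = 0.05 in our calibration.
- **ANCOVA** — OLS of `after ~ intercept + before + group` with control as
  the reference level; a positive group coefficient means the intervention
  arm ends higher at equal baseline.  A constant baseline is flagged as
  collinear rather than fitted.
- **Paired change test** — with exactly two timepoints and a subject random
  intercept, the mixed-model group-mean change test is algebraically the
  paired t-test on within-subject differences; it is implemented as that
  equivalence (deterministic, no iterative REML).  Zero-variance changes
  are flagged rather than producing NaNs.
- **Covariate screens** — one simple OLS per covariate (mirroring
  per-variable screening), numeric covariates z-scored for the fit with
  coefficients reported in original units, BH-corrected across covariates.
- **Welch t** with Welch–Satterthwaite degrees of freedom; **BH FDR** is
  the standard step-up rule (statsmodels backend, verified against literal
  enumeration).

## Differential abundance

**Within-group DBA.**  On zero-replaced proportions of one group's paired
samples, every two-taxon log-ratio is scored by the absolute standardised
mean difference between timepoints (pooled within-condition SD).  Pairs are
accepted greedily under taxon-disjointness; an accepted balance may grow by
one taxon per step on either side while that raises the score, never past
2 taxa per side — the variant that favours small balances, matching the
1–2-taxa-per-side balances such analyses report.  Balances are returned in
acceptance order (descending seed-pair score); the post-extension score is
reported but deliberately does not re-rank, because the extension search
optimises over many candidates and its score is slightly optimistic —
re-ranking on it would let over-fitted extended balances leapfrog genuinely
discriminative pairs.  Each balance's change is tested with the paired
change test and BH-corrected; q-values in (0.05, 0.06) are flagged
"marginal".

**Dirichlet–clr Monte-Carlo effects.**  For each of `n_mc_instances`
(default 128) instances, per-sample proportions are drawn from
`Dirichlet(counts + 0.5)` and clr-transformed.  Pooling instance × sample
values per group, `diff` is the difference of pooled medians, `disp` the
square root of the mean pooled within-group variance, and
`effect = diff/disp`; a per-instance Welch p on clr values is averaged
across instances and BH-corrected across taxa.  The pooled-median
formulation concentrates under the null (an exchangeable input yields
|effect| within Monte-Carlo error of zero) while real fold-changes produce
|effect| well above 1 at typical depths.

**Between-group protocol** (the six-step analysis):

1. Compute between-group effect magnitudes at *before* and at *after*;
   **retain** taxa with |effect_before| < |effect_after|.  This removes
   baseline-confounded taxa: a taxon whose groups differ at baseline more
   than after cannot be credited to the intervention.  The rule is monotone
   in the after-effect.
2. Build the change matrix `log(p_after/p_before)` per subject on retained
   taxa (zero-replaced proportions; exponentials available for display as
   after/before ratios).
3. DBA on the change matrix with group as the condition.
4. Per-balance values at before and after per subject.
5. ANCOVA `balance_after ~ intercept + balance_before + group` per balance.
6. BH across balances.

If step 1 retains nothing, a structured "no candidate taxa" result is
returned, with all intermediate artefacts kept for audit.

**selbal-style search.**  A greedy forward search for one balance
maximising AUC: initialise with the taxon pair whose log-ratio maximises
training AUC (rank statistic), add one taxon to either side while training
AUC improves, up to 4 taxa.  Within each of `n_repeats` (default 20)
stratified `k`-fold splits (default 5), selection runs on the training
folds and AUC is measured on the held-out fold; reported AUC is the
mean ± SD of held-out fold AUCs, and per-taxon **reproducibility** is the
fraction of fold-selections containing the taxon.  In the
perfect-separation limit the search returns AUC 1.0 with 100%
reproducibility; on pure noise, held-out AUC centres on 0.5.

## Butyrate potential

The **producer balance** places the matched butyrate-producing genera
(Faecalibacterium, Eubacterium, Roseburia, Ruminococcus, Anaerostipes;
auxiliary secondary set Lactobacillus + Bifidobacterium) in the numerator
and all other taxa in the denominator.  Name matching is genus-level,
case-insensitive and prefix-aware; the same genus under two parent families
matches once per row and all matches are included.  **Pathway potential**
multiplies a user-supplied pathways × taxa weight matrix (e.g. glutarate,
4-aminobutyrate/succinate and acetyl-CoA butyrate-synthesis variants) into
relative abundances and re-closes per sample; inferring the weights
themselves (reference-genome pathway annotation) is out of scope, so the
matrix is an explicit input with a documented toy fixture in the tests.
Both statistics are compared between arms with the baseline-adjusted
ANCOVA (+ BH across pathways).

## Synthetic studies

`generate_study` draws, per subject, a logistic-normal baseline
(`log-abundance = μ + subject effect + per-sample noise`), applies planted
multiplicative effects pre-closure (at "after" by default; "before" or
"both" express baseline confounds), and samples multinomial counts at a
lognormal depth moment-matched to mean 38,734 / SD 4,387 reads.  A
Dirichlet baseline mode is available as an alternative.  Because closure
renormalises, a planted effect on one taxon slightly perturbs all others;
the recorded truth includes both planted and induced (post-closure)
log fold-changes.

The paper-like preset uses 20 subjects/group and 40 genera with a
Bacteroides (23%) / Prevotella (10%) / Faecalibacterium (9%) dominated
baseline (means are log-normal mean-matched so expected shares hit these
targets; Prevotella gets a much larger between-subject sigma, reflecting
its known bimodality), a Tenericutes-like taxon planted to halve in the
intervention arm and to rise slightly (×1.1) in control, and
producer-like genera (Lachnospira ×1.4, Roseburia/Ruminococcus ×1.25)
planted to rise in the intervention arm.  Between-subject sigma defaults
to 0.8 in the preset (0.5 in the smaller simulation studies) and
within-subject temporal sigma to 0.3 (0.2 in the small studies) — values
in the range of repeat-sampling variability reported for adult gut 16S
profiles.

What the generator does **not** emulate: taxon–taxon interaction networks,
overdispersion beyond the logistic-normal (no zero-inflation process —
zeros arise only from sampling), read-level artefacts (chimeras,
contamination, variable trimming) and classification error.  Passing
recovery tests therefore demonstrate correctness of the statistical
machinery under the stated generative model, not robustness to upstream
bioinformatic noise.

## Numerical choices

- All stochastic operations take explicit seeds; the CLI derives per-stage
  seeds from one master seed via `SeedSequence.spawn` and logs each once,
  so stages are independently reproducible and full reruns are
  byte-identical.
- Simulation sizes in the validation suite: 1000 null replicates per test
  statistic for type-I calibration; 200 replicates for recovery of a
  planted ×2 intervention-only change (n = 20/20, depth 5000) and for DBA
  recovery of a 1.5-SD pair shift; 50 replicates for the selbal null.
- Greedy searches break ties deterministically on sorted taxon names, so
  results are invariant to input row/column order.
- Degenerate inputs (constant baselines, zero-variance changes, single
  condition levels, empty filtration results) return flagged results or
  typed errors rather than NaNs.

## Known limitations

- The mixed-model equivalence holds only for exactly two timepoints;
  longitudinal designs with more are out of scope.
- DBA's exhaustive scoring is over taxon *pairs*; signals spread thinly
  across many taxa may be found only via side extensions, which are capped
  at 2 taxa per side by design.
- The baseline filtration compares effect magnitudes, so a taxon whose
  baseline difference persists unchanged is retained or removed essentially
  at random (its ANCOVA is baseline-adjusted anyway); only taxa whose
  baseline difference *exceeds* their after difference are reliably
  removed.
- Reported p-values are conditional on balance selection within the same
  data; they are controlled empirically under the null by the simulations
  in the test suite, but selection-adjusted inference is not attempted.
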
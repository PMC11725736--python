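# Methods

## Scope and data model

`soyenergy` analyses total-collection digestibility trials in which a
test ingredient (full-fat deactivated soybeans) replaces a fixed
fraction *p* of a reference diet. Five validated record types carry the
data: sample assays (composition, quality indicators, gross energy; DM
basis), plant processing records, diet specifications, pig records and
collection-period totals. Validation is structural (ranges, NDF ≥ ADF,
hemicellulose = NDF − ADF within 0.2 points, fecal DM ≤ intake,
metabolic weight = BW^0.75 within 1e-9) and runs at construction and on
CSV read; CSV write∘read is the identity on values.

## Energy balance

For each pig, with DMI the feed intake over the collection period
(kg DM):

- DE = (DMI·GE_feed − fecalDM·GE_fecal) / DMI
- ME = DE − GE_urine / DMI
- NB = N_intake − N_fecal − N_urinary (g)
- MEn = ME − k_N · NB / DMI
- CADDM = 100·(DMI − fecalDM)/DMI, CADCP = 100·(N_in − N_fec)/N_in,
  BV = 100·NB/(N_in − N_fec)

The classical total-collection formulation is cited in the trial
literature without its constants, so k_N is a parameter; the default
7.45 kcal per g retained N is the common swine convention. Consequences:
DE ≥ ME always (urinary energy is nonnegative) and ME ≥ MEn whenever
nitrogen retention is nonnegative. Published MEn values computed with an
undisclosed k_N are therefore reproduced approximately, not bit-exactly.
A pig whose absorbed nitrogen is zero has undefined BV; it is flagged
(`bv=None`) and excluded from BV means only, never from energy means.
Diet values are unweighted means over pigs; experiment-level values are
unweighted means over diets.

Feed allocation within a weight block scales the lightest pig's
voluntary intake by metabolic weight: CMW = intake/BW_min^0.75 and
allocation_i = CMW·BW_i^0.75, making feed per kg^0.75 constant within a
block.

### Substitution method

E_ingredient = (E_TD − (1−p)·E_RD)/p, linear in both diet energies. The
`naive` mode (default) applies the as-fed inclusion fraction directly to
DM-basis energies; `dm_corrected` re-expresses *p* on a DM basis from
the DM fractions of ingredient and reference diet first, and coincides
with `naive` when the two DM fractions are equal. Applied to the
packaged diet table, naive substitution reproduces the published
per-sample envelopes within ≈1% and the published means within ≈0.5%;
the residual gap reflects DM-basis adjustments not disclosed with the
published table, which is why both modes exist rather than guessing a
correction.

## Processing energy

SH(kJ/kg) = 0.391 + 0.461·M/(100+M) with M the final moisture (%), and
EAS(cal/kg) = SH(cal/kg)·time(min)·temperature(°C). The formula is
applied verbatim (temperature in °C, no Kelvin offset; kJ→cal at
4.1868×1000); plant times recorded in seconds are converted to minutes,
the only convention that reproduces the published plant-level minimum of
0.63 Mcal/kg. EAS is strictly increasing in time, temperature and
moisture. Recomputing the five plants spans 0.63–5.51 Mcal/kg against a
published maximum of 5.52; the 0.01 discrepancy is consistent with the
published value having used a per-sample rather than plant-level
moisture, which is not disclosed. Plant-level moisture is used whenever
per-sample moisture is absent.

## Model search

Candidates are all nonempty subsets of the predictor pool, with two
refinements:

- **Quadratic bundling/hierarchy.** A predictor declared quadratic
  (default: UA only, the only squared term appearing in published
  equations) enters as a bundled pair (X, X²) — the square never appears
  without the linear term, and in enumeration the pair is one unit.
- **Interaction whitelist.** Pairs may be whitelisted and join any
  subset containing both parents; the default whitelist is empty, so
  candidate counts are configuration-dependent by design.

Fitting is maximum likelihood under i.i.d. normal errors (identical to
OLS for the coefficients): σ̂² = RSS/n, ln L̂ = −n/2·(ln 2πσ̂² + 1), and
AIC = 2k − 2 ln L̂ with **k counting the error variance**
(k = terms + intercept + 1). Packages that omit the variance parameter
report AIC exactly 2 lower per model; the ranking is unchanged among
models of equal size, and published absolute AICs (whose convention is
unstated) are not treated as exact targets. Ranking is ascending AIC
with deterministic tie-breaks (fewer terms, then lexicographic term
names). Prediction errors are in-sample absolute residuals
(mean/SD/min/max) and their percentage counterparts — a single fit per
candidate, no cross-validation, matching how the published tables were
built. Coefficient standard errors use the unbiased σ̂²(X'X)⁻¹ with
t-based two-sided p-values, reported unadjusted; reports carry a
multiplicity note since many candidates are examined. A concave fitted
UA response (negative squared-term coefficient) yields the UA at maximum
predicted energy, −b₁/(2·b₂); a nonnegative squared coefficient yields
no interior maximum and the optimum is reported absent. All 18 published
quadratic equations reproduce their printed UA-at-maximum column at
3 decimals under this formula.

Group comparisons (unpeeled vs partially dehulled) use the unpaired
two-sided t-test with pooled or Welch variances; correlations are
Pearson r with t-distribution p-values (n−2 df), flagged undefined on
zero variance.

## Synthetic-trial generator

The generator emulates the published survey's study conditions and is
the pipeline's oracle, not a digestion model:

- **Samples.** Independent truncated normals per composition field at
  the published per-sample means/SDs (defaults from the packaged
  statistics table); NDF is constructed as ADF + hemicellulose so fiber
  additivity holds by construction. Truncation: percentages to [0, 100],
  UA to [0.005, 0.2] ΔpH, PS to [60, 95]% — generator policy, not
  biology. Plants are assigned round-robin from the packaged five-plant
  regimes; unpeeled/dehulled alternates. Field correlations present in
  real samples (e.g. CF with ADF/NDF) are not modelled, so passing tests
  demonstrate pipeline correctness, not biological realism of joint
  distributions.
- **Planted truth.** MEn = 2827 + 18.5·PS − 51·CF + 10500·UA −
  116666.67·UA² + N(0, 30) kcal/kg DM: slopes of the magnitude seen in
  the published equations, a concave UA maximum at 0.045 ΔpH (inside
  the published 0.043–0.055 range), and a mean near the published
  4,344 kcal/kg DM at the composition means. DE and ME sit at fixed
  offsets above MEn (214 and 113 kcal/kg DM, the published mean
  differences).
- **Trial layout.** Experiments of 1–3 samples following the survey's
  ten-experiment pattern (2,1,1,2,1,1,1,1,3,1, cycled), one reference
  diet per experiment with fixed energies (DE/ME/MEn =
  3870/3775/3690 kcal/kg DM, a typical corn–soybean-meal diet), 30%
  substitution, 8 pigs per diet, BW ~ N(51.4, 5.4) kg truncated to
  [20, 120], one weight block per replicate, 5-day collection at 88% DM.
- **Back-solving.** Test-diet energies invert the naive substitution
  formula; each pig's collection record is solved from its target
  energies (diet truth + N(0, pig_noise_sd), default 30 kcal/kg DM, with
  the pig's DE/ME/MEn gaps held at the diet's): fecal DM from the
  GE deficit at a fixed fecal GE of 4,300 kcal/kg, urinary GE from the
  DE−ME gap, nitrogen balance from the ME−MEn gap at the generator's
  k_N, fecal N at 13% of N intake, urinary N as the remainder. Draws
  implying negative masses are resampled (≤100 attempts, then error).
  This guarantees inverse-consistency: with zero noise the balance +
  substitution pipeline returns the planted truths to 1e-6.

With these defaults the end-to-end recovery of the planted UA optimum at
100 samples is well inside ±0.005 ΔpH (the acceptance simulation uses
100 replicates of 100 samples, ~0.3 s each), and the mean absolute MEn
recovery error stays below 50 kcal/kg DM.

## Numerical and design choices

- Least squares via `numpy.linalg.lstsq`; singular designs are rejected
  with the collinear terms named (greedy left-to-right rank scan).
  Candidates that cannot be fitted on a given table (too few rows,
  collinearity) are skipped by the search rather than aborting it.
- Determinism: one `numpy.random.Generator` seeded from the config
  drives sampling, truth noise and trial noise in a fixed order; equal
  seeds give byte-identical CSV outputs.
- Display rounding (energies to integers, ratios to 1 decimal, UA
  optima to 3 decimals) is applied only by the `report` CLI subcommand;
  all machine-readable outputs keep full precision. An MJ/kg rendering
  is a ×0.0041868 rescale of the kcal columns.
- Identifiers are free strings; the sample→plant mapping is an explicit
  column because it cannot be derived.

## Known limitations

- No marker-based or ileal digestibility, no net-energy model, no
  mechanistic digestion or growth simulation.
- The fitted models ignore the block/experiment structure (no mixed
  models), as in the published analysis.
- Published regression tables (coefficients, AICs, R², correlations,
  t-tests) depend on per-sample data that was never published; the
  package verifies its machinery by property-based and
  simulation-recovery tests instead of reproducing those tables.
- Amino-acid data are carried as pass-through descriptive columns only.
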
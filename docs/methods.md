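# Methods

## Problem and data

The unit of observation is one published study's summary of one
pharmacokinetic parameter (Cmax, AUC or clearance) for one UGT probe
substrate and route: a sample size, a central statistic (arithmetic or
geometric mean), a dispersion statistic (SD, SE, CV as a fraction, or GSD),
the administered dose and its basis, and population descriptors. Individual
PK values are treated as lognormal throughout, the standard assumption for
concentration and clearance data.

## Standardisation

Every record becomes a (lnGM, lnGSD, n) triple in canonical units:
Cmax in ng/mL and AUC in ng·h/mL, both per mg/kg of normalised dose;
clearance in mL/min/kg. Choices worth noting:

- SE converts to SD via SD = SE·√n; a CV (fraction, never percent — percent
  inputs must be tagged in the source file) via SD = CV·AM. GSD pairs only
  with a geometric mean and bypasses conversion.
- AM/SD pairs are moment-matched to GM/GSD with
  GM = AM/√(1+CV²), GSD = exp(√(ln(1+CV²))); the inverse map is exact, and
  both are tested to 1e-12 over CV ∈ [0, 5].
- Total-mg doses divide by the study's reported mean body weight, falling
  back to a continent default (the Walpole et al. 2012 regional mean adult
  body masses, shipped as editable configuration — they are defaults, not
  truth). Substrates conventionally dosed per body surface area (SN38)
  divide by reported BSA, default 1.79 m²; when both body weight and BSA
  are present for such a substrate, BSA wins.
- Clearance is already weight-normalised; only the unit conversion
  (×1000/60 from L/h/kg) applies.

Repeated-dosing and patient records are excluded by default at selection
time; callers opt in explicitly for the known exceptions (the
ethinylestradiol 21-day contraceptive regimen; SN38 and deferiprone, where
only or mostly patient data exist).

## Hierarchical model

Three levels mirror the three named variance components:

- interindividual: log values within study i of substrate j are
  N(m_ij, σ²_ind,j);
- interstudy: m_ij ~ N(μ_j, σ²_study,j);
- intersubstrate (only when ≥ 2 substrates are fitted jointly):
  ln σ_ind,j ~ N(M, S²).

Summary statistics enter through their exact sampling distributions: the
sample log-mean is N(m_ij, σ²_ind,j/n_ij) and
(n_ij−1)·lnGSD²_ij/σ²_ind,j is χ²(n_ij−1). Studies with n = 1 or a
degenerate GSD of exactly 1 contribute only the mean term, with the study
effect integrated out (variance σ²_study + σ²_ind).

Priors (defaults; all overridable): μ_j ~ N(0, 10²) on the log scale;
σ_study,j ~ HalfNormal(1); σ_ind,j ~ HalfNormal(1) when a single substrate
is fitted; in pooled fits ln σ_ind,j ~ N(M, S²) with M ~ N(−1, 1²) and
S ~ HalfNormal(0.5). These are weakly informative on the GSD range seen in
human PK (≈1–5). Substrates whose variability was previously meta-analysed
(zidovudine, oxazepam) can carry an informative normal prior on ln σ_ind
via `PriorConfig.informative_overrides`; no published numerical values are
bundled, so the mechanism is configuration, not data.

## Sampling and diagnostics

The sampler is an adaptive Metropolis-within-Gibbs on
(μ_j, ln σ_ind,j, ln σ_study,j[, M, ln S]). Study effects are marginalised
analytically — marginally lnGM_ij ~ N(μ_j, σ²_study,j + σ²_ind,j/n_ij) —
which removes one parameter per study and the associated funnel geometry;
the full-parameter log posterior (with explicit study effects) is kept as
the reference density and is cross-checked against the marginal form by
numerical quadrature in the tests. Proposal scales adapt toward a 0.44
acceptance rate in batches of 50 during warmup and are frozen afterwards,
so the kept chains are a valid Markov chain with the posterior invariant.
Default run size: 4 chains × (1000 warmup + 2500 kept). One master seed
drives everything; per-chain seeds derive deterministically from it, and an
identical seed + configuration reproduces the draws bit for bit.

Convergence is assessed per scalar parameter with split R-hat (threshold
1.05) and bulk effective sample size (threshold 400) via ArviZ; failure
flags the result and warns rather than raising. The weakly identified
hyper-scale S is routinely the slowest-mixing coordinate and sets the
default draw count.

## Reported quantities

Per draw, CV = √(exp(σ²_ind)−1) and UF_p = exp(z_p·σ_ind). Posterior
summaries are the 2.5/50/97.5 percentiles computed with the inverted-CDF
(order-statistic) quantile, so that summaries commute exactly with
monotone transforms: the reported median UF *is* the UF of the reported
median CV. The isoform-level "overall" row uses the predictive σ_ind of a
new substrate — one N(M, S) draw per posterior draw, seeded — which is
wider than any single substrate's posterior, as an out-of-sample statement
should be; no geometric mean is reported at that level. For a
single-substrate fit the substrate is its own overall row. Rounding
(CV to integer percent, UFs half-up to one decimal) happens only at report
time. The default toxicokinetic factor 3.16 is a report annotation, never
an input.

## Synthetic data

The generator emulates the structure of a literature-derived database:
lognormal individuals, study-level random effects, per-study sizes drawn
uniformly from a range, reporting mode drawn from a mix (60% AM/SD, 15%
AM/SE, 10% AM/CV, 15% GM/GSD), doses as total mg with body weight
N(70.8, 10²) kg and 10% of studies missing it (the analyst then falls back
to the continent default, a realistic source of study-level noise), and
clearance units mixed between mL/min/kg and L/h/kg. Ground truth travels
with the generated database as a sidecar JSON.

Shipped presets: `default` (the reference recovery scenario: 2 substrates ×
12 studies × 20 subjects, interindividual CV 0.5, σ_study 0.2),
`ugt2b7_oral_auc` (18 + 12 studies, CVs 0.29/0.28) and
`ugt1a6_oral_clearance` (9 studies, CV 0.40) mimicking the corresponding
published table structures.

What the generator does *not* emulate: covariates (age, sex, genotype),
publication bias, non-lognormal tails, correlated parameters within a
study, or extraction errors. Passing recovery tests therefore demonstrates
correctness of the inferential machinery under the stated model, not
robustness to real-data violations of it.

## Problem sizes and numerical choices

Recovery experiments use 20 replicates of the `default` preset fitted with
2 chains × (800 warmup + 800 kept) draws — enough for stable medians and
interval endpoints of CV while keeping a full experiment under a minute;
single fits elsewhere use the 4 × 2500 default. Nonpositive SDs evaluate to
−∞ (rejection) rather than raising. Chains initialise at data-driven
centres (per-substrate mean lnGM, mean lnGSD) with N(0, 0.1²) jitter.
τ_j = 1/σ²_ind,j is derived from draws when needed, never a sampled
coordinate.

## Known limitations

- The exact likelihood and priors of the antecedent meta-analytic model
  this reconstructs are not published in full; this package's three-level
  form is the minimal structure producing the three named variance
  components from summary data, and is declared rather than claimed
  identical to any prior implementation.
- Whether isoform-level rows should pool substrate data or use the
  hyper-predictive is a genuine modelling choice; the predictive was chosen
  as the standard meta-analytic answer to "what about a new substrate of
  this isoform?".
- Published tables that print both CV and UF occasionally disagree with the
  analytic map by one rounding step (consistent with UFs computed from
  unrounded CVs); the analytic relation, not any printed row, is the
  specification of `uf_from_cv`.
- No covariate modelling: the analysis describes non-phenotyped healthy
  adults; genotype effects appear only as the descriptive frequency and
  AUC-ratio summaries in `polymorphism`.
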
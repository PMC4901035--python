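# Methods

This note documents the models, parameter choices and numerical
conventions behind `rumenferm`, and what the synthetic-data generator
does and does not emulate.

## Fermentation stoichiometry

Rumen carbohydrate fermentation is summarised by the classical
fermentation-balance equations on molar VFA yields (acetate Ac,
propionate Pr, butyrate But, valerate Val; iso-acids excluded because
they derive from amino-acid, not hexose, fermentation):

    FOM               = 0.5 Ac + 0.5 Pr + But + Val
    [2H] produced     = 2 Ac + Pr + 4 But + 3 Val
    [2H] incorporated = 2 Pr + 2 But + 4 Val + 4 CH4
    [2H] recovery     = 100 x incorporated / produced

The coefficient on CH4 is 4 because methanogenesis consumes four
reducing-equivalent pairs per mole (CO2 + 4 H2 → CH4 + 2 H2O).  It is
exposed as `stoichiometry.CH4_H_COEFFICIENT` for sensitivity work.
FOM in hexose mmol converts to mass with the anhydro-hexose monomer
mass, 162 mg/mmol, configurable because published FOM-mass values
depend on unprinted molar proportions and cannot be reproduced exactly.

Batch-culture concentrations (mM) convert to amounts with a declared
vessel liquid volume (default 0.05 L, a 120-mL bottle holding 50 mL).
Redox readings against an Ag/AgCl reference electrode are corrected to
the standard-hydrogen scale by adding +198 mV (the reference potential
at 39 °C); the correction is exactly additive and invertible.

### Reproducing published summary tables

The derived rows of the source study's tables are recomputed from the
printed treatment means (`rumenferm.reference`).  Linear combinations
([2H] produced/incorporated, efficiency ratios) reproduce to one unit
in the last printed digit.  Rows that were published as *means of
per-vessel ratios* — hydrogen recovery, CH4:VFA, apparent N
degradability — cannot be reproduced to that precision from rounded
treatment means; propagation of the printed rounding leaves up to
0.5 points on recovery, 0.002 on CH4:VFA and 0.4 points on
degradability.  The reproduction tests assert exactly these slacks; the
`report` module emits computed-vs-printed tables so the residuals are
visible.  Both per-sample and on-means recovery variants are available
(compute `hydrogen_balance` per vessel and average, or feed treatment
means).

## Nitrogen partitioning by ¹⁵N dilution

With the ammonia pool labelled by continuous (¹⁵NH₄)₂SO₄ infusion, two
steady-state enrichment ratios partition nitrogen flows:

    microbial N / NAN       = E(digesta NAN) / E(bacterial pellet)
    % microbial N from NH3  = 100 E(bacterial pellet) / E(ammonia)

Both are scale-invariant, so only a shared background per run is
required, not absolute calibration.  A microbial fraction above 1
indicates measurement error and is clipped to 1 with a warning;
NANM-N = NAN − microbial N then floors at 0.

Degradability definitions: apparent = 100 (intake − NAN)/intake and
true = 100 (intake − NANM-N)/intake.  These forms reproduce the
published table from its printed inputs; the alternative apparent form
subtracting NAN + ammonia-N does not, and is provided as an option
(`include_ammonia`) but not used by default.  N intake comes from DM
intake (11.25 g/d) times the intake-weighted diet N content (80:20
forage:concentrate).  The four efficiency-of-synthesis ratios divide
microbial N by NAN, N intake, truly degraded N (intake − NANM-N) and
degraded OM (EMPS, mg/g).

## Gas-production kinetics

Pressure excess converts to volume with the ideal gas law at fixed
incubation temperature, V = V_headspace ΔP / P_ambient (defaults 70 mL
and 101.3 kPa, both configurable; no transducer calibration curve is
modelled).  Readings are treated as vented increments by default
(cumulative = running sum); a non-venting mode is available.  Blank
correction subtracts the time-point-wise mean of blank-bottle curves.

The cumulative curve is fitted to the single-pool exponential model
Y = A(1 − e^(−ct)) by bounded nonlinear least squares.  Initialisation:
A₀ = 1.05 × max(Y); c₀ from a log-linear regression of log(1 − Y/A₀).
If that start fails, a coarse multi-start over A ∈ {1, 1.2, 2} × max(Y)
and c ∈ {0.01, 0.05, 0.2} h⁻¹ is tried; a fit that still fails returns
`converged=False` rather than raising, so batch runs survive
pathological bottles.  Because "gas-production rate" in the literature
sometimes means c (h⁻¹) and sometimes the initial slope, fits expose
both c and A·c (mL/h).

Protozoal activity is the OLS slope of %¹⁴C released on time over
0–4 h, per tube; ≥ 2 distinct time points required.

## Community statistics

* **Rarefaction** — each sample is subsampled *without replacement*
  (multivariate hypergeometric draw) to the minimum sample depth,
  seeded.  Proportional scaling was considered and rejected: it
  preserves no integer counts and biases richness.
* **Alpha diversity** — richness (observed OTUs), Shannon H = −Σp ln p
  (natural log), Pielou evenness H/ln S (defined as 0 for S = 1),
  Gini-Simpson 1 − Σp², bias-corrected Chao1
  S + F₁(F₁−1)/(2(F₂+1)), Good's coverage 1 − F₁/N.
* **Beta diversity** — Bray-Curtis on log(x+1) abundances (the zero-safe
  log transform; configurable to raw counts).  UPGMA trees come from
  average-linkage clustering with deterministic lowest-index
  tie-breaking, serialised as newick.
* **PERMANOVA** — the Gower-centred matrix G = −½ J (D∘D) J is
  partitioned by hat matrices of the design (McArdle–Anderson); each
  factor is tested marginally against a reduced model holding all other
  factors.  Significance uses Freedman-Lane permutation of
  reduced-model residuals, G* = M G Mᵀ with M = H₀ + P(I − H₀), with
  p = (1 + #{F* ≥ F}) / (1 + n_perm); an exhaustive mode enumerates all
  n! permutations for exact small-sample p-values.  One-way pseudo-F
  values agree with scikit-bio's permanova and multi-factor marginal
  tests with vegan's `adonis2(..., by="margin")` (checked during
  development to 6 decimals).
* **CCA** — ter Braak's constrained correspondence analysis:
  chi-square-standardised abundances are projected onto row-weighted,
  weighted-centred explanatory variables (via QR) and the fitted matrix
  decomposed by SVD.  Total inertia equals the unconstrained CA inertia
  (the scaled chi-square statistic of the table) — an identity the
  tests assert.  Per-variable significance is marginal: a
  single-variable pseudo-F, recomputed under permutations of that
  variable, matching the one-arrow-at-a-time reading of ordination
  biplots.  Rank-deficient environmental matrices are flagged, not
  rejected.
* **FDR** — Benjamini-Hochberg step-up via statsmodels.

## Synthetic-data generator

The generator emulates the study design so every stage has inputs with
the assumed statistical structure:

* **Vessels** — 2×2 factorial, 4 vessels/treatment.  Flows are Normal
  around the published treatment means with vessel SD implied by the
  published SEDs: SED = SD √(2/n) with the source n = 4, so
  SD = SED √(n/2).  The SD is a property of the source experiment and
  does not change when more vessels are simulated.  Enrichments are
  constructed by inverting the tracer formulas from the configured
  microbial fraction and ammonia contribution (multiplicative lognormal
  noise optional), so noise-free analysis is the identity on the
  configured targets.
* **Gas bottles** — the 9-point sampling grid (2–96 h), exponential
  signal (defaults A = 116 mL, c = 0.065 h⁻¹, the control-bottle scale)
  plus a small blank baseline and Normal(0, σ = 1 mL) cumulative noise,
  inverted to vented pressure increments with the same ideal-gas
  convention the analysis applies.
* **OTU tables** — Dirichlet-multinomial counts over a ranked-abundance
  baseline (geometric decay, shuffled), Dirichlet precision 50, depths
  uniform in 5 000–12 000; the hay treatment multiplies a designated
  effect-OTU set's base proportions by a fold-change before
  renormalising.  Defaults: 32 samples (16 vessels × 2 time points),
  200 OTUs, balanced factorial metadata with 4 inoculum animals.
* **Release tubes** — linear %release with Normal noise, clipped to
  [0, 100].

What the generator does **not** emulate: temporal autocorrelation
within vessels, animal-inoculum random effects on the measured flows,
compositional correlation between VFA species, lactate dynamics,
sequencing error/chimeras, and phylogenetic structure among OTUs.
Passing round-trip tests therefore demonstrates correctness of the
estimators under the assumed error model, not robustness to real-data
pathologies.

## Problem sizes used by the test suite

Simulation-based checks run at sizes chosen to keep Monte-Carlo error
well below the asserted tolerances: estimator-recovery loops use 100
seeds; PERMANOVA type-I calibration uses 200 null tables of 16 samples
× 100 OTUs with 999 permutations (rejection rate asserted in
0.05 ± 0.03); the power curve uses a 3-point fold-change grid with 60
replicates and 99 permutations; the exhaustive-enumeration check uses
6 samples (720 relabellings).

## Known limitations

* Apparent/true degradability definitions are reconstructions that
  reproduce the published table; other studies define apparent
  degradability with ammonia-N included.
* The France fit assumes no lag phase and a single pool; curves with
  diauxic behaviour will converge to a compromise fit (flagged only via
  RSS).
* PERMANOVA assumes exchangeability under the reduced model; with
  strongly unbalanced designs the Freedman-Lane scheme is approximate.
* CCA permutation tests permute one variable at a time and therefore
  test marginal, not partial, association.
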
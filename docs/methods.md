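# Methods

This note documents the statistical model, the synthetic-data
generator, the numerical choices, and the design decisions taken where
the problem left the design genuinely open. Everything quantitative
stated here is computed by the test suite or `scripts/acceptance.py`;
nothing is quoted from an external analysis.

## The mixed model

All analyses fit

    y = X b + Z u + e,    u ~ N(0, G σ²ᵤ),    e ~ N(0, I σ²ₑ)

where `y` holds one record per phenotyped animal, `b` stacks a fixed
class effect per herd and a fixed regression on Jersey breed fraction,
and `u` is the random genetic effect. There is deliberately no global
intercept: the herd classes absorb it, which keeps `X` full rank, and
the breed slope is identified through within-herd variation in breed
fraction (about half the simulated animals are crossbred, so this
variation is plentiful). `G` is the pedigree numerator relationship
matrix `A` for the animal model, or (by default) the identity over
sires for the sire model; the sampler only ever touches the sparse
`A⁻¹` assembled by Henderson's rules, with inbreeding coefficients from
a memoized kinship recursion. The dense tabular construction of `A` is
retained purely as a small-pedigree oracle and is tested against the
Henderson inverse to 1e−8 on pedigrees up to 200 animals.

Unknown parents are treated as unrelated, non-inbred founders; no
genetic groups are fitted. This matches the intended use, where animals
with incomplete parentage are excluded before analysis anyway.

### Response modes

* **continuous** (AGEVISIT): `y` observed.
* **interval** (AUG): `y` latent with per-record bounds; each
  iteration redraws `yᵢ ~ N(xᵢ'b + zᵢ'u, σ²ₑ)` truncated to
  `[lowerᵢ, upperᵢ]`. Right-censored records are ordinary interval
  records with the 500 d ceiling as upper bound — no penalty.
* **ordinal** (CAT): `y` is a liability constrained to the threshold
  interval of its category. With K categories the K−1 thresholds are
  fixed at 0, 1, …, K−2 and `σ²ₑ` is estimated; fixing the spacing to
  one unit is what identifies the liability scale. Two caveats:
  * With **K = 2** (single-visit and RANDOM1 scenarios) there is no
    interior category, fixed thresholds cannot identify the scale, and
    a free `σ²ₑ` performs an unanchored random walk (we observed it
    diverging). The sampler therefore fixes `σ²ₑ = 1` whenever K ≤ 2 —
    the standard probit convention.
  * An alternative identification (fix `σ²ₑ = 1`, pin the first
    threshold, and sample the remaining thresholds uniformly between
    the adjacent order statistics of the liabilities) is available via
    `ModelSpec(estimate_thresholds=True)`. Single-site threshold
    updates mix slowly; the fixed-threshold default is preferred.

### Sampler

One iteration performs response update → location sweep → variance
update (→ threshold update when enabled). The order is arbitrary for
correctness but pinned for reproducibility. The location sweep is
single-site: each herd effect, the breed slope, and each random level
is drawn from its scalar normal full conditional, with the random
levels using the prior precision `λ A⁻¹` (λ = σ²ₑ/σ²ᵤ) row by row.
The sweep is the only sequential hot loop and is compiled with numba;
all its randomness enters as pre-generated standard-normal deviates,
so a single `numpy` Generator seeded from the config drives the whole
chain and results are bit-reproducible.

Variances get scaled-inverse-χ² full-conditional draws,

    σ²ᵤ | · ~ (u'A⁻¹u + νᵤSᵤ) / χ²(νᵤ + q),
    σ²ₑ | · ~ (e'e     + νₑSₑ) / χ²(νₑ + n).

Priors default to ν = 4 with scales set from a prior heritability of
0.25 times a prior phenotypic variance (900 d² on the age scale, 1 on
the liability scale; the genetic scale is quartered for the sire
model). These are weakly informative: with n ≈ 1,000 records they
contribute a few effective observations. A fit with ~5,000+ records is
insensitive to them.

Truncated-normal draws use vectorized inverse-CDF sampling computed in
whichever tail is better conditioned (survival-function interpolation
for intervals in the far tail), which stays accurate for intervals 6+
SD from the mean; empirical moments on a [−1, 1] truncation match the
φ/Φ closed form (SD 0.53956) within Monte-Carlo error at 10⁵ draws.

Chains default to 100,000 iterations with 50,000 burn-in and no
thinning. Convergence is assessed by grouping post-burn-in samples in
consecutive lots of 10,000 and requiring the 95% CrIs of every pair of
lots to overlap for each monitored parameter (variances, heritability,
breed effect). Credibility intervals throughout are central 95%
intervals — empirical 2.5/97.5 percentiles with the linear-interpolation
definition; heritability is computed per draw and then summarized,
never as a ratio of summaries.

## Phenotype derivation

Within an animal's retained visits (sorted by age):

* `CAT` = 1-based index of the first elevated visit; never elevated →
  `n_retained + 1`. Under reduced scenarios the categories re-index
  over retained visits (two visits → scores 1–3, one visit → 1–2),
  because the threshold model needs consecutive codes.
* `AGEVISIT` = age at the first elevated visit, else age at the last
  *retained* visit + 31 d. The penalty anchors to the last retained
  visit, consistent with the phenotype's definition when only those
  visits exist.
* `AUG` = [age at latest non-elevated visit before the first elevated
  one (or 200 d floor), age at first elevated visit (or 500 d
  ceiling)]. The floor/ceiling encode ages at which essentially no and
  essentially every heifer has reached puberty.

Non-monotone status sequences (possible only with false negatives) are
governed by the *first* elevated visit for all three methods — an
animal counts as pubertal from its first positive test onward. Censor
classes follow directly: left iff elevated at the first retained
visit, right iff never elevated, interval otherwise; single-visit
scenarios can only produce left/right.

The record-exclusion filter mirrors field practice: animals with
identification issues (duplicate id, not in the pedigree), incomplete
parentage (unknown sire or dam), or missing any required visit record
are dropped, with a tally per reason.

## The synthetic herd study

The generator emulates a seasonal-calving progeny-test design on the
true-age scale:

    AGEP4ᵢ = μ + herd_h(i) + β_J · jerseyᵢ + aᵢ + eᵢ

| parameter | default | rationale |
|---|---|---|
| herds | 54 of 88 ± 45 heifers (min 10) | emulated study scale |
| sires | 100, random mating, dams ≤ 2 calves | widely used sires, ~50 daughters each |
| visit target ages | 299/327/354 d | ~30-day intervals around the expected pubertal window |
| age SD within herd | 14.5 d; herd schedule jitter SD 3 d | spread of birth dates in a seasonal block |
| σ²ₐ, σ²ₑ | 270, 630 d² | h² = 0.30 with 30 d phenotypic SD (the field data's phenotypic scale is unpublished; these are stated assumptions, mid-range of literature heritabilities) |
| herd effect SD | 10 d | modest between-herd management differences |
| Jersey effect β_J | −56 d | Jerseys mature earlier; magnitude set to the kind of breed contrast a three-visit interval-censored analysis reports |
| breed mixture | 48% HF (jersey ∈ U(0,0.1)), 50% crossbred (U(0.25,0.75)), 2% Jersey (U(0.9,1)) | approximates the admixed NZ population structure |
| μ (global mean) | 348 d | calibrated analytically, and confirmed by simulation, so ≈45% of heifers are post-pubertal at the mid visit under the defaults |
| false-negative probability | 0 | the core censoring experiment is noise-free |

Breeding values descend the pedigree: founders `N(0, σ²ₐ)`, offspring
mid-parent plus Mendelian sampling with variance
`σ²ₐ(½ − ¼(F_s + F_d))`, so `cov(aᵢ, aⱼ) = Aᵢⱼσ²ₐ` exactly (verified by
a 10,000-trio Monte-Carlo check of the parent–offspring covariance).
Ages are integer days (visits are dated events); the latent trait is
continuous. An optional false-negative mechanism suppresses elevated
status at a post-pubertal visit with a configurable probability
(post-pubertal BP4 is basal for roughly a week of the three-week
estrous cycle, i.e. ~30% of the time), with a flag that disallows two
consecutive misses since monthly visits cannot catch the same animal
in the luteal dip twice running.

What the generator does **not** emulate: continuous BP4 trajectories
or estrous cyclicity beyond the Bernoulli miss, heterosis (confounded
with breed fraction in admixed populations), growth/management
covariates, non-random allocation of sires to herds, and selection or
non-random missingness. Passing tests therefore demonstrate that the
estimators recover the parameters of *this* generating process under
censoring — not that field data are free of confounding.

## The experiment driver

`run_experiment` simulates one population and reuses it for every
method × scenario cell, mirroring the one-dataset design it emulates:
scenario differences are then attributable to censoring, not sampling.
Sire EBV correlations filter to sires with ≥ 5 phenotyped daughters in
the *control* scenario (the filter could equally be applied
per-scenario; control-based filtering keeps the sire set constant
across cells). For the animal-model methods, a sire's EBV is its own
animal-model solution. EBVs are within-breed solutions from models
that already contain the breed covariate; breed solutions are not
added back. Herd-effect correlations use posterior-mean herd class
solutions.

## Problem sizes used in checks

Automated checks run at desk scale, chosen for thoroughness per unit
of compute: parameter recovery uses 10 replicate ~1,200-heifer studies
(20 herds, 60 sires) with 10,000-iteration chains, and the
scenario-ordering check uses 5 replicate ~900-heifer studies with
4,000-iteration chains; the acceptance script runs one ~1,200-heifer
population through the full 3 × 8 grid at 8,000 iterations. At these
sizes the qualitative orderings (two-visit ≫ one-visit EBV stability;
data augmentation ≥ penalized age under single visits; breed effect
attenuating as left censoring grows) are stable across seeds, and the
interval-censored control fit covers the generator's h² and breed
effect in ≥ 8/10 replicates.

## Known limitations

* Single-site Gibbs mixes slowly for strongly confounded effects
  (e.g. breed slope vs herds when within-herd breed variation is
  small); no blocking is implemented.
* The threshold-sampling variant (`estimate_thresholds=True`) uses
  uniform single-site threshold updates and needs long chains.
* The sire model defaults to independent sires; pedigree mode inverts
  a dense sire relationship matrix, acceptable for a few hundred
  sires.
* No REML or alternative samplers; no multi-trait or genomic models.
* `tabular_a_matrix` is O(n²) memory and intended for oracles
  (≤ ~2,000 animals).
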
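# Methods

This note documents the statistical model, the estimation procedures, the
synthetic-data generator and the numerical choices made in this package,
in enough detail to reproduce or deliberately deviate from them.

## Dispersal estimation from band recoveries

A banding→recovery record contributes a natal dispersal distance when the
banding site can be read as the natal site and the recovery site as a
potential breeding site. Six sequential filters implement that reading
(order fixed; each removal is attributed to the first failing filter, and
the retained set is provably order-independent because a record must pass
all of them):

1. **age** — banded as nestling or fledgling (configurable code set; the
   banding scheme's age encodings are versioned and external, so
   membership is configuration, not code);
2. **maturity** — at least `maturity_years` (default 1.0) elapsed between
   banding and recovery. The banding scheme's age-at-recovery mechanics
   are not modeled; elapsed time is the operational proxy;
3. **season** — both dates fall in the species' breeding season, tested
   on calendar month with wrap-around (Nov–Feb spans the new year);
4. **range** — both coordinates inside the species' breeding-range
   bounding box (extreme-point filter, antimeridian-aware); polygon
   point-in-polygon testing is deliberately out of scope;
5. **condition** — found dead only, excluding recoveries at banding
   stations or hunting sites that oversample human activity;
6. **precision** — coordinate uncertainty no coarser than the 1′ block.

Distances are Vincenty inverse geodesics on WGS84 (a = 6378137 m,
f = 1/298.257223563), iterated to 1e-12 on the longitude difference with a
200-iteration cap. Near-antipodal non-convergence raises an error naming
both points rather than silently substituting; within-range dispersal
never approaches that regime. Records with identical rounded coordinates
produce a zero distance that reflects coordinate resolution, not biology:
they are floored at half the 1′ block (0.926 km, configurable) before the
log transform, and the count of floored records is reported.

Per species: geometric mean exp(mean(ln d)), the standard error of ln d
(sample sd / √n; undefined and reported as NaN at n = 1), and the mean
elapsed years banding→recovery, carried later as a covariate because late
recoveries may add breeding-dispersal movement. Species with fewer than
five recoveries are dropped (estimate standard errors grow steeply below
that), matching the retention rule the estimation design assumes.

## Wing aspect ratio

AR = B²/A_tot with A_tot = 2·A_w + C_r·(B − 2E). Inputs are validated
(all positive, E ≤ B/2, C_r ≤ B, B − 2E ≥ 0); AR is dimensionless, so
units need only internal consistency per specimen. The species value is
the arithmetic mean of per-specimen ARs — robust when wingspans and wing
areas come from unpaired sources — with the alternative convention
(AR of the mean measurements) exposed as `ar_of_means`. Species means
outside the typical avian range [3, 20] trigger a warning, not an error.

## PGLS with Pagel's λ

Under Brownian motion, trait covariance between species i and j equals
C_ij, the shared branch length from the root to their MRCA (C_ii is the
tip depth). Pagel's λ multiplies the off-diagonal entries, interpolating
between phylogenetic independence (λ = 0) and full Brownian structure
(λ = 1); λ is bounded at 1, not the algebraic maximum, matching the
common comparative-methods default. The regression model is

y = Xβ + ε, ε ~ MVN(0, σ²·V(λ)), V(λ) = λ·C + (1−λ)·diag(C).

Fitting is maximum likelihood throughout (not REML): for fixed λ, β̂ and
σ̂² = RSS_w/n are profiled analytically via Cholesky whitening, and λ is
maximized by a 101-point grid scan followed by bounded scalar refinement
(tolerance 1e-6) between the neighbors of the best grid point. The
profile is often multimodal-flat near the boundary; boundary optima
(λ̂ = 0 or 1) are legitimate results. λ̂ and β̂ are invariant to rescaling
all branch lengths (σ̂² rescales accordingly); this is tested.

Coefficient standard errors use the unbiased residual variance
RSS_w/(n − p) with t-tests on n − p df, while the reported likelihood uses
the ML σ̂²; this mirrors standard GLS practice. AICc = −2ℓ + 2k +
2k(k+1)/(n−k−1) with **k = (number of coefficients) + 1 (σ²) + 1 (λ)**;
λ is re-estimated inside every candidate model, so counting it keeps
model comparison honest. Users reproducing other conventions can refit
with `count_lambda=False`. R² = 1 − RSS_model/SS_null, where SS_null is
the whitened RSS of an intercept-only GLS sharing the model's λ̂ (same
correlation structure), so the intercept-only model scores exactly 0.

Phylogenetic signal in a single trait is the intercept-only λ̂ with a
likelihood-ratio test against λ = 0. Because the null pins λ to its
boundary, the reference distribution is the 50:50 mixture of a point mass
at zero and χ²₁.

**Sampling behavior of λ̂.** At n ≈ 44 the ML estimator of λ is noisy and
median-biased downward: with true λ = 0.4 roughly a third of replicates
collapse to λ̂ = 0, and the replicate median sits near 0.2–0.3 depending
on tree shape. This was cross-validated replicate-by-replicate against
R's `nlme::corPagel` (identical estimates, including the collapses, where
`corPagel` fails instead of returning 0) and distributionally against
`phytools::phylosig` on independently generated pure-birth trees. Slope
estimates and their confidence intervals remain well calibrated
regardless (bias ≈ 0, ~90–93% empirical coverage of nominal 95%
intervals); only λ itself is weakly identified at this sample size.

## Model selection and averaging

Candidates are all subsets of main effects with at most `max_terms` = 5
variables, plus pairwise interactions restricted to continuous×continuous
and continuous×binary pairs, admitted only when both main effects are
present, each interaction counting as one variable toward the cap.
Multi-level categorical predictors enter as main effects only. The
intercept-only model is always included, and enumeration order is
deterministic.

Continuous predictors are natural-log transformed where flagged
(dispersal distance, aspect ratio, recovery years, population size, mass,
migration distance, range area — right-skewed quantities) and z-scored
with the sample (n−1) standard deviation, the convention of R's `scale`.
Categorical predictors are reference-coded; habitat uses "coasts" as
reference. Rows with missing values in used columns are dropped and
recorded, mirroring real trait-coverage attrition. Unobserved categorical
levels are skipped rather than emitted as aliased all-zero columns.

Ranking: ΔAICc against the best model; Akaike weights; ties break toward
fewer parameters then lexicographic formula. The 95% confidence set is
the smallest weight-ordered prefix with cumulative weight ≥ 0.95 —
whether it contains the intercept-only model is therefore data-driven,
not a convention. Importance is the summed weight of models containing a
variable (as main effect or inside an interaction). Model averaging
reports both flavors, since published tables rarely say which was used:
conditional (weights renormalized over models containing the term) and
full (absent term contributes 0). Unconditional standard errors follow
the Burnham–Anderson formula SE = Σ wᵢ·√(seᵢ² + (βᵢ − β̄)²), with 95%
normal intervals. No multiple-testing correction is applied: inference is
information-theoretic, and p-values are reported raw.

GVIF is computed from determinant partitions of the predictor correlation
matrix excluding the intercept, GVIF_g = det(R_gg)·det(R₋g)/det(R), with
the dimensionality correction GVIF^(1/(2·df)) whose square is read
against the usual VIF bands (< 2 none, 2–5 moderate, > 5 high).

## Synthetic-data generator

The generator produces data under exactly the assumptions the analysis
makes, with ground truth recorded, and these defaults define the study
conditions used throughout the tests:

- **Phylogeny**: pure-birth tree, 44 species (the size of the comparative
  set the package targets), scaled to unit depth.
- **Traits**: the latent flight-efficiency predictor is Brownian motion
  scaled to tip sd 0.5; noise predictors are independent Brownian traits;
  a four-state habitat character evolves by a symmetric CTMC (rate 1).
  The response is y = 3.5 + 2.0·x_flight + ε with ε ~ MVN(0, 1²·V(0.4)):
  a strong flight-efficiency effect, moderate residual phylogenetic
  inertia, and dispersal medians exp(y) centered on ~33 km — the scale of
  real band-recovery geometric means — ranging roughly 3–400 km.
- **Records**: 200 clean records per species; natal sites uniform in the
  breeding bbox (10% margin), displacement log-normal with median exp(y)
  and log-sd 0.7 (moderate within-species spread), direction uniform,
  placed on a local tangent plane (exact forward geodesy is unnecessary
  below ~500 km, where tangent-plane error is far below the kernel
  spread). Banding in a random breeding-season month of 1960–2010,
  recovery two to six seasons later so the maturity filter is satisfied
  by construction. Contaminants are generated at 5% each and violate
  exactly one named filter — out-of-season recovery date, out-of-range
  recovery point, hunting recovery, coarse coordinates — carrying a truth
  label, so filter attribution can be checked exactly.
- **Ranges**: continental-scale bounding boxes (12–22° latitude,
  30–55° longitude), so within-range kernels are not artificially
  truncated for wide-dispersing species.
- **Wings**: four specimens per species whose aspect ratios realize
  exp(1.95 + 0.3·x_flight) with 3% specimen-level log-normal noise;
  wing area is back-solved from the target AR given plausible chord and
  extent proportions.

All generators are pure functions of (config, seed).

**What the generator does and does not emulate.** It reproduces the
statistical structure the analysis assumes: log-normal within-species
kernels, λ-structured between-species residuals, single-filter
contaminants, uniform recovery effort. Real banding data violate several
of these — spatially biased recovery effort, range polygons that are not
boxes, multi-filter contaminants, taxon-dependent reporting rates — so
passing recovery tests demonstrates correctness of the estimation
machinery, not robustness to those field artifacts. Two boundary effects
remain by design and are quantified in the end-to-end tests: the
zero-distance floor inflates geometric means of species with sub-km
medians, and bounded ranges truncate the kernels of the widest-dispersing
species. Under the default conditions these compress the recovered
flight-efficiency slope by roughly 4–6% relative to the generative truth,
within the 10% tolerance the end-to-end recovery check asserts.

## Problem sizes and determinism

The test suite and the acceptance script use 44-species studies, 200
records per species, 100–200 replicate simulations for recovery
properties, and 10–300-tip trees for structural oracles; these sizes make
every Monte-Carlo bound comfortably separated from its threshold while
keeping a full run in minutes on one core. Every stochastic test is
seeded (hypothesis properties are derandomized), pipeline outputs are
byte-identical on rerun, and the run manifest records seed, config hash
and library versions.

## Known limitations

- Maturity is an elapsed-time proxy; true age-at-recovery codes are not
  parsed.
- Bounding-box range filters admit corner areas outside real range
  polygons.
- λ is weakly identified at n ≈ 44 (see above); interpret per-model λ̂
  values with that spread in mind.
- The AICc parameter count includes λ; comparisons against software that
  conditions on λ or excludes it from k shift all AICc values by a
  near-constant and can reorder closely tied models.
- Model-averaged intervals use normal quantiles, not t.
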
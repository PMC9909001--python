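# dispersal-pgls

Tools for estimating **natal dispersal distances** of birds from
band-recovery records and for analyzing their morphological and ecological
determinants with **phylogenetic generalized least squares (PGLS)**.

Natal dispersal — the movement from birth site to first breeding site —
drives gene flow, population spatial dynamics and community connectivity,
yet comparable cross-species estimates are scarce. Continental banding
programs make them possible: a bird banded as a nestling and found dead
years later inside its species' breeding range and season provides one
natal dispersal distance. This package implements that estimation chain
and the comparative machinery needed to ask *why* species differ, for
example whether long-distance flight efficiency (wing aspect ratio)
predicts how far birds disperse.

## What it computes

**Dispersal estimation** (`dispersal`, `geodesy`). Band-recovery records
are filtered so the banding site is a natal site and the recovery site a
potential breeding site: banded as nestling/fledgling, recovered after
maturity, banding and recovery dates within the species' breeding season
and both points inside its breeding range, recoveries of birds found dead
only, coordinate precision no coarser than a 1-arc-minute block. Distances
are Vincenty geodesics on the WGS84 ellipsoid (implemented from scratch,
validated against `geosphere` to 1e-6 relative error), summarized per
species as the geometric mean

&nbsp;&nbsp;&nbsp;&nbsp;d̄ = exp( mean( ln dᵢ ) ),

with species retained at n ≥ 5 recoveries. The mean elapsed time between
banding and recovery is carried as a covariate against breeding-dispersal
contamination.

**Flight-efficiency morphometrics** (`morphometrics`). Wing aspect ratio
AR = B²/A_tot, with total lifting area A_tot = 2·A_w + C_r·(B − 2E)
(B wingspan, A_w single-wing area, C_r root chord, E wing extent),
averaged over specimens per species.

**Phylogenetic regression** (`phylo`). PGLS with the error covariance
σ²·V(λ), where V(λ) scales the off-diagonal entries of the Brownian-motion
covariance **C** (shared root-to-MRCA branch lengths) by Pagel's λ. Models
are fit by maximum likelihood: β and σ² profiled analytically, λ by a
grid-plus-bounded 1-D search on [0, 1]. Reports log-likelihood, AICc
(k counts coefficients + σ² + λ), R² = 1 − RSS_model/SS_null against an
intercept-only model sharing the same λ, and a boundary-corrected
(½χ²₀ + ½χ²₁) likelihood-ratio test of phylogenetic signal.

**Multimodel inference** (`model_selection`). All-subsets model
enumeration (≤ 5 variables, pairwise interactions between continuous and
binary predictors with marginality enforced), AICc ranking, Akaike weights
wᵢ = exp(−Δᵢ/2)/Σ exp(−Δⱼ/2), 95% confidence model sets, per-variable
importance (summed weights of models containing the variable), conditional
and full model-averaged coefficients with unconditional standard errors,
and generalized variance inflation factors with the Fox–Monette
correction GVIF^(1/(2·df)).

**Synthetic studies** (`simulate`). A generator with known ground truth —
pure-birth trees, Brownian predictors, λ-structured residuals, log-normal
dispersal kernels tied to the trait model, labelled contaminant records,
and wing specimens realizing the latent flight-efficiency trait — so every
stage is testable end to end without restricted banding data.

## Worked example

Simulate a 44-species study, estimate dispersal distances, compute aspect
ratios, and run the multimodel comparison:

```bash
dispersal-pgls simulate --seed 7 --out sim
dispersal-pgls estimate-dispersal --records sim/records.csv --meta sim/meta.csv \
    --out estimates.csv --audit audit.json
# -> 8800/10560 records retained; 44 species with n >= 5
dispersal-pgls aspect-ratio --wings sim/wings.csv --out ar.csv
```

`estimates.csv` starts:

```
species,n,geomean_km,log_se,mean_recovery_years
sp01,200,47.905921717120265,0.049338153776344276,4.149075975359343
sp02,200,197.22307111158406,0.04981561061969953,3.9212046543463384
```

i.e. species sp01's geometric-mean natal dispersal distance is 47.9 km
from 200 retained recoveries, averaging 4.1 years between banding and
recovery. After merging estimates, aspect ratios and metadata into a trait
table (`dispersal_pgls.pipeline.build_trait_table`):

```bash
dispersal-pgls dredge --traits traits.csv --tree sim/tree.nwk \
    --predictors aspect_ratio,recovery_years,population_size,habitat \
    --max-terms 4 --out dredge_out
# -> 25 models ranked; best: aspect_ratio + population_size (weight 0.290);
#    confidence set 11 models
```

with `dredge_out/importance.csv`:

```
predictor,importance
aspect_ratio,0.9995105352678725
population_size,0.7069439882412393
recovery_years,0.266257134762957
habitat,0.2108483202991956
```

The generator ties log dispersal to the latent flight-efficiency trait, so
aspect ratio attains importance ≈ 1.0 and heads the best model (here with
λ̂ = 0.42 and R² = 0.44); the remaining predictors carry no generative
effect and show correspondingly lower importance. The full pipeline —
records to report bundle with a reproducibility manifest — is
`dispersal-pgls run --config pipeline.yaml`.

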
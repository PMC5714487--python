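# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `beanqtl`.

## Models

### Stage 1 — spatial adjustment (per site)

Plot-level flowering time within one site follows

    TF_ijkl = mu + G_i + B_j + BR_jk + BC_jl + e_ijkl

with genotype G and replicate B fixed and rows/columns nested in replicate
(BR, BC) plus the plot error random.  Adjusted means are mu + G_i evaluated
at equally weighted replicates, so in a balanced design with no spatial
signal they reduce to raw line means.  For single-site heritability the
genotype and replicate are refit as random; the genotype term carries the
expected genetic correlation of a biparental RIL family — 0 between the
parents, 0.5 parent-RIL and 0.5 RIL-RIL, 1 on the diagonal — and

    H_s^2 = Var(G) / (Var(G) + Var(B) + Var(BR) + Var(BC) + Var(e)).

Two consequences of these conventions are worth knowing.  First, the
replicate component is included in the denominator; this is an assumption
(the alternative, excluding it, changes H_s^2 in the third decimal at trial
scale).  Second, under the family correlation matrix the genetic variance is
expressed on the base-population scale: contrasts between exchangeable RILs
carry half of Var(G), so generative checks must simulate line effects with
covariance sigma_g^2 (0.5 J + 0.5 I), not sigma_g^2 I.

### Stage 2 — multi-site model

    TF_ijklm = mu + S_m + SB_mj + SG_mi + SBR_mjk + SBC_mjl + e_ijklm

Site S and site-replicate SB are fixed; the genotype-in-site term SG has an
unstructured s x s covariance across sites (distinct lines independent), and
SBR, SBC and the residual get a separate variance per site.  Site-level
heritability divides the genetic variance at the site by the sum of row,
column, genetic and error components at that site; the overall value is the
ratio of across-site averages, never the average of ratios.  The replicate
term, being fixed, does not enter the denominator.

### Stage 3 — genome scans and the QTL x Site model

Scans operate on adjusted line means stacked over sites.  At each grid
position the model is TF = mu + Site + QTL + QTL x Site + line + e with the
line effect random; the reported statistic is the joint Wald chi-square of
the QTL main and interaction coefficients (df = number of sites), on the
-log10 p scale.  Two deliberate choices:

- **Two-stage GLS.**  The line and residual variances are estimated once by
  REML under the no-QTL null and held fixed along the genome; each position
  is then a generalized-least-squares test in the whitened space.  At the
  sample sizes of a RIL trial a per-position variance refit changes the
  profile imperceptibly and costs three orders of magnitude more; the final
  QTL model refits everything by REML.  Null-genome calibration of the
  family-wise error rate with the genome-wide threshold is verified at
  0.05 +- 0.02 in the test suite.
- **Cofactor exclusion in CIM.**  A cofactor on the tested chromosome within
  the minimum cofactor distance (default 50 cM) of the tested position is
  excluded from the covariate set; the scan window (default 5 cM) is kept as
  a parameter and is subsumed by the 50-cM rule at the defaults.  The
  operational distinction between the two radii in legacy software is not
  documented; this interpretation is the package's own.

The genome-wide threshold uses the eigenvalue-based effective number of
independent tests: per chromosome, M_eff = sum_i [ 1(lambda_i >= 1) +
(lambda_i - floor(lambda_i)) ] over the eigenvalues of the marker
correlation matrix, summed over chromosomes; threshold = -log10(alpha /
M_eff).  Note that when all eigenvalues lie in (0, 2) this sum equals the
trace, so demonstrating M_eff ~ marker count for independent markers
requires many more lines than markers.

Peak selection takes local maxima above the threshold greedily by height
with a minimum separation (default 10 cM — configurable, since real linked
QTL can sit closer).  The QTL x Site model backward-eliminates interaction
terms by Wald p at alpha = 0.05, respecting marginality and protecting main
effects; AIC (counting variance parameters) arbitrates between the initial
and final candidates.  Wald tests use the chi-square reference without
denominator-degree-of-freedom correction — an approximation adequate at
n ~ 10^3 observations.

### Stage 4 — the QTL-EC model

Eight candidate covariates are computed per line x site as arithmetic means
over [sowing, flowering): day length DAY (from latitude and day of year via
solar declination delta = 23.45 sin(2 pi (284+DOY)/365) and hour angle
arccos(-tan phi tan delta)), NIGHT = 24 - DAY, solar radiation Srad, and
Tmin, Tavg, Tmax, DTavg, NTavg.  Day/night mean temperatures use a 0.75
weight on the respective extreme (configurable); no sub-daily model is
implied, and both are normally removed by the collinearity screen.

The screen admits covariates greedily in a priority order (DAY, Srad, Tmin,
Tmax, then the rest), rejecting any with |Spearman rho| >= 0.5 against an
already-admitted covariate.  In a five-site trial the between-site rank
correlations of the temperature summaries sit near this boundary, so the
screen's outcome is sensitive to the realized weather; when the model
structure is known (simulation refits, cross-validation with a fixed EC
set) the EC set can be passed explicitly.

Candidate QTL x EC interactions are tested one at a time for each
site-interacting QTL (with the site factor still in the model), then pruned
jointly by backward elimination in the final site-free fit — the
one-at-a-time step alone admits collinear proxies of the true partner.  EC
main effects are centered at stored constants (by default the across-record
means; fixed constants can be supplied so coefficients are comparable with
an external parameterization) and dropped if non-significant.

**Prediction** must resolve a circularity: the ECs are averaged up to
flowering, which is what is being predicted.  The window iterates from 45 d:
compute ECs over the window, evaluate the linear predictor, set the window
to the prediction rounded to whole days, repeat until the change is < 0.1 d
(max 25 iterations).  The iteration contracts whenever the model's total
sensitivity to the window |sum_e b_e dEC_e/dL| < 1, which holds for
realistic coefficient magnitudes; day-to-day weather noise can still make
the rounded window oscillate by one day for occasional genotypes, which is
reported as a flagged failure, not silently accepted.  Training-time ECs use
observed flowering dates and need no iteration.

Evaluation reports RMSE and adjusted r^2 = 1 - (1-R^2)(n-1)/(n-p-1) with
R^2 the squared Pearson correlation and p the fixed-coefficient count (the
adjustment convention is the package's own choice).  Leave-one-site-out
refits the model on the remaining sites (QTL set held fixed by default,
per-fold EC screening by default) and flags extrapolation whenever the
held-out site's realized EC range leaves the training range.

## REML engine

The engine maximizes the restricted likelihood of Gaussian mixed models with
IID random terms, known-correlation terms, an unstructured site covariance
for a nested factor, and single or per-site residual variances.  The general
path assembles the marginal covariance V densely and uses L-BFGS-B on
transformed parameters (log variances; Cholesky factors with log diagonals
for UN, guaranteeing positive semi-definiteness) with an analytic gradient
dl/dtheta = -1/2 [tr(P dV) - y'P dV P y], followed by a Nelder-Mead polish;
convergence requires the polish to yield no improvement beyond 1e-7
relative.  Variance components are floored at 1e-10 and reported as 0 at
the floor.  Models with exactly one IID random term and a single residual —
the scan and QTL-regression models — dispatch to a closed-form Woodbury
path in the grouped structure, which matches closed-form ANOVA estimators
to ~1e-7 relative error on balanced layouts and the general path to the
same tolerance.

AIC counts only variance parameters (REML likelihoods are comparable only
across a fixed mean structure); during backward selection the Wald p-value
drives removal and AIC is compared between the initial and final candidate
models only.

The model interface is a programmatic `ModelSpec` (fixed terms as strings
with `:` interactions, declared categorical columns, typed random terms); a
text formula grammar was considered and rejected as surface area without
capability, since the CLI builds all specs internally.

## Synthetic-data generator

The generator emulates a five-site biparental RIL trial:

- **Map and genotypes.**  11 chromosomes, 47 markers each (~1.85 cM
  spacing); fully homozygous RILs simulated as two-state Markov chains with
  switch probability haldane_r(d) between adjacent markers.  Map distances
  are treated as RIL-map distances — no Haldane-Waddington re-expansion —
  because maps estimated from RIL data already absorb the accumulation of
  recombination over selfing generations; `genotypes.ril_r` (R = 2r/(1+2r))
  is provided for users starting from a meiotic map.
- **Sites.**  Five profiles spanning day lengths ~11.5-15.9 h: a
  subtropical spring site and a Caribbean winter site with strong seasonal
  temperature ramps, a high-latitude summer site, and two near-equatorial
  sites at different altitudes (warm vs cool) with weak seasonality.  Base
  temperatures are set so the realized sowing-to-flowering window averages
  land near the emulated trial's climate summaries (Tmin ~13-19, Tmax
  ~25-32 deg C); daily anomalies are driven by a persistent AR(1)
  "cloudiness" process (phi = 0.85) that lowers Tmax and solar radiation
  while raising Tmin, which is both how weather systems couple these series
  and what keeps the temperature covariates from being rank-degenerate
  across only five site clusters.
- **Phenotypes.**  True line x site TF solves the same fixed point used at
  prediction time, from a truth model with 12 QTL on six chromosomes
  (main effects 0.3-2.3 d, signs mixed between the parents), four EC main
  effects (DAY +4.03 d/h, Srad -0.30 d/MJ, Tmin -0.61 and Tmax -1.36
  d/deg), seven QTL x EC interactions, one epistatic pair, a polygenic line
  effect (sd 1.5 d) and a line x site residual (default sd 1 d).  The DAY,
  Tmin, Tmax and TF2 values are the reference coefficients for this cross;
  the remaining magnitudes are package choices consistent with per-site
  effect patterns (e.g. a stable QTL at ~1.4 d everywhere; the major QTL's
  site profile reproduced through its Tmin interaction).  Plot-level data
  add replicate (0.5 d^2), row and column (0.4 d^2 each) effects and plot
  error (sd 1.5 d, i.e. 2.25 d^2, inside the 0.9-14.2 d^2 range seen in
  real multi-site components); plant-level replication within plots is
  collapsed into this plot error, since the analysis operates on plot
  means.

**What passing tests do and do not show.**  The generator reproduces the
statistical structure the pipeline assumes — linked biallelic markers,
row-column field noise, site-correlated genetic effects, weather-driven
covariate windows.  It does not emulate genotyping error or segregation
distortion, non-Gaussian plot errors, spatially autocorrelated (AR1 x AR1)
field trends, true sub-daily weather, or the nonlinear
photoperiod-by-temperature responses known to exist at environmental
extremes; recovery on synthetic data therefore validates the estimation
machinery, not the adequacy of the linear model for real extreme
environments.  The leave-one-site-out behavior makes this concrete: with
five scattered environments and four covariates the between-site design is
nearly saturated, so a held-out site is predicted well only when the
remaining sites cover its covariate range (the two short-day sites cover
each other; the long-day site, held out, is an extrapolation and degrades
sharply — the same failure mode reported for real data).

## Problem sizes and numerics

Test and acceptance runs use 188-1,000 lines, five sites, 1-3 replicates, a
1-cM scan grid, and 200 null genomes for the calibration check — sizes
chosen so each property is measured with useful Monte-Carlo precision.
Recovery assertions use 3-SE bounds at fixed seeds; calibration assertions
use binomial bounds.  Degenerate inputs are handled explicitly: constant
markers are dropped from the correlation screen, monomorphic scan positions
record p = 1, aliased QTL dosage columns are dropped with a warning,
fully-missing chromosomes impute to dosage 0, and non-convergent fixed
points are flagged and excluded rather than clipped into the data.

## Known limitations

- Wald chi-square p-values are not small-sample corrected (no
  Kenward-Roger); per-site LOD profiles in the legacy single-environment
  style are not produced.
- The HMM imputation returns posterior expected dosages, not hard calls;
  the emission model is a single symmetric error rate (default 0.005).
- Thresholds by permutation, multiple-interval-mapping epistasis searches,
  AR1 x AR1 spatial models, and nonlinear temperature-photoperiod response
  surfaces are out of scope.
- With only five environments the EC coefficient estimates lean heavily on
  between-site contrasts; the model is trustworthy only inside the observed
  covariate ranges.
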
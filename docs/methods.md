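# Methods

This note documents the statistical models implemented in `firetraits`,
the synthetic-data generator that provides their test surface, and the
design decisions taken where more than one defensible choice existed.

## Community-weighted means and the slope decomposition

For plot *j* and trait *t*, CWM_j = Σ_s w_sj t_s with w_sj the relative
cover (weights renormalised to sum to 1 *after* aggregation at each scale,
so coarser scales are genuine reweightings, not approximations). The four
trait-aggregation scales are:

1. **full_variability** — the species' mean trait measured in that plot;
   if a species has cover in a plot but no trait record there, its
   cross-plot mean is substituted and the substitution is logged. This
   keeps the weight vector identical across scales, so scale differences
   are attributable to trait aggregation alone.
2. **species_means** — one value per species: the unweighted mean of its
   plot-level means (each plot where the species was sampled counts
   equally; a cover-weighted alternative would let abundant-plot phenotypes
   dominate and re-import part of the intraspecific signal).
3. **genera_means** — unweighted mean of constituent species means; genus
   cover is the sum of member covers.
4. **functional_means** — likewise per functional group.

Each scale's CWM is regressed on fire frequency by OLS (one CWM per plot,
so no pseudo-replication). Reported per trait: slope, SE, r², p per scale;
the signed percent slope change between adjacent scales,
100·(slope_finer − slope_coarser)/|slope_coarser|; and a `co_gradient`
flag (all slopes share a sign and |slope| is non-decreasing from the
functional to the full-variability scale).

Interpretation on the generator's truth: the species-means slope estimates
the interspecific component β; slope(full) − slope(species_means)
estimates the cover-weighted mean intraspecific slope δ.

Per-species trends are OLS fits of a species' plot-level mean trait on fire
frequency across the plots where it occurs, flagged at α = 0.10 (two-sided;
configurable). Species in fewer than 3 plots are marked unfit, not dropped.

## Phylogenetic signal

Blomberg's K is computed from the shared path-length matrix C by the
ratio-of-ratios formula with a phylogenetic GLS mean (see README for the
expression). Properties relied on in tests: K = 1 exactly on a star tree,
invariance to affine trait transforms, and mean K ≈ 1 for Brownian traits.

The observed K is located against two nulls:

* **Brownian motion** — traits simulated on the same tree (rate estimated
  from the observed trait by the REML-style quadratic form first; K is
  rate-invariant so this choice is cosmetic). The comparison is two-sided
  by distance from the null median, since both conservatism (K high) and
  lability (K low) are departures of interest.
* **White noise** — tip permutations of the observed trait; one-sided
  (K_obs large rejects the hypothesis that history is irrelevant).

Both use the add-one permutation correction; p-values have resolution
1/(n_sims + 1).

## Lambda-profile PGLS

The phylogenetic regression assumes y = Xβ + ε, ε ~ N(0, σ²·C(λ)) where
C(λ) multiplies off-diagonal entries of C by λ. λ is estimated by bounded
scalar maximisation of the profile log-likelihood on [0, λ_max], tolerance
1e-6, where λ_max ≥ 1 is the largest value keeping C(λ) positive definite
(found by bisection; for ultrametric trees it is typically slightly above
1). Because the bounded search only approaches boundaries, the likelihood
is also evaluated at {0, 1, λ_max} and the maximiser snapped there when it
wins — this makes the invariant "loglik(λ̂) ≥ loglik(0), loglik(1)" exact.
r² is 1 − RSS_gls/TSS_gls with both quadratic forms taken under C(λ̂)
about the GLS mean. With λ fixed at 0 on an ultrametric tree the fit
reproduces OLS exactly (the covariance is a scalar matrix).

A Bayesian variant of the phylogenetic regression is out of scope; the
frequentist λ-profile fit is the package's design choice, and its variance
explained will generally differ from Bayesian posterior summaries.

## Marginal PERMANOVA

The dissimilarity matrix is Gower-centred (G = −½·J D² J). For model
matrix X with hat matrix H, explained SS = tr(HG). Each term's marginal
(Type III) SS is tr(H_full G) − tr(H_−t G); pseudo-F uses the full-model
residual; partial R² = SS_t / tr(G). p-values permute raw plot identities
(free permutation), matching the default of the standard marginal
implementation; reduced-model residual permutation is not implemented. An
exhaustive mode enumerates all n! permutations for small n (used by the
enumeration oracle test). Rank-deficient predictor sets are rejected with
the aliased terms named.

## Diversity

Richness counts species with positive cover; Shannon entropy is in nats;
Pielou evenness is H/ln S (undefined for S ≤ 1); Faith's PD is the branch
length of the minimal subtree spanning the community's tips *including the
path to the root* (so a one-species community has positive PD equal to its
root-to-tip depth); a `include_root_path=False` switch gives the
MRCA-rooted variant. Plots with zero total cover yield flagged NaNs.

Domin cover classes convert to percent cover by class-interval midpoints.
"Modified" Domin scales differ between surveys, so the mapping is an
explicit, overridable table; the shipped default uses the common 10-class
intervals (class 8 = 50–75% → 62.5).

## Backbone grafting

Species missing from a dated backbone are attached within their genus (or
family when the genus is absent): the new stem joins at the midpoint of the
anchor lineage's subtending edge, and the terminal branch makes the tip
contemporaneous with the anchor's tips (mean tip depth). When a genus has
several tips the anchor is the genus crown group and the attachment splits
its stem edge — this reads "midpoint of the sister lineage" without
inventing within-genus resolution, and grafting therefore creates
polytomies only where knowledge is genuinely absent. Depths of pre-existing
nodes are never altered. Species with no congeneric or confamilial anchor
are returned in an `unplaced` list, never silently dropped. For
family-level placements the anchor is the family crown; the choice of node
within the family is otherwise unconstrained by the grafting rule and this
is the package's convention.

## Mixed model for repeated soil measurements

Soil variables measured on the same plots across years are fit with a
random-intercept linear mixed model (REML, via statsmodels). The fire
fixed effects are tested with a Wald F using containment denominator
degrees of freedom computed from the data: effects constant within plots
use n_plots − rank(X); effects varying within plots use
N − rank(X) − (n_plots − 1). Satterthwaite/Kenward–Roger approximations
are out of scope. With one observation per group the group and residual
variances are unidentifiable; the fit degenerates to OLS and is flagged.

## Type II regression

SMA slope = sign(r)·sd(y)/sd(x); MA slope from the leading eigenvector of
the 2×2 covariance matrix; intercept through the means. Significance is the
two-sided correlation test (t on Pearson r), standard practice for Type II
lines; Spearman ρ is reported alongside. Grouped fits (per fire treatment,
per functional group) report only groups with n ≥ 5, because Type II
slopes from smaller groups are unstable.

## The synthetic generator

The generator emulates the statistical structure of a 41-year
fire-frequency experiment: 12 plots at 9 realized frequencies spanning
0–0.77 fires/yr (three unburned, two ≈ 1/decade, two ≈ 1/3 yr, two
alternate-year, three ≈ 3-in-4 years), ~89 species in 6 functional groups,
and ~900 sampled individuals.

* **Cover** follows a Gaussian coenocline: cover(plot, s) = peak ·
  exp(−(f_j − o_s)²/(2b²)) · lognormal(0, σ_c), with niche breadth
  b = 0.33 fires/yr, peak 80% and σ_c = 0.6 by default. Covers below the
  survey floor (0.5%, the same threshold that gates trait sampling) are
  recorded as absent. Species optima are uniform on the fire range
  *extended by 0.6 fires/yr at both ends*: a pool truncated exactly at the
  sampled gradient attenuates the cover-weighted mean optimum near the
  gradient ends (edge effects shrink the realized interspecific slope by
  25–70% in a noise-free calculation), whereas the extended pool keeps it
  tracking plot fire almost one-to-one. The breadth/margin/peak constants
  were fixed by that one-off noise-free design calculation so that the
  slope-decomposition recovery invariants hold (|bias| < 10% for both β
  and δ at zero noise, in expectation over optima draws).
* **The trait-sampling floor is absolute percent cover (0.5)**, not
  relative cover. This mirrors the field rule and is also load-bearing:
  with a relative floor, each species' occupancy window tracks its optimum
  so tightly that the species' cross-plot mean fire becomes collinear with
  its optimum and the species-means scale absorbs most of the
  intraspecific signal — the decomposition is then biased by 45–80% and no
  parameter choice rescues it.
* **Species trait means** are baseline + β·o_s + dev_s, with dev drawn
  multivariate normal with covariance bm_sd²·C(λ) on a simulated Yule tree
  (depth scaled to 1; λ = 0.75 by default). Genera, families and
  functional groups are clade blocks on that tree, so group turnover is
  phylogenetically structured. Defaults: β_N = −7.0 mg/g per fire/yr,
  β_SLA = −190 cm²/g per fire/yr, baselines 24.5 mg/g and 380 cm²/g,
  bm_sd 3 mg/g and 60 cm²/g.
* **Individuals**: trait = species mean + δ·f_j + N(0, sd), with
  δ_N = −3.6, δ_SLA = −78, sd 2 mg/g and 40 cm²/g, one individual per
  (plot, species) by default; %C ~ N(45, 1.5) so C:N is computable. Traits
  are floored at physiological minima (SLA 20 cm²/g, N 1 mg/g), which the
  default noise levels rarely reach. The within-species trait variance is
  a free parameter of the emulated design, not calibrated to any dataset.
* **Environment**: light penetration rises linearly 12→76% across the
  gradient; net N mineralisation and inorganic N decline quadratically
  (5.15→1.15 and 0.51→0.24 kg N/ha) with a plot random intercept and
  5 years of repeated measurements; total soil N declines linearly
  2.75→1.68 Mg/ha.
* **Reproducibility**: one master seed spawns independent substreams for
  tree, optima, species traits, cover, individuals and environment;
  regeneration is byte-identical.

What the generator does *not* emulate: spatial structure among sampling
points within a plot (the design averages them before analysis), skewed or
zero-inflated trait distributions, covariance between cover noise and
trait noise, and interannual variation in cover. Passing recovery tests
therefore demonstrate estimator correctness under the stated model, not
robustness to those real-data features.

## Numerical choices

* Covariance matrices receive a 1e-12 ridge before Cholesky; the Yule
  simulation runs past the last speciation so terminal branches are
  strictly positive and C is well-conditioned.
* λ feasibility bound found by 40-step bisection on Cholesky success.
* Permutation p-values use the add-one correction except in exhaustive
  mode, where the identity permutation plays that role.
* Ultrametricity is never enforced; methods that assume it (the λ = 0 ⇒
  OLS identity) state so.
* Degenerate inputs fail loudly: constant traits (K), constant fire
  (decomposition), zero-variance axes (SMA), zero-cover plots (diversity),
  aliased predictors (PERMANOVA), species with cover but no traits (CWM).

## Problem sizes used in the test suite

Oracle-equivalence tests run on 4–20-tip trees and hand-sized matrices.
Calibration tests use 500 replicates × 199 null draws (white-noise K),
1000 replicates × 199 permutations (PERMANOVA type-I), 500 Brownian
replicates at 64 tips (mean K), and 200 replicates at 128 tips (λ
recovery); CWM slope recovery averages 20 replicate gradients per noise
condition. These sizes give Monte-Carlo error comfortably inside the
asserted bands while keeping the full suite under a minute.

## Known limitations

* The white-noise comparison for K loses power on traits whose
  phylogenetic share of variance is small, as in the default generator
  where the niche-optimum component dominates the Brownian deviation.
* Marginal PERMANOVA with free permutation is slightly liberal for
  multi-term models with strong covariate correlation; reduced-model
  permutation is not implemented.
* Containment df is a convention; software using Satterthwaite will report
  different denominator df for the same fit.
* The λ-profile likelihood is assumed unimodal on [0, λ_max]; the 101-point
  grid check in the tests guards the optimizer but multimodal profiles on
  pathological trees would only be caught there.
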
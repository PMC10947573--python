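# firetraits

Tools for asking how repeated disturbance reshapes the functional
composition of plant communities, built around the analysis design of
long-term fire-frequency experiments on savanna–forest ecotones. Fire
creates an inverse gradient in light and soil nitrogen; plant communities
respond both by species turnover (replacement of taxa with different leaf
economics) and by within-species plasticity. `firetraits` separates those
responses and asks whether they reinforce or oppose each other.

The package is aimed at community ecologists working with plot × species
cover surveys, individual-level leaf trait measurements (%N, %C, SLA) and a
phylogeny of the species pool.

## What it computes

**Hierarchical CWM decomposition.** The community-weighted mean of a trait
*t* in plot *j* is CWM_j = Σ_s w_sj · t_s, with w_sj the relative cover of
species *s*. Computing CWM with trait values aggregated at four scales —
plot-specific species values ("full variability"), cross-plot species
means, genus means, and functional-group means — and regressing each CWM on
fire frequency partitions the community trait–fire slope: the species-means
slope carries turnover alone (the interspecific component β), and the
difference between the full-variability and species-means slopes estimates
the cover-weighted mean within-species response (the intraspecific
component δ). When all four slopes share a sign and steepen monotonically
toward finer scales, turnover and plasticity reinforce each other — a
*co-gradient*.

**Phylogenetic comparative statistics.** Blomberg's K
(K = [MSE₀/MSE]_obs / E_BM[MSE₀/MSE], with the GLS mean
â = (1′C⁻¹x)/(1′C⁻¹1) and C the shared path-length matrix) located
against both a Brownian-motion null (simulated on the tree) and a
white-noise null (tip permutations); Pagel's λ-profile phylogenetic
regression (GLS with residual covariance σ²·C(λ), λ estimated by bounded
profile maximum likelihood).

**Community statistics.** Richness, Shannon–Wiener diversity, Pielou
evenness, Faith's phylogenetic diversity; Bray–Curtis dissimilarity; and a
PERMANOVA with marginal (Type III) sums of squares supporting continuous
predictors (each term's SS is the drop in Gower-centred explained SS when
that term is removed; p by free permutation of plots).

**Supporting models.** Polynomial OLS for environment–fire curves,
random-intercept mixed models (REML) for repeated soil measurements, and
Type II (standardized major axis / major axis) regression for trait–trait
covariation.

**Synthetic data with known truth.** A Gaussian-coenocline generator
emulating a 12-plot, 9-level fire gradient (0–0.77 fires/yr) with ~89
species in 6 functional groups: species fire optima, niche-kernel cover
with log-normal noise, species trait means that are linear in the optimum
plus a λ-scaled Brownian deviation on a simulated phylogeny, within-species
linear responses to fire, and individual measurement noise. Every
downstream estimator has a parameter-recovery test against this ground
truth. See `docs/methods.md` for the model and its design choices.

## Worked example

```python
from firetraits import SimulationConfig, make_dataset, cwm_profiles, decompose

ds = make_dataset(SimulationConfig(rng_seed=1))   # synthetic fire gradient
dec = decompose(cwm_profiles(ds.cover, ds.traits), ds.environment)
print(dec.slopes.loc["n_mass"].round(2))
```

```
                  slope  stderr  intercept    r2  p_value
scale
functional_means  -0.24    0.25      21.10  0.08     0.36
genera_means      -2.37    0.29      21.67  0.87     0.00
species_means     -7.82    0.40      23.50  0.97     0.00
full_variability -11.39    0.51      24.69  0.98     0.00
```

Leaf N per mass (mg/g) declines with fire frequency at every scale, and the
slope steepens from the functional-group scale to the full-variability
scale: community N loss is driven mostly by genus/species turnover
(−7.8 mg/g per fire/yr) reinforced by within-species declines (the
additional −3.6 mg/g per fire/yr between the species-means and
full-variability rows — the generator's true intraspecific slope). All four
traits flag `co_gradient = True` here: plasticity and turnover push the
same way. The generating truth for this dataset is in `ds.truth`.

The same stages run from the shell:

```sh
firetraits simulate --out data/ --seed 1
firetraits run-all --simulate --seed 1 --out results/
firetraits tree graft --backbone backbone.nwk --taxonomy tax.csv --out full.nwk
```

`run-all` executes diversity → PERMANOVA → CWM (4 scales) → decomposition →
species trends → phylogenetic signal → PGLS → covariation → environment
models, writing one CSV per result plus a `manifest.json` that suffices to
reproduce the run bit-for-bit.

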
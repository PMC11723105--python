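# droughtscreen

Multi-trait screening of crop genotype panels for drought tolerance.

Field trials that phenotype a panel of genotypes under well-watered and
water-limited conditions produce dozens of correlated physiological,
gas-exchange, chlorophyll-fluorescence, stomatal, biochemical and yield
traits.  Ranking genotypes across all of them at once is the hard part.
`droughtscreen` implements the complete analysis chain used for this kind of
study — aimed at breeders and crop physiologists — on a replicated
two-factor randomized complete block design (genotype × growing condition,
blocks nested in condition):

1. **Trait derivation** (`droughtscreen.traits`) — every derived trait from
   its raw measurements: LRWC = (FW−DW)/(TW−DW)×100, ELWR, RWL, CMS =
   (1−C1/C2)×100, CTD = AT−CT, g_m = P_n/C_i, WUE_L = P_n/T_r, the PAM
   fluorescence set (F_v/F_m, F_v/F_o, Φ_PSII, qP, NPQ, ETR), and the
   stomatal indices SAI, Sg_s and the anatomical maximum conductance

   g_s.max = d·SD·a_max / [1.6·v·(l + (π/2)·√(a_max/π))],

   with a_max = π(p/2)² and pore depth l = W/2.
2. **Variance analysis** (`droughtscreen.anova`) — balanced factorial-RCBD
   ANOVA with exact expected-mean-squares variance components and
   broad-sense heritability on a genotype-mean basis,
   H² = σ²_g/(σ²_g + σ²_ge/e + σ²_ε/(e·r)), plus paired *t* tests and
   star-coded Pearson correlation tables.  `FactorialRCBD(obs, trait).fit()`
   returns a results object with the ANOVA table, components and
   `summary()`.
3. **Classification** (`droughtscreen.cluster`) — two-way hierarchical
   clustering (Ward.D2 on Euclidean distances) of standardized
   drought/control relative trait values, PCA of the trait correlation
   matrix, leave-one-out linear-discriminant cross-validation of the
   cluster assignment, and per-cluster drought-response summaries.
4. **MGIDI** (`droughtscreen.mgidi`) — the multi-trait genotype-ideotype
   distance index, written from scratch: direction-aware 0–100 rescaling of
   genotype means, factor analysis (Kaiser retention λ ≥ 1, normalized
   varimax rotation, regression scores B = R⁻¹Λ*), and

   MGIDI_i = [Σ_{j=1..f} (γ_ij − γ_j)²]^½,

   the Euclidean distance of genotype *i* from the ideotype (the
   hypothetical genotype scoring best on every trait) in factor-score
   space.  `MGIDI(means, pressure=0.3).fit()` returns the index, ranking,
   selected set, per-trait selection differentials and per-factor
   strengths/weaknesses shares.
5. **Synthetic data** (`droughtscreen.synthetic`) — a seeded generator for
   the full study design (14 genotypes × 2 conditions × 3 blocks × 37
   traits, three latent tolerance clusters of sizes 6/7/1 that differ in
   drought-response magnitude), plus inversion of the trait formulas into
   raw-measurement tables so the whole chain is testable end to end.

## Worked example

```python
from droughtscreen import synthetic, pipeline, anova
from droughtscreen.mgidi import MGIDI

obs = synthetic.simulate_trait_panel(synthetic.default_design(seed=1))
print(anova.FactorialRCBD(obs, "Pn").fit().summary())

drought = pipeline.trait_means(obs, "drought")
print(MGIDI(drought, pressure=0.3).fit().summary())
```

prints (abridged):

```
Factorial RCBD ANOVA — trait 'Pn'
                    df  sum_sq  mean_sq       F           p
condition            1 291.993  291.993 342.977  1.5015e-24
block(condition)     4  16.196  4.04901 4.75599   0.0024027
genotype            13 135.906  10.4543 12.2797 1.28132e-11
genotype:condition  13 61.2317  4.71013 5.53255 3.65015e-06
residual            52 44.2701 0.851348     NaN         NaN
sigma2_g=0.957363  sigma2_ge=1.28626  sigma2_eps=0.851348  H2=0.5495

MGIDI — multi-trait genotype-ideotype distance index
genotypes: 14   traits: 37   retained factors (eigenvalue >= 1): 9
...
selection pressure 0.30 -> 5 selected (cutpoint 4.0710)
selection differential totals: +89.52% (higher-better), -52.08% (lower-better)
```

Reading this: photosynthesis differs strongly between genotypes and
conditions (the genotype and condition F tests), about 55 % of the
variance among genotype means is genetic (H²), and the 37-trait panel
condenses into 9 factors; the five genotypes with the smallest
genotype-ideotype distance are flagged `selected`, and selecting them would
shift the higher-better traits up by a summed 89.5 % and the lower-better
traits (C_i, VPD_LA, WUE_L, NPQ, oxidative markers, ELWR) down by 52.1 %.

The same chain runs from the shell:

```sh
droughtscreen all --seed 1 --out run1/      # simulate → ANOVA → cluster → MGIDI
droughtscreen simulate --seed 1 --out obs.csv
droughtscreen anova obs.csv
```

Every stage persists tidy CSVs plus a `manifest.json`; the same
configuration and seed reproduce every output byte for byte.

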
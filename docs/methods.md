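# Methods

This note documents the statistical model behind `droughtscreen`, the
conventions and defaults that matter, what the synthetic generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Design and linear model

All analyses assume a balanced two-factor randomized complete block design:
*g* genotypes × two growing conditions (well-watered control, terminal
drought) × *r* blocks, with blocks nested in condition and one observation
per cell.  Each trait is modelled as

    y_ijk = μ + a_i + c_j + b_k(j) + (ac)_ij + e_ijk,

genotype *i*, condition *j*, block *k* within condition, errors normal,
independent, homoscedastic.  The ANOVA decomposes the total sum of squares
into condition (1 df), blocks-within-condition (2(r−1)), genotype (g−1),
genotype×condition (g−1), and residual ((g−1)·2·(r−1)); all F tests use
the residual mean square, and the decomposition is exact (sources sum to
the total; the suite property-tests this on random inputs).

Variance components come from equating observed to expected mean squares,
which is exact on balanced data — unbalanced or incomplete tables are
rejected outright rather than approximated (no REML, no imputation):

    σ̂²_ε  = MS_res
    σ̂²_ge = max(0, (MS_GE − MS_res)/r)
    σ̂²_g  = max(0, (MS_G − MS_GE)/(2r))

Broad-sense heritability is reported on a genotype-mean basis across both
conditions (e = 2 environments, r blocks):

    H² = σ̂²_g / (σ̂²_g + σ̂²_ge/e + σ̂²_ε/(e·r)).

Truncations of negative component estimates are warned about and recorded
on the result object.

**Known limitation.** The plug-in H² estimator is biased downward in small
designs: on balanced data H² = 1 − MS_GE/MS_G before truncation, and with
both mean squares on g−1 df, E[1/MS_G] = (g−1)/((g−3)·E[MS_G]).  At g = 14
the mean estimate runs ≈ 0.05 below the truth near H² = 0.55 (truncation
offsets part of it); the bias fades as H² → 1 and as g grows.  Interval
estimation and bias correction are out of scope.

## Trait formulas and their conventions

The derived traits follow the standard field conventions; the ambiguous
cases are pinned down as follows, each selectable in the API:

* **RWL** — the wilting assay weighs the same excised leaves fresh (FW),
  wilted (WW) and oven-dry (DW).  Default RWL = (FW−WW)/DW × 100 (water
  lost per unit dry mass); the fresh-mass-normalised variant
  (FW−WW)/FW × 100 is available via `per_dry_mass=False`.
* **g_s.max** — d·SD·a_max / (1.6·v·(l + (π/2)√(a_max/π))) with
  d = 2.82×10⁻⁵ m² s⁻¹ (water-vapour diffusivity at 25 °C), a_max =
  π(p/2)², l = W/2.  The molar volume of air at 25 °C is taken as
  v = 0.0245 m³ mol⁻¹, which yields conductances of the realistic order
  (≈0.3–1 mol m⁻² s⁻¹ for wheat-like geometry); a literal 24.5 can be
  passed instead, and the 1.6 water/CO₂ diffusivity factor can be dropped
  (`boundary_factor=1.0`).  Inputs use microscope units (SD mm⁻², lengths
  µm) and are converted to SI internally.
* **Fluorescence** — ETR = Φ_PSII × PPFD × 0.84 × 0.5; leaf absorptance
  and the PSII quantum fraction are explicit keyword constants.
* **Stomatal metrics** are the adaxial/abaxial average with equal weight;
  SAI is reported in mm² stomata per mm² leaf (SS converted from µm²).

## Relative values, clustering, validation

Genotype responses are expressed as relative values (drought mean /
control mean per genotype per trait).  Columns are standardized to z-scores
(ddof = 1); the ±2 clipping seen in heatmap exports is display-only — all
distances are computed on unclipped scores.  Genotypes and traits are
clustered independently with the Ward.D2 criterion on Euclidean distances
(the implementation delegates to scipy's `linkage(method="ward")`, which is
exactly that criterion; the test suite re-derives every merge from scratch
with a greedy Ward-cost oracle).  The dendrogram is cut into k groups by
removing the k−1 highest merges; k defaults to 3 for genotypes and 2 for
traits and both are configurable.

PCA is the eigen decomposition of the trait correlation matrix; percent
variance shares sum to 100 by construction.

Cluster assignments are validated by leave-one-out linear discriminant
analysis with pooled within-class covariance and uniform class priors.
Because the trait count (37) exceeds the genotype count (14), the pooled
covariance is singular; features are first projected onto the leading
principal components capturing ≥ 90 % of the variance (threshold
configurable).  Folds whose left-out genotype belongs to a singleton class
are skipped with a warning — the class cannot be represented in training —
and the confusion matrix counts only evaluated folds.  Leave-one-out was
chosen as the prediction-capacity protocol because at n = 14 a single
misassignment yields 13/14 ≈ 93 %, the natural resolution of the design.

## MGIDI

Genotype means (drought-condition means by default; across-condition means
or relative values selectable) are rescaled per trait to 0–100 so that the
*desired* extreme maps to 100: for higher-better traits the observed
maximum, for lower-better traits the observed minimum.  The default
lower-better set is {ELWR, C_i, VPD_LA, WUE_L, NPQ, MDA, H₂O₂, MG} —
traits whose drought-driven increase signals stress — and is fully
user-overridable.

Factor analysis of the rescaled matrix: correlation matrix R, eigen
decomposition, retain all factors with λ ≥ 1, initial loadings Λ = V√λ,
normalized (Kaiser) varimax rotation iterated to a 1e-8 criterion change
(1000 sweeps cap), rotated columns sign-fixed and ordered by explained
variance for determinism.  Score coefficients use the regression method
B = R⁻¹Λ*; when R is rank-deficient (inevitable at 37 traits × 14
genotypes) the inverse is a ridge-stabilized pseudo-inverse (ε = 1e-8)
with a logged warning.  The ideotype is the all-100 row, standardized with
the genotype sample's column means/SDs and scored with the same B.  The
index is the Euclidean distance between genotype and ideotype factor
scores.  Because scores transform covariantly under any orthogonal
rotation of the loadings, the index is invariant to the rotation (and to
factor sign/permutation); the rotation only shapes the per-factor
strengths/weaknesses shares, which divide each genotype's squared distance
among factors and sum to one.

Selection takes the ⌈pressure × t⌉ smallest-index genotypes (default
pressure 0.15; 0.30 reproduces a 5-of-14 style selection), ties broken by
identifier.  Selection differentials are computed on the original trait
scale from arithmetic means (no BLUP shrinkage), as
(mean_selected − mean_all)/mean_all × 100, with success flags against the
direction vector and per-direction totals; traits with a zero grand mean
are excluded from totals and flagged.

## Synthetic generator

The generator emulates the screening study's structure, not any real
panel: 14 genotypes, 3 blocks, 37 traits with field-realistic means and
signed drought responses (water status, photochemistry, conductance,
stomatal anatomy and yield decline; C_i, VPD_LA, WUE_L, NPQ, oxidative
markers and osmolytes rise).  Three latent tolerance clusters of sizes
6/7/1 scale the drought main effect multiplicatively (tolerant ×0.5,
intermediate ×1.0, susceptible ×1.6) — clusters differ in response
magnitude, not in control-condition level.  All random effects are normal;
block effects are drawn per block-within-condition.

Calibration choices (made once, documented here):

* Residual, interaction and block SDs default to 4 %, 2 % and 2 % of the
  trait mean.  True per-trait H² targets span 0.55–0.95 (0.45/0.50 for
  Φ_PSII and ETR, the noisiest traits at this design); σ_g is obtained by
  inverting the H² formula, **including** the cluster-induced response
  variance in the interaction term — at e = 2 a genotype-specific
  condition response loads genotype and interaction mean squares equally,
  so this keeps the simulated interaction subordinate to the genotype main
  effect, matching the structure the analysis expects.
* Strong gas-exchange declines are capped near −65 % in the susceptible
  cluster so that rates stay positive at ±3–4 SD.
* Raw-measurement simulation inverts the trait formulas exactly (anchor
  weights/conductivities/fluorescence levels fixed, e.g. F_m = 1500,
  C2 = 1.0); noise is a ±2 SD-clipped multiplicative jitter applied to the
  targets before inversion.  Composite traits (g_m, WUE_L, F_v/F_o, SAI,
  Sg_s, g_s.max) are deterministic functions of other panel traits and are
  recomputed, not independently targeted; `consistent_targets` closes a
  panel before inversion.

What passing tests on this generator do **not** show: real trait
distributions are skewed and heteroscedastic, real G×E is not a clean
three-cluster scaling, assay errors are correlated within plots, and field
trials lose plots (the balanced-only ANOVA would refuse such data).  The
generator certifies the algorithms, not field performance.

## Determinism and numerics

Every stochastic step takes an explicit integer seed (numpy Generator);
the same configuration reproduces every CSV byte for byte, and the run
manifest records the configuration hash and the formula variants in force.
Eigen decompositions fix eigenvector signs by the largest-magnitude
coordinate; varimax fixes column signs/order; agglomeration ties break on
the lowest indices; selection ties break on identifiers.  Degenerate
inputs (zero-variance traits, constant panels, singleton classes, zero
control means, zero MGIDI) are dropped, flagged or errored explicitly
rather than silently propagated.
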
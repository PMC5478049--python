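# Methods

## Shape analysis

**Centroid size** is the square root of the summed *squared* distances of
the landmarks to their centroid — the standard GM size measure. (Informal
descriptions sometimes omit "squared"; the quantity implemented is the
standard one, and it is what GPA removes.)

**GPA.** Full Procrustes superimposition with scaling: each configuration is
centered, scaled to unit centroid size, and iteratively rotated to the
consensus (the renormalized mean shape) until the consensus changes by less
than `tol = 1e-10` in Frobenius norm (`max_iter = 100`; non-convergence
returns `converged=False` with a warning rather than raising). The 2-D
optimal rotation is solved in closed form — the (c, s) pair proportional to
(Σ xᵢ·yᵢ, Σ xᵢ×yᵢ), equivalent to the SVD solution with determinant forced
+1; reflections are never allowed because landmark configurations have fixed
chirality. After convergence the whole set is rotated to a deterministic
orientation (consensus on its principal axes, largest-magnitude consensus
element positive), which makes the output independent of specimen order.
The stored consensus is the plain coordinate-wise mean of the aligned
shapes. For shapes with a nearly isotropic consensus the canonical
orientation is numerically ill-determined; this does not affect any
rotation-invariant downstream quantity (sizes, eigenvalues, test
statistics).

**Tangent PCA** operates on the covariance (not correlation) of the
flattened 2k aligned coordinates, keeping min(n−1, 2k) components; the
aligned coordinates are treated as tangent-space coordinates with no further
re-projection, adequate for the small shape dispersions of within-species
data. Loading signs are fixed (largest-magnitude element positive) so scores
are reproducible across runs and orderings.

**Static allometry** is parameterized per coordinate: ordinary least squares
of each aligned coordinate on *raw* centroid size. Raw rather than log size
is used because the simulation model is linear in size and the LRT is
equivariant to affine transformations of the covariate, so inference is
unchanged either way. The common allometric component (CAC) is the unit
vector of covariances between centered coordinates and size; it is flagged
absent if that covariance is numerically zero.

## The heritability model and test

Scores of one PC are modeled as MVN(β·s + μ₀, σ²(h²K + (1−h²)I)). All fits
are ML, not REML. The kinship matrix is eigendecomposed once; in that basis
the covariance is diagonal for every h², each likelihood evaluation is O(n),
and for fixed h² the nuisance parameters have closed forms (GLS for β, μ₀;
the ML variance for σ²). The alternative therefore reduces to a 1-D profile
likelihood in h², maximized deterministically: a 41-point grid on
[0, 1−10⁻⁶] followed by bounded scalar refinement (`xatol = 1e-10`), with
the null solution h² = 0 always among the candidates so the nesting
L_A ≥ L₀ holds by construction. λ values in (−10⁻⁶, 0) from round-off are
clipped to zero; anything more negative raises. h² is capped at 1−10⁻⁶
because h² = 1 with a singular K would make the covariance singular.

The standard error of ĥ² comes from the curvature of the profile
log-likelihood (central second difference, step 10⁻⁴). At a boundary
optimum the quadratic approximation is meaningless and the SE is reported as
0 — the convention under which boundary estimates are printed as
"h² = 0 (SE = 0)".

**Boundary mixture.** p = 1 at λ = 0, else ½·P(χ²₁ ≥ λ). Two calibration
facts matter in practice, both reproduced by the test suite:

- With *separable* half-sib families (no between-family relatedness), the
  asymptotic picture holds: roughly half the null mass sits at λ = 0 and the
  positive part is χ²₁ (measured at 50 families of 10: boundary mass 0.57,
  Kolmogorov–Smirnov against χ²₁ not rejected).
- With a *colony-baseline* kinship (0.25 between all colony mates), the
  colony-mean axis of K is nearly collinear with the intercept μ₀. The
  profile score at h² = 0 then has negative expectation, the boundary mass
  rises far above ½ (≈0.9 at n = 100), and the realized type-I error at the
  0.0125 level is ≈0.002–0.004: the mixture p-value is *conservative* for
  such kinships, never anti-conservative. Users should interpret borderline
  p-values accordingly.

Identifiability also limits what can be estimated: with very few families
the between-family variance has only (families − 1) degrees of freedom, so
ĥ² is strongly dispersed and boundary clipping biases its *mean* toward the
middle of [0, 1] (with two equal families the mean of ĥ² under a true 0.8 is
near 0.5). Unbiased-looking recovery requires a design with enough families;
the suite demonstrates mean recovery of h² = 0.8 within 0.05 using 20
patrilines of 25.

**Multi-PC testing** applies the LRT to the top `n_pcs` scores (default 4)
at a Bonferroni per-test level family_alpha/n_pcs (default 0.0125). The
default of four reflects a typical eigenvalue spectrum in which a handful of
axes carry interpretable variation; testing all PCs dilutes the correction
and the method's power, and is deliberately not the default.

## The simulator

Each individual is built in shape space as
`template + AD(size) + ND + HD(patriline)` and then multiplied by its drawn
centroid size, so the written coordinates behave like digitized raw data and
the analysis pipeline recovers the size covariate by itself. The shape-space
configurations are also retained on the dataset object.

What the defaults emulate, and why:

- **Template**: a bilaterally symmetric 14-landmark head-capsule-like
  configuration, unit centroid size. Fourteen landmarks is the typical
  density for an insect head case.
- **Sizes**: log-normal, median 1.0, log-SD 0.43 (10–90% range ≈ 0.58–1.74),
  emulating a continuous polymorphic worker size range spanning roughly
  threefold.
- **AD**: per-coordinate linear response to size with slope-vector norm
  0.04, which makes allometry the dominant variance component (PC1 carries
  ≈70–80% of variance in the default configuration). The fixture slope
  vector is a smooth broadening/shortening field projected (a) off the
  similarity-transform directions of the template — translation, scaling,
  rotation — so the generating model lives in the tangent space GPA exposes,
  and (b) to zero at the heritable target landmarks, so the allometric and
  heritable axes are geometrically distinct and PC1 carries the allometric
  signal only, the regime the power analysis is about.
- **ND**: isotropic per-landmark Gaussian noise (no evidence of anisotropic
  digitizing error is assumed), default SD 0.004 shape units per landmark,
  configurable; the standard noise treatment ND1 uses multiplier 1, ND2
  multiplier 2. The power and acceptance runs use SD 0.002.
- **HD**: displacement of two target landmarks (defaults 9 and 10, the
  clypeal corners), standard magnitude 0.01 shape units. Patriline 1 is the
  undeformed reference form; across mating frequency *m* the per-patriline
  magnitudes rise on a linear gradient 0 … maximum (the distribution of
  effect across more than two families is a documented choice — a gradient
  rather than all-or-none). HD5 keeps the maximum independent of *m*; HD6
  inflates it by 5% per mating above the smallest simulated frequency (a
  concrete reading of "slightly increasing" with polyandry, configurable).
  "Parallel" displaces both targets along +y; "orthogonal" uses +y at the
  first target and +x at the second. The absolute reference axis is a
  convention; only the relative orientation of the two displacements
  matters.
- **Treatments**: T1 = (HD1, ND1), T2 = (HD2 = 2×, ND1), T3 = (HD1, ND2),
  T4 = (HD3 = ½×, ND1) for the two-patriline effect-size series; T5o/T5p
  (HD5) and T6o/T6p (HD6) for the multi-patriline series at mating
  frequencies such as 3, 5, 10, 20.
- Patriline blocks are as equal as possible (remainder to the earliest
  patrilines); the random streams for sizes and noise are split from the
  seed independently so toggling one deformation never shifts another's
  draws; a dataset is bit-for-bit reproducible from (treatment, n, mating
  frequency, seed).

What the simulator does **not** emulate: structured non-heritable variation
(developmental environment, within-colony microenvironments), digitizing
outliers, allometric curvature, or bilateral-asymmetry structure. Passing
power tests on simulated data therefore bound what is detectable under the
stated noise model, not under arbitrary real-world confounding.

## Power analysis

Each replicate regenerates a dataset, runs GPA → tangent PCA → kinship →
four-PC LRT, and records per-PC significance; power is the detection
fraction with binomial SE √(p(1−p)/R). Replicate r is seeded by
SeedSequence(master, r), so replicates are independent, individually
reproducible, and a run's first R′ replicates coincide with a standalone
R′-replicate run. Defaults follow the study design: 100 individuals, 100
replicates. The decay curve steps the heritable magnitude linearly from the
standard effect down to half of it (10 steps), the range over which
detection power collapses under the default parameterization.

At the standard effect with noise SD 0.002 the measured operating
characteristics (1000 replicates, mating frequency 3) are: PC2 power 1.0,
PC1 false-detection below 0.01, PC3/PC4 at or near 0 — computed by
`scripts/acceptance.py` and the acceptance tests, not quoted from anywhere.

## Colony statistics

- **Rarefaction**: for each m = 1…n, the mean count of distinct patrilines
  in n_boot (default 1000) random subsamples drawn *without* replacement,
  with a percentile confidence band. On discrete richness the 2.5% quantile
  can exceed the mean near saturation; the band is reported as computed.
- **Chao1**: S_obs + F1²/(2F2), switching automatically to the
  bias-corrected S_obs + F1(F1−1)/2 when no doubletons exist (the classic
  formula divides by zero there). Integer-sequence input is interpreted as
  per-patriline abundances; anything else as per-individual labels.
- **Caste ANOVA**: one-way fixed-effects ANOVA of a continuous caste proxy
  (centroid size, back-leg length) among patrilines. The reported effect
  size is the ML (size-weighted population) SD of the fitted patriline
  means — a single-number summary of how far family means spread.
- **Detectable effect**: injected patriline-mean spreads on an increasing
  grid, a fixed centered mean pattern standardized to unit population SD
  (so the injected "effect" is exactly the SD of patriline means, and for a
  balanced design the noncentrality is n·effect²/σ²), detection = ANOVA
  p < 0.05 in more than half the replicates.

## Degenerate inputs and numerical conventions

- TPS records with mismatched LM counts, non-numeric coordinates, or
  inconsistent landmark counts across records raise with the record/line
  named; unknown TPS keys warn and are skipped; keys are case-insensitive.
- Coincident landmarks (zero centroid size) raise; allometry requires
  non-constant sizes; the PSD of any kinship matrix is verified (tolerance
  1e-8) at construction.
- With K = I the weights do not depend on h², the profile is flat, λ = 0
  and p = 1: an uninformative design cannot produce spurious significance.
- Ties in the PCA sign convention (exactly equal magnitudes) resolve to the
  first index; eigenvalues below round-off may appear as tiny negatives in
  the kinship eigendecomposition and are clipped to zero.

## Problem sizes used in the checks

The packaged checks run the power analysis at 100 individuals per replicate
with 100 replicates for the PC2 power figure and 1000 replicates for the
PC1 specificity figure; parameter recovery uses n = 500 with 200 replicates
and null calibration n = 500 with 1000 replicates. These sizes mirror the
simulated study design while keeping a full run on one CPU around a minute.
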
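# Methods

This note records the models, estimators, numerical choices and open design
decisions behind `meliapop`, in the order the pipeline uses them.

## Marker simulation (island model)

Population allele frequencies follow the Balding–Nichols parameterization:
for ancestral vector `p` and drift parameter `F`, each population's
frequency vector is an independent Dirichlet draw with concentration
`p · (1−F)/F`. This makes `F` a direct dial for expected F_ST — the
between-population variance of each allele's frequency is
`F · p(1−p)` — and `F = 0` degenerates to all populations sharing `p`
exactly. Genotypes are two independent allele draws per diploid, so
populations are in Hardy–Weinberg equilibrium internally by construction.

Defaults mirror the study conditions: 31 populations × 15 diploids × 15
loci, `F = 0.086`. Ancestral vectors are Dirichlet(3) over 8 alleles,
giving expected gene diversity `1 − (c+1)/(kc+1) = 0.84`, i.e. the highly
polymorphic SSR regime (the study's observed per-population He averaged
0.80). The generator does not model mutation, linkage, null alleles, or
spatially structured gene flow; a passing calibration says the estimators
recover a symmetric-island truth, not that real chinaberry data are
island-like.

All streams derive from one integer seed through `numpy` `SeedSequence`
spawn keys, so identical configs are bit-identical.

## Common-garden simulation

Observations follow `Y = μ + block + provenance + family(provenance) +
error` with fixed block offsets and independent normal random effects.
The trial's defaults are 22 provenances with the real unbalanced family
counts (1–26 per provenance, 236 total), 10 blocks, 5 trees per family ×
block, `σ²_P = 0.5`, `σ²_F = 0.0625`, `σ²_E = 1` — i.e. true
`Q_ST = 0.5`, the magnitude the trial reported for growth traits.
Mortality is emulated as missing-at-random thinning; a threshold-liability
0/1 survival trait is available as an option, since the study analysed
survival with the same linear model without stating its observation scale
(we provide both readings and claim neither).

## Diversity statistics

Per population × locus with allele frequencies `p` and `n` typed diploids:
`Na` = allele count; `Ne = 1/Σp²`; `h = 1 − Σp²` (Nei gene diversity);
`He = 2n/(2n−1) · h` (unbiased); `Ho` = observed heterozygote fraction;
`I = −Σ p ln p`; `PIC = 1 − Σp² − Σ_{i<j} 2p_i²p_j²` (Botstein codominant
form); `F_IS = 1 − Ho/h`. The unbiased-He / raw-h assignment is the only
one consistent with a published summary table in which the He column
exceeds the h column in every population. Population values are unweighted
means over loci (±SD); across-population aggregates are unweighted means
over populations.

## Hardy–Weinberg testing

The default exact test is Monte-Carlo: pooled alleles are repeatedly
re-paired at random — a uniform random perfect matching of the allele
multiset is exactly a draw from the conditional-on-allele-counts HWE
distribution — and the p-value is the add-one-corrected fraction of
matchings whose conditional probability (∝ `2^het / Π n_g!`) does not
exceed the observed one. 100 000 shuffles by default (SSR loci have many
alleles, so asymptotic χ² is offered only as a fast alternative).
Bonferroni control counts every population × locus cell: a 31 × 15 grid
gives 465 tests and threshold 0.05/465 ≈ 1.08e-4. Monomorphic cells are
reported non-applicable, not as p = 1.

## Differentiation

G_ST uses Nei–Chesser sample-size-corrected H_S and H_T with the harmonic
mean sample size; the multilocus value is computed from H_S and H_T
averaged over loci, so it is invariant to locus order and to duplicating a
locus. Globally monomorphic loci are excluded from the average with a
record. θ follows Weir–Cockerham (1984) per allele and locus; multilocus
and pairwise values are ratios of summed components `Σa / Σ(a+b+c)`, which
also supplies the locus-bootstrap resampling units. Negative pairwise θ
is reported as computed and truncated at zero only when a matrix is used
as a distance (`DistanceMatrix.clipped()`). Nei's (1972) standard distance
composes identities summed over loci; a pair with zero shared identity is
+∞ and must be capped explicitly by the caller before tree building — no
silent capping.

## REML

The residual variance is profiled out and the two ratios `σ²_P/σ²_E`,
`σ²_F/σ²_E` are optimized on the log scale (bounds e−20…e12, so estimates
are nonnegative and a ratio at the floor is reported as a zero component).
The criterion is evaluated through the random-effect cross-product
matrices via the Woodbury identity — O(q³) per evaluation in the number of
random levels, independent of the number of trees — with three L-BFGS-B
starts followed by a Nelder–Mead polish (the finite-difference L-BFGS-B
stop point can sit ~1e-4 relative off the optimum, which matters when
checking against closed forms; on balanced data the polished optimum
matches sequential-sums-of-squares ANOVA to ≤1e-5 relative). A fit is
flagged non-converged rather than silently accepted. Pairwise Q_ST refits
the model per provenance pair, reusing the full trial's block coding so
block effects stay estimable inside small pairs; pairs where a member has
one family (σ²_F weakly identified), or whose fit fails, are masked with a
reason. Q_ST with both components at zero is flagged undefined, not 0/0.

## Geography and climate

Sites are embedded as `x = (h+R) cos(lat) cos(lon)` etc. with
`R = 6 371 000 m` and elevation `h` in meters (coordinates converted to
radians; the source formula is silent on both, and these are the only
dimensionally consistent readings). The chord runs through the sphere:
it is a lower bound on the great-circle arc and converges to it at short
range, which the tests check against an independent haversine evaluation.
Climate distance is `|v_i − v_j|` per variable. Degree-minute(-second)
strings with optional hemisphere letters are parsed tolerantly (spaces,
ASCII quotes); minutes or seconds ≥ 60 are errors, not wrapped.

## Matrix inference

The Mantel statistic is the Pearson correlation of lower triangles; one
matrix's rows and columns are permuted jointly; p-values carry the +1
correction with 10 000 permutations by default (one-sided positive for
distance–distance tests, two-sided for signed correlation grids). Masked
cells are pairwise-deleted and the retained pair count is always reported.
The IBD regression fits `x/(1−x) = a + b ln d` by OLS over pairs,
excluding `ln 0` cells with a count, and takes its p from the two-sided
Mantel permutation of the transformed matrices. The trait × predictor
correlation grid is reported unadjusted for multiplicity (matching the
source presentation; Holm adjustment is a flag away in the caller's hands
via the returned p column).

## Q_ST–F_ST comparison

The null distribution of `Q_ST − F_ST` under neutrality is built per
resample as follows. (i) F_ST*: multilocus θ recomputed from a bootstrap
sample of loci. (ii) Component estimates: the ANOVA mean squares are drawn
from their χ² sampling distributions — MS_P with `df = n_pops − 1`, MS_F
with `df = n_families − n_pops`, MS_E with the residual df — around their
neutral expectations, and σ²-components are reconstructed by mean-square
subtraction with the balanced EMS coefficients (observations per family,
per provenance). Drawing at the mean-square level rather than the
component level is essential: it propagates the estimator's own sampling
noise, including near-zero components, into the null; drawing components
directly as χ² makes the test sharply anticonservative. Reconstructed
components are clipped at zero, mirroring the REML constraint on the
observed statistic. (iii) Conditioning: the neutral between-provenance
scale is set per resample so that `E[Q_ST*] = F_ST*` for that draw
(`σ²_P0 = 8 σ̂²_F F*/(1−F*)`), which cancels the locus-bootstrap noise in
the difference to first order; one global multiplier on that scale is then
solved by bisection on the drawn sample itself (common random numbers) so
the null mean is exactly zero despite the ratio's Jensen bias.

The observed difference is located in this null: critical values at
2.5%/97.5%, two-tailed `p = 2·min(tail fractions)` with +1 correction,
default 10 000 resamples, and a divergent/neutral/uniform call. The test
refuses < 5 loci or < 3 populations. Calibration note: with very few
populations (df_P ≲ 8) the nonnegativity of the observed Q_ST leaves the
two-tailed test almost no usable lower tail and rejection rates fall well
below nominal; the calibration suite therefore runs at 12 populations,
the mildest reduction from the trial's 22 that avoids this small-df
artifact, where the neutral rejection rate is ~0.04 at α = 0.05 and power
against 10× inflated σ²_P exceeds 0.9.

## Trees and ΔK

Neighbor joining is the Saitou–Nei algorithm with two determinism
conventions: Q-criterion ties break on the lexicographically smallest
cluster-label pair, and negative branch lengths are clamped to zero with
the deficit moved to the sibling branch (counted on the result). On an
additive matrix the tree reproduces all leaf-to-leaf path lengths exactly.
Bootstrap support resamples loci with replacement, recomputes Nei distance
and the NJ tree, and scores each original bipartition by its replicate
fraction; replicates with infinite distances are skipped and counted.
Newick output quotes labels containing metacharacters and round-trips
through the module's own parser. The Evanno table computes
`L'(K) = mean L(K) − mean L(K−1)`, `L''(K) = |L'(K+1) − L'(K)|`,
`ΔK = L''(K)/SD(L(K))` over replicate clustering log-likelihoods; ΔK is
undefined at the edge K values and flagged where the run SD is zero. The
clustering runs themselves are external input — only the model selection
is implemented.

## Problem sizes and runtime

The test suite and the acceptance script scale their simulations to
single-CPU minutes as the package's own default study sizes: F_ST
calibration uses 50 replicates at the full 31-population design;
variance-component recovery uses 50 trial-scale REML fits (11 800
observations each); Q_ST–F_ST calibration uses 200–400 neutral replicates
at the 12-population reduced design with 600 resamples each. The pairwise
Q_ST matrix at the full design (231 refits) lives in the analysis drivers.

## Known limitations

- The island model has no spatial structure, so simulated IBD slopes are
  ~0 by construction; IBD machinery is validated on constructed inputs and
  the published coefficient table instead.
- SR (survival) is analysed on the observed 0/1 scale with the same linear
  model as the growth traits; no link function is used.
- The EMS coefficients inside the Q_ST–F_ST null use balanced-design
  formulas (totals per family / per provenance); strongly unbalanced
  designs inherit an approximation there, though the trial's own family
  counts are handled exactly in the REML fit itself.
- Pairwise θ/G_ST matrices treat populations as exchangeable samples;
  no correction for null alleles or genotyping error is attempted.
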
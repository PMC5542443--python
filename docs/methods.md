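# Methods

This note documents the statistical models implemented in `finekin`, the
numerical and design choices made where conventions differ between
programs, what the synthetic-data generator does and does not emulate,
and the problem sizes the test suite uses.

## Kinship and the correlogram

Pairwise kinship uses the Loiselle et al. (1995) estimator. For locus
`l` with allele frequencies `p_a` estimated from the whole sample and
`n_l` typed gene copies, each allele contributes
`(x_ia − p_a)(x_ja − p_a) + p_a(1 − p_a)/(n_l − 1)` to the numerator and
`p_a(1 − p_a)` to the denominator, with `x` the individual allele dosage
(0, ½, 1 diploid; 0, 1 haploid). Multilocus values are the ratio of
locus-summed numerators to denominators; per-locus components are
retained so the jackknife can delete one locus at a time. A pair with no
co-typed locus is missing and excluded downstream with a count. Because
of the finite-sample bias-correction term, the all-pair average of this
estimator sits at ≈ 0 on panmictic data (the correction cancels the
−1/(2n) shift that sample-referenced estimators otherwise carry); the
property suite asserts exactly this.

Distance classes are built by ranking all pairs by distance (stable on
ties) and cutting into near-equal chunks, which keeps pair counts
balanced even when many distances tie (regular transects, grids).
Diagnostics follow the standard recommendations — similar pair counts,
more than 50% of individuals represented per class, coefficient of
variation of per-individual representation below 1 — and a failing
scheme is returned flagged rather than silently used.

The regression of `F_ij` on the natural logarithm of distance uses all
pairs with positive distance and defined kinship. Choices worth stating:

- **Natural log.** The base only rescales `b`, and `Sp` inherits the
  choice; ln is the convention of the standard FSGS software.
- **Zero-distance pairs** (co-located clones) are excluded from the
  regression (ln 0 undefined) but included in first-class means; their
  count is reported.
- **Permutation unit** is the individual: the genotype-to-location
  assignment is shuffled, kinship held fixed. The test is one-sided for
  `b < 0` with `P = (extreme + 1)/(n_perm + 1)`.
- **Jackknife** deletes one locus; with ≤ 3 loci the SE is reported with
  a small-sample warning. The reported `b` is the jackknife mean; the
  raw slope is also kept. `Sp = −b/(1 − F1)` is recomputed independently
  in the tests on every output.

## Spatial PCA and the G/L tests

The operator is `C = Xᵀ(W + Wᵀ)X / (2n)` with `X` the
allele-frequency-centred dosage matrix (missing genotypes mean-imputed
per allele column before centring) and `W` the row-normalised connection
network; with an identity weight matrix this degenerates to ordinary PCA
of dosages, which the tests verify to 1e−10 along with conservation of
the operator trace. The default network is 10-nearest-neighbours
symmetrised by union — robust to the transect geometries common in field
sampling; distance-threshold and Gabriel rules are available, and a
disconnected graph is a warning, not an error. The G statistic is the
positive eigenvalue mass, the L statistic the absolute negative mass;
both are re-specified here as permutation tests (genotype rows shuffled
over locations) rather than the original spectral formulation —
equivalence with the original tests is not claimed, and the calibration
requirement (uniform null P) is the acceptance surface. Axis signs are
fixed by making each score's correlation with the x-coordinate
non-negative.

## Admixture model

The sampler implements the admixture model with **independent**
Dirichlet (λ = 1) cluster allele frequencies. The original analysis this
package follows used the correlated-frequencies variant; the clusters it
deals with are strongly differentiated and recoverable under either
prior, so the simpler model is the default here and the deviation is
deliberate. Updates per sweep: latent allele-copy origins `z` from
`Q_i,k · P_k,l,a`; `P` from Dirichlet(1 + counts); `Q` from
Dirichlet(α + n_ik); α by a Metropolis step (proposal SD 0.025, prior
uniform on (0, 10], one α shared by all clusters). Missing alleles are
skipped in both the updates and the likelihood. `L(K)` is the standard
`mean − variance/2` estimator of the model log-probability over the
post-burn-in likelihood trace; for K = 1 it is checked against the exact
Dirichlet-multinomial marginal (agreement within ~1 nat on toy data),
and the K = 1 posterior allele frequencies are checked against their
closed-form Dirichlet conditional. These closed-form conditional checks
stand in for a full simulator-consistency (Geweke-style) audit. ΔK
follows Evanno (`|L(K−1) − 2L(K) + L(K+1)| / sd(L(K))`, interior K, ≥ 2
replicates, undefined when the sd is zero); disagreement between L(K)
and ΔK is flagged, never auto-resolved. On unstructured data `L(K)` is
noisy across K — a well-known property of the estimator — so "no
structure" is asserted through symmetric ancestry and the absence of
decisive support for K > 1, not through a strict argmax. Label switching
across replicates is resolved by Hungarian matching on Q-column
covariance; alignment cannot change PI or L(K). Defaults follow common
practice (burn-in 20,000, total length 80,000); the test suite uses
500–2,000 burn-in and 2,000–4,000 total on 60–80 individuals, where the
strongly differentiated test scenarios mix quickly.

## Diversity, null alleles, clonality

Allelic richness is exact hypergeometric rarefaction,
`A_R = Σ_a [1 − C(N−N_a, g)/C(N, g)]`. Rarefaction is in **gene copies**
(2 × the stated number of individuals for diploids; individuals for the
haploid plastid marker); this convention is a documented choice since
"a sample of g individuals" is ambiguous between copies and individuals.
`H_E` is Nei's unbiased gene diversity with a delete-one-locus jackknife
SE. `F_IS = 1 − H_O/H_E` per locus, multilocus by ratio of locus sums;
the null re-pairs gene copies within loci.

The null-allele frequency `r` is the maximum-likelihood (EM) estimate
under the one-null-allele HWE model in which whole-locus amplification
failures are candidate null homozygotes — the model behind Brookfield's
(1996) second estimator; the published closed form is not reproduced
here, the likelihood is maximised directly. A locus with no heterozygote
deficit reports r = 0 and no correction. `F_IS*` adds the estimated
visible/null heterozygotes back into `H_O` and includes the null allele
in `H_E`. No permutation scheme exists for a null-corrected index, so
its significance is assessed by parametric Monte Carlo: simulate HWE
data with the fitted frequencies (including nulls), re-apply the same
masking and correction, and compare. Note the estimator deliberately
cannot distinguish a Wahlund effect from nulls when no blanks are
observed; in that case `r` absorbs part of the deficit but the corrected
index remains positive and significant, which is the behaviour the tests
pin down.

psex uses the plug-in genotype probability (HWE, optionally F-adjusted)
and the binomial upper tail `P(X ≥ k−1)` over the other N−1 individuals;
the clone-call threshold defaults to psex < 0.01. psex grows with N at
fixed genotype probability (more draws, more chances) and shrinks as the
genotype gets rarer.

## Association battery

`F_ST` among gene pools is Weir–Cockerham (1984) θ, ratio of the summed
a-components to the summed (a+b+c) over loci and alleles, with a
label-permutation test; unassigned individuals are dropped and at least
two groups of two are required. ANOVA of sPCA scores is the ordinary
one-way decomposition (two groups reduce exactly to the pooled t). The
Fisher test is exact (hypergeometric, two-sided) for 2×2 and
fixed-margin Monte Carlo with the probability-based criterion for larger
tables (margins paired by random permutation — the classical fixed-margin
sampler). Partial Mantel correlates off-diagonal similarities controlling
for spatial distance, permuting rows/columns of the first matrix jointly
(9,999 default); with a constant control it reduces exactly to the simple
Mantel test. The between-continent contrast is the pooled-variance
one-tailed Student t (df = n₁+n₂−2): recomputing the published contrast
from the printed per-population values reproduces the printed P only
under the pooled form, which fixed this choice. Spearman tests on ≤ 10
populations enumerate all n! rank permutations for an exact one-sided P
(5040 permutations for n = 7 are instant); midranks handle ties. No
multiple-testing correction is applied across the battery, matching the
analysis this package mirrors.

## The simulator

Non-overlapping generations on a rectangular habitat gridded into cells
of fixed carrying capacity (`capacity = density × cell area`), which
keeps the census density interpretable as the `D` in the Sp theory
check. Offspring slots are placed uniformly within cells; each
offspring's mother is drawn by backward application of the Gaussian seed
kernel (this fills every cell exactly to capacity — density regulation
by competition among arriving seeds), its father by the pollen kernel
from the mother (the mother herself at the selfing rate; fathers are
otherwise drawn without the mother). Nuclear alleles are transmitted
Mendelian with stepwise mutation (μ = 10⁻³ per copy) on a 40-state
ladder, bounded to emulate the 3–35 alleles/locus range of real SSR
panels; the plastid haplotype is strictly maternal with rare mutation to
a new label. Kernels are Gaussian by design: leptokurtic kernels would
break the `Sp ≈ 1/(4πDσ_g²)` anchor that the calibration tests rely on.
Equilibration defaults to `10 × span/σ_g` generations — enough for FSGS,
which approaches its drift–dispersal equilibrium shape within tens of
generations, though not for full coalescent equilibrium of diversity.

Scenarios: `panmixia` (kernels as wide as the habitat — the calibrated
null), `ibd` (kernels sized so `1/(4πDσ_g²)` hits a requested Sp, default
0.01 at D = 0.01/m², i.e. 100 stems/ha), `two_deme_contact` (founders in
two halves with Dirichlet-perturbed allele frequencies at a target
differentiation, deme-specific haplotypes, assortative mating, few
generations so the contact is recent — realised Weir–Cockerham F_ST
averages ≈ 0.15–0.17 at the default target of 0.15), and
`altitudinal_barrier` (linear altitude in x; kernel weights across the
mid-altitude contour multiplied by a permeability). The truth record
carries deme of origin, continuous ancestry, the dispersal parameters
and the realised null-allele states, sufficient to score recovery.

What the generator does **not** emulate: overlapping generations and age
structure, leptokurtic or anisotropic dispersal, selection and
microhabitat adaptation, genotyping error other than null alleles
(stutter, allele dropout), and mutation models other than strict
stepwise. Passing tests therefore demonstrate correct behaviour under
the drift–dispersal model with Gaussian kernels, not robustness to every
feature of field data.

## Problem sizes and reproducibility

Every stochastic routine takes an explicit seed; a fixed configuration
reproduces its output byte for byte, and the pipeline writes a manifest
with the full configuration and its hash. The test suite runs the
calibration checks at 200 replicates × 99 permutations on 15–25
individuals and 2–3 loci, the admixture recovery on 80 individuals with
2,000–4,000 sweeps, and the IBD calibration on 10 replicate worlds of
1,000 individuals sampled to 100 — sizes chosen so the whole suite
completes in a couple of minutes on one core while keeping every check
at its stated statistical strength. Production analyses should use the
defaults (10,000 permutations, 20,000/80,000 MCMC).

## Known limitations

- The G/L tests are calibrated permutation analogues, not the original
  spectral tests; only their null calibration and power patterns are
  guaranteed.
- The null-allele model is confounded with substructure in the absence
  of amplification failures; `F_IS*` should be read jointly with the
  clustering results.
- `L(K)` inherits the instability of the mean−variance/2 estimator on
  weakly structured data; ΔK and the ancestry matrix should always be
  inspected together, and conflicts are reported rather than resolved.
- The equirectangular lon/lat projection is only meant for sampling
  extents up to a few kilometres.
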
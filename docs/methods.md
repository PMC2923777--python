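# Methods

`peakpattern` infers the *spatial patterning* of supra-threshold local
maxima ("events") in statistical parametric maps over a pre-specified
partition of the search volume. It deliberately ignores the height,
extent and absolute number of activations: the data feature is the vector
of regional event counts.

## The null model

For a smooth statistic field under the null, high local maxima behave as
a homogeneous Poisson point process *in resel space* (the Poisson
clumping heuristic): region j receives `d_j ~ Poisson(lambda |A_j|)`
independently, where `|A_j|` is the region's resel count. Conditioning on
the observed total `k = sum d_j` removes the nuisance rate `lambda` and
leaves a multinomial likelihood

    p(d | a) = k! / prod(d_j!) * prod(a_j ^ d_j),   a_j = |A_j| / |A|.

Everything downstream — the chi-square pattern test, the exact binomial
small-volume p-value for a two-region partition, and the Bayesian model
comparison — is built on this conditional multinomial. The rate `lambda`
never needs to be estimated; it appears only in a simulation-based
property test of the conditioning argument itself.

## Resel geometry

Regional statistical volumes are estimated with the conventional
resels-per-voxel (RPV) approach: GLM residual volumes are standardized to
unit sum of squares per voxel, per-axis spatial gradients are formed by
forward differences (a voxel contributes to an axis only when its +1
neighbour is in-mask), the 3x3 gradient covariance `Lambda` is
accumulated over volumes, and the resel density is
`(4 ln 2)^(-3/2) |Lambda|^(1/2)`. Regional resel counts are sums of this
density over the region's voxels; relative volumes `a_j` are the
normalised sums.

Numerical choices:

- Boundary voxels missing a +1 neighbour on some axis have the affected
  covariance entries imputed from the mask mean of that entry; voxels
  where nothing is computable (isolated voxels, all-zero residuals)
  receive the mask-mean density. This avoids bias holes without
  discarding regions.
- Negative determinants arising from floating-point noise are clamped to
  zero before the square root.
- No degrees-of-freedom bias correction is applied: the small-sample bias
  of `|Lambda|^(1/2)` is spatially uniform to first order and cancels in
  the relative volumes that the inference actually uses.
- Forward differencing underestimates the gradient variance of a smooth
  field by a factor of roughly `1 - ln 2 / f^2` per axis at FWHM `f`
  voxels, so total resel counts run ~13% low at `f = 3` and within 10%
  of the stationary closed form `V / f^3` from `f ≈ 4` upward. Relative
  volumes are far less affected, because the bias is shared across
  regions of similar smoothness.
- No smoothing is applied to the RPV image: regional sums are invariant
  to volume-preserving smoothing, and only sums enter the model.

The `isotropic_rel_volume` shortcut (voxel-count shares) is exact when
smoothness is stationary, and is offered for that case only.

## Event detection

A peak is an in-mask voxel above the height threshold (default `t = 3`,
statistic units) that strictly exceeds all in-mask neighbours under
26-connectivity (18 optional); out-of-mask neighbours count as -inf.
Connected plateaus of exactly equal value that dominate their
surroundings — a measure-zero event for continuous fields, but routine
in integer-valued test fixtures — contribute one peak at the
lexicographically smallest coordinate; a constant region with no in-mask
surroundings is not a maximum. An optional `one_per_excursion` mode keeps
only the global maximum of each supra-threshold connected component,
which is the safer convention at low thresholds where one blob can carry
several nearby maxima. Low thresholds raise the fraction of noise events,
very high thresholds starve the counts; `t = 3` is a practical
compromise.

## Fixed-effects inference

With between-subject variation treated as noise, regional event and
resel counts are pooled over subjects and analysed as one count vector.
Two models are compared with equal prior probability: M0 pins the
pattern to the chance vector `a` (Dirac prior), M1 gives it a Jeffreys
Dirichlet prior (all concentrations 1/2). Both evidences are analytic
(multinomial pmf; Dirichlet-multinomial marginal), giving an exact Bayes
factor; the integrated likelihood automatically penalises M1's freedom
(Occam's razor — for a bipartition the prior-predictive count variance is
`k a (1-a) [1 + (k-1)/(c+1)]`, strictly decreasing in the prior
concentration `c`, so the point-null wins whenever the data sit near
`a`). A Bayes factor of 20 is used as the conventional "very strong"
decision threshold.

Under M1 the posterior is Dirichlet `Dir(d + 1/2)`, with Beta marginals
`theta_j ~ Beta(d_j + 1/2, k - d_j + (n-1)/2)`. Because the posterior is
unimodal, central credible intervals are used. Reporting n marginal
intervals raises a multiplicity problem, handled by inflating each
interval: the net tail credibility is `epsilon = (1 - x)/(n - 1)`
(default `x = 0.99`), split equally between tails — a Bonferroni-like
penalty in the number of free parameters. A region is flagged "rich"
("sparse") when its interval lies wholly above (below) `a_j`, using
strict exclusion of the closed interval.

## Random-effects inference

When patterning genuinely varies across subjects, each subject's pattern
`theta_i` is modelled as a draw from a population Dirichlet `Dir(c m)`:
`m` is the population mean pattern of interest, `c > 0` the
between-subject concentration. `theta_i` integrates out analytically
(conjugacy), leaving a Dirichlet-multinomial likelihood per subject.

The prior `p(m, c)` is not dictated by the model; the package's default
is `m ~ Dir(1/n, ..., 1/n)` — the symmetric Dirichlet with *total*
concentration 1 — and `log c ~ U[log 0.1, log 1e4]`, both configurable.
The total-weight-1 choice matters: a uniform-density `Dir(1, ..., 1)`
carries n pseudo-counts, and when events are scarce relative to the
number of regions it drags every marginal mean toward `1/n`. With a
strongly non-uniform chance pattern (a dominant rest-of-volume region
has `a_j` far above `1/n`) that shrinkage alone flags null data; in the
package's own null study the uniform-density prior inflated the
family-wise error to 0.85 at 21 regions, while the single-pseudo-event
prior restores nominal control. `Dir(1/n)` adds the weight of one event
regardless of n, so its influence vanishes as data accrue at any
partition size. The posterior over
`(m, c)` is sampled by adaptive random-walk Metropolis on unconstrained
coordinates (additive log-ratio transform of `m`, plus `log c`, with the
log-Jacobian `sum log m_j` included). Burn-in adapts a global step scale
toward 30% acceptance and, Haario-style, the proposal covariance from
the accumulated burn-in history — necessary because the simplex induces
strong negative correlations; both are frozen afterwards. Defaults: 4
chains, 10 000 iterations, 2 000 burn-in, optional thinning; the seed is
mandatory and runs are bit-reproducible. Split-Rhat is reported per
coordinate and the result is *flagged* (never silently returned) when
any Rhat exceeds 1.1. Marginal intervals on `m_j` use the same
penalised level as FFX, and flags compare against a single chance
vector — the resel-weighted mean of the per-subject `a_i` (plain mean
when resels are unavailable). The penalised tails are extreme (mass
`~1e-4` per tail at 20 regions), where raw empirical quantiles of a few
thousand correlated draws collapse onto the sample extremes and
understate the interval; the default therefore reads the tail quantiles
from a moment-matched Beta fit to each marginal (simplex marginals are
smooth, unimodal [0,1] variables for which the fit is accurate), with
the plain sort-based quantiles available as `method="empirical"` and
used automatically for degenerate marginals.

The integrated likelihood of the free-`m` RFX model has no analytic
form, so model-level Bayes factors are not computed for it; inference is
restricted to the population means. Informed models — population mean
pinned to a hypothesised pattern — are the exception: only the scalar
`c` remains, integrated by adaptive 1D quadrature on `log c`, and paired
evaluations (null vs alternative pattern) give an exact RFX Bayes
factor. The "pinning" is interpreted at the population level (the delta
prior fixes `m`, not each `theta_i`), which keeps between-subject
dispersion in the model.

FFX is the low-heterogeneity limit of RFX (`c -> inf`), and the two
agree there; FFX remains attractive in practice because its evidence is
exact and cheap, and it is robust to *within*-region heterogeneity,
which the regional counts never see.

## Null simulator and frequentist audit

The Bayesian decisions are audited frequentistly on simulated pure-noise
data with realistic non-stationary smoothness:

1. Each subject gets a random Voronoi layout of 20 cells; each cell a
   FWHM drawn uniformly on [4, 10] units (1 unit = 1 voxel = 1 mm; only
   relative smoothness matters under the null).
2. Each scan is iid N(0,1) noise; every cell takes its voxels from the
   whole volume smoothed at the cell's FWHM (mask-composition of
   whole-volume smoothings avoids edge renormalisation artefacts), and
   the composite is re-smoothed at FWHM 2 to preclude sharp transitions.
   Smoothing is separable Gaussian convolution truncated at 4 sigma.
3. A mean-effect GLM gives the subject's t-field (df = scans - 1);
   residuals give its RPV image, and per-subject smoothing is applied
   per scan before the GLM.
4. A fixed "anatomical-style" Voronoi parcellation (distinct from the
   smoothness layouts) stands in for a labelled atlas; any integer atlas
   can be substituted. Each experiment draws a random group and N random
   atlas regions plus the rest-of-volume complement (the full-atlas case
   omits the rest region), pools counts and resels, and runs the
   inference.

Reported operating characteristics: the rate of decisive Bayes factors
(BF >= 20) and the family-wise error rate — the fraction of null
experiments with at least one flagged region.

Reference conditions are a 64^3 lattice, 84 scans, a 1000-subject
corpus and 150 experiments of 20 subjects. The package's routine study
profile (`NullSimConfig.scaled_down()`) keeps the identical statistical
structure at a reduced problem size — 32^3 lattice, 24 scans, 300
subjects, 100 experiments of 10, a 60-region atlas — chosen so the whole
study runs in minutes on one core; the full-scale profile remains one
flag away. At the reduced scale each subject yields roughly 80-90 resels
and a handful of peaks at `t = 3`, so pooled totals per experiment are
several dozen events.

What the simulator does and does not emulate: it reproduces the
non-stationary smoothness, the t-field null distribution, and the
resel-count machinery end to end, so passing audits shows the conditional
multinomial calculus and the multiplicity penalty control errors under a
truthful null. It does not simulate BOLD physiology, task designs,
physiological noise, registration error or anatomically realistic
parcellations, so it cannot by itself validate behaviour under model
violations in real data (the companion check for real data is
`null_spm_sanity`, which tests whether observed event fractions track
relative resel counts).

## Degenerate inputs and tie-breaks

- A region with (near-)zero resel mass makes the null pmf degenerate;
  `region_resels` refuses it (default floor 1e-6 resels) and instructs
  merging or exclusion.
- Zero total events: the chi-square test raises; `null_spm_sanity`
  reports "no test".
- Exact plateau ties and equal-height excursion maxima break
  lexicographically; Voronoi distance ties go to the lowest seed index.
- `k = 0` or single-region partitions disable interval machinery (no
  free parameter).

## Known limitations

- Resel totals are biased low at FWHM below ~4 voxels (forward-difference
  discretization; see above).
- The random-walk sampler needs long chains for partitions beyond ~30
  regions; the FFX path (exact, analytic) is recommended for
  high-dimensional exploratory partitions.
- Counts tables carry one resel vector per subject only when produced by
  the library; the TSV interchange format shares one resel column across
  subjects.
- Cluster-extent/peak-height inference, surface-based resel estimation,
  covariate effects on patterning and non-parametric random effects are
  out of scope.
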
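# Methods

This note records the model, the numerical choices and the limitations of
the implementation, in the order the pipeline runs.

## Template model

A template of charge c anchored at m (m/z of the pattern's most intense
peak) is

    φ(x) = Σ_k a_k · ψ_θ(x − (m + κ k / c)),

where the isotopic weights a_k come from the averagine model evaluated at
the neutral mass c·m − c·m_proton, k is indexed relative to the most
intense peak (k = 0 at the anchor, negative k toward the monoisotopic
peak), and ψ_θ is the single-peak model.  Each template is max-normalized
on a grid of spacing σ/50, so a fitted coefficient is the intensity of the
pattern's most intense peak.

* **Averagine.**  The average residue composition C4.9384 H7.7583 N1.3577
  O1.4773 S0.0417 per 111.1254 Da (Senko's averagine) is scaled to the
  target mass; C/N/O/S counts are rounded to integers and hydrogen is
  adjusted so the monoisotopic mass matches.  Elemental isotope
  distributions (IUPAC abundances) are convolved by binary exponentiation;
  trailing peaks below `trim_rel` (default 0.01) of the maximum are
  trimmed, which bounds template support and hence the Gram bandwidth.
* **Peak shapes.**  The Gaussian is implemented unit-height (the 1/(σ√2π)
  prefactor cancels under max-normalization).  The EMG density

      ψ(x) = (1/α) exp(σ²/2α² + (μ−d)/α) (1 − F(σ/α + (μ−d)/σ)),  d = x−m,

  with F the standard normal CDF, models right-tailed peaks (late ion
  formation in MALDI-TOF).  It is evaluated through the scaled
  complementary error function: combining the exponent with
  erfc(z) = erfcx(z)·exp(−z²) reduces the exponential factor to exactly
  −d'²/2σ² (d' = d−μ), so the formula never overflows, verified up to
  σ/α = 1e4.  For α → 0 the EMG degenerates to the Gaussian.
* **κ** defaults to 1.00235 Da (configurable within the physically
  sensible band 1.002–1.008 Da).

## Peak-shape calibration

Well-resolved peaks are detected by quantile-gated local maxima (apex
above the 0.75 intensity quantile) grown outward while the intensity
descends (one violation tolerated per side).  A region is *well resolved*
only if it decays on both sides to a floor of 5% of the apex, measured
above a baseline proxy (the 25% intensity quantile) — a peak interrupted
by a valley, i.e. overlapped by a neighbour, is rejected, and retained
apexes closer than `min_separation` (0.3 Th) are discarded pairwise.
Regions need at least 8 points; fewer than `min_regions` (5) regions is a
calibration failure that falls back to user-supplied shape parameters.

Each region is fitted by nonlinear least squares with a free
multiplicative height (the EMG is not unit-height; the height is
discarded).  Fits whose width exceeds the region span (no curvature
evidence — e.g. flat noise fitted by a near-constant wide Gaussian) or
whose relative residual sum of squares exceeds 0.2 are excluded.  The
surviving (apex, θ̂) pairs feed linear trends θ_l(x) = Σ_m ν_{l,m} g_{l,m}(x)
with default basis {1, x}, fitted by least absolute deviation (quantile
regression at the median; a single constant column reduces exactly to the
median, and an exactly-interpolating least-squares fit is returned
directly since a zero-residual fit is already LAD-optimal).  Evaluation
clips σ and α below at 1e−4 Th.

Limitation: two equal peaks closer than ~2σ merge into a strictly
unimodal bump that is indistinguishable from a single wider peak at
detection time; such contaminated estimates enter the trend fit as
outliers and are absorbed by the LAD regression.

## Noise model and placement

LNL(x) is the median intensity in [x−h, x+h] (default h = 2.5 Th, wide
enough that the window sees mostly noise around an isotope pattern);
boundary windows are truncated, not padded.  Being a median, LNL is
robust and equivariant under monotone intensity transforms (exactly so
for odd window counts).  LNL₊ = max(LNL, ¼·median(LNL)) guards the
signal-to-noise denominator in low-intensity regions.  Templates are
placed at every datum with y > `factor_place`·LNL (default 1.5 — a
permissive gate; specificity is delegated to thresholding), one per
charge state.

## Fitting

The fit solves min_{β≥0} ‖y − Φβ‖_q^q by a log-barrier interior-point
method: barrier weight γ runs from 10 to 1e8 in factors of 10 (about
eight stages, standard log-barrier practice; γ_max is configurable and
tests that compare objectives against oracles at 1e−8 relative tighten it
to 1e12, since the duality gap of a barrier stage is bounded by the
number of constraints over γ).  Each stage is minimized by Newton's
method with backtracking line search that keeps all barrier arguments
strictly positive; the strictly feasible start is β = 1e−3·max(Φᵀy)·1
(and r = 1.5·|y − Φβ| + ε for q = 1).

For q = 2 the Hessian is ΦᵀΦ + diag(1/γβ²); the Gram matrix is formed
once and only the diagonal changes per step.  For q = 1 the LP
reformulation (minimize 1ᵀr subject to ±(Φβ − y) + r ≥ 0, r ≥ 0, β ≥ 0)
is solved with barrier terms on all constraints; the (r, β) Newton system
is reduced by block elimination of the diagonal r-block, leaving a system
with the scaled-Gram sparsity that must be re-formed every step.  In both
cases the system matrix, after permuting columns by support position, is
a band matrix (templates are localized and supports are contiguous by
construction), and is factorized by banded Cholesky; a dense-Cholesky
mode exists and produces identical solutions, which the tests assert.
On factorization failure a diagonal regularization of 1e−12·trace/p is
added once.  Zero-norm columns are rejected at input validation.  Results
carry a KKT certificate (dual feasibility and complementarity for q = 2,
the barrier duality-gap bound for q = 1) and the per-stage objective
sequence, which is non-increasing along the central path.

The weighted non-negative lasso min_{β≥0} ‖y−Φβ‖² + λ·1ᵀWβ (W = diag of
LNL₊ at the anchors, rescaling the penalty by local noise) reuses the
same machinery — the linear term only shifts the gradient — and reduces
exactly to NNLS at λ = 0.  It is provided as a comparison baseline, not
used by the pipeline.

## Postprocessing, scoring, thresholding

Interior-point coefficients are never exactly zero; a template counts as
active when β̂ exceeds 1e−6 of the largest coefficient.  Measured
coefficient spectra separate cleanly (genuine contributions above ~1e−2
relative, barrier zeros below ~1e−7, and the latter scale *inversely*
with intensity, so a much smaller cutoff would make the active set — and
the grouping below — unstable under rescaling of the spectrum).

Active anchors of the same charge are chained into groups while
consecutive gaps stay below `merge_ppm`.  Each group is collapsed by
minimizing ∫(Σ_j β̂_j ψ_{m_j}(x) − β ψ_m(x))² dx over continuous (m, β),
sampled on a grid of spacing min(σ/20, data spacing/4) over the group
support ± 5σ and solved by nonlinear least squares initialized at the
coefficient-weighted mean anchor and the summed coefficient.  Shape
parameters inside the integral are evaluated at the weighted mean anchor
(members of one group are at most a few sampling intervals apart, so the
trend variation across them is negligible).  Singletons pass through;
optimizer failure falls back to the largest-coefficient member, flagged.
This repairs *peak splitting* — adjacent templates sharing the weight of
one true pattern whose apex fell between grid points — and localizes
patterns below the sampling rate.

`merge_ppm` must span a few sampling intervals to do its job: the default
100 ppm suits TOF-like sampling (0.01–0.02 Th); for 0.06 Th ion-trap
grids around m/z 350, adjacent points are ~170 ppm apart and ~300 ppm is
appropriate.  The overlap studies in the tests use 300 ppm for exactly
this reason.

Each merged feature (m̃, β̃) is scored as ratio = GOF₊(m̃)·β̃/LNL₊(m̃),
with both statistics looked up at the datum nearest m̃ (they are
step-like window statistics; interpolation would add nothing).  GOF₊ is
computed from a fit of the spectrum by *single* peaks placed at every
datum (same shape model and q as the main fit):
GOF₊(x) = min(1 − Σ_w |r_i|^q / Σ_w |y_i|^q, 0.5) over the same windows
as the LNL, with all-zero windows given the neutral value 0.5.  The cap
at 0.5 limits the influence of the correction; it is implemented as
printed and the cap value and min/max mode are configurable.  The
monoisotopic m/z is reported as m̃ − k_max·κ/c with k_max the averagine
most-intense index at the feature's neutral mass (the anchor is the most
intense peak, not the monoisotopic one; this conversion is this package's
construction).  Thresholding keeps ratio ≥ t — a pure filter on a single
fit, no re-fitting.  The optional peptide-mass filter keeps features
whose neutral mass lies within 200 ppm of the nearest empirical peptide
mass center 1.000485·m_n + 0.029 (integer nominal masses m_n).

## Synthetic data and what the tests show

The generator sums height-scaled, max-normalized averagine templates on a
regular grid and adds a constant baseline, additive Gaussian noise (sd
relative to the largest height) and optionally multiplicative log-normal
noise, clipping at zero.  It emulates the study conditions used
throughout the tests: a five-pattern spectrum (charges 1–3, 0.06 Th
spacing, 0.5% baseline, no random noise) for end-to-end recovery, and the
1:1 charge-2/charge-3 overlap of GACLLPK (2+, 351.204) and CCTKPESER
(3+, 351.488) at 0.06 Th spacing with 2% additive noise and 1% baseline
for unmixing.  The "noise-free" fixture deliberately keeps the small
constant baseline: with an identically zero noise floor the LNL vanishes
and every ratio is infinite, a degenerate regime real spectra never
present.

What it does not emulate: chemical and matrix artifact patterns,
non-averagine compositions, baseline drift, detector saturation,
retention-time structure, and centroided input.  Passing tests therefore
demonstrate correctness of the algorithmic chain under its model
assumptions, not instrument-level performance.

Evaluation matches peaklist entries to truth greedily, one-to-one, by
increasing relative m/z distance within a ppm tolerance and same charge;
recall = matched/truth, precision = matched/list (0 for an empty list).

## Default parameters

| parameter | default | meaning |
|---|---|---|
| charges | 1–4 | charge states considered |
| peak shape | gaussian | template single-peak model |
| q | 2 | fitting norm (2 = NNLS, 1 = NNLAD) |
| h | 2.5 Th | LNL / GOF window half-width |
| factor_place | 1.5 | placement gate over LNL |
| merge_ppm | 100 | grouping tolerance (see note above) |
| t | 5 | signal-to-noise threshold, always user-reviewed |
| κ | 1.00235 Da | isotopic spacing |
| trim_rel | 0.01 | isotope-peak trimming |
| γ0, M, γ_max | 10, 10, 1e8 | barrier schedule |

The threshold t has no universal default in spirit — a reasonable choice
depends on platform and sample; the CLI prints the score distribution so
users can calibrate it.

## Problem sizes

The pipeline-level tests and the acceptance script run on spectra of
roughly 200–5000 points with up to ~600 placed templates, and solver
oracle comparisons on 40×60 randomized designs; these sizes exercise every
code path (banded factorization included) while keeping the full suite in
the low minutes on one CPU.
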
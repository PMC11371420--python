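# Methods

## Model

Colour matching is additive over lights, so an observer's matching
experiment is a linear map from spectral energy to primary intensities.
Discretized on a wavelength grid of N samples (default 380–780 nm in 5 nm
steps), the matching functions form the columns of a matrix whose column
space — not the individual curves — is the observer-invariant object:
measuring with different primaries right-multiplies the matrix by an
invertible mixing matrix and leaves the span unchanged.

A reduction dichromat's two matching functions span the plane of their
two retained cone fundamentals.  Two dichromats of different classes
share one cone class, so the shared fundamental lies on the intersection
of two planes in wavelength space.  Algebraically, with CMF matrices C₁
and C₂ (N×2 each), the intersection is the null space of the joined
matrix [C₁ −C₂] (N×4): a null vector [x₁; x₂] satisfies C₁x₁ = C₂x₂, and
that common vector is the estimate.  For exact reduction observers
without noise the null space is one-dimensional; its ray *is* the
fundamental, determined up to a scalar.

## Estimators

**SVD (default).**  The approximate null vector is the right singular
vector of the smallest singular value — the direction minimizing
‖C₁x₁ − C₂x₂‖ subject to ‖x₁‖² + ‖x₂‖² = 1.  Under noise the two
one-sided reconstructions C₁x₁ and C₂x₂ differ; the first observer's
reconstruction is reported (both are exposed, as is their normalized
average).  The reporting convention is peak = 1 with the sign chosen so
the curve's sum is positive, since the ray fixes the estimate only up to
scale and sign.

**Explicit optimization.**  The same problem posed to a constrained
optimizer (SLSQP on the sphere ‖z‖ = 1, four deterministic starts, best
minimum kept).  It must agree with the SVD; it exists because the
formulation extends to additional constraints.

**Non-negative variant.**  Adds C₁x₁ ≥ 0 elementwise and replaces the
norm constraint by mean(C₁x₁) = 1, which excludes the degenerate zero
solution while keeping the problem convex.  Because x₁ is 2-dimensional,
the normalization set is a *line* in coefficient space; clipping it
against the N half-planes leaves an interval, and after eliminating x₂
(ordinary least squares given x₁, linear in x₁) the objective is a scalar
quadratic minimized in closed form on that interval.  The solution
therefore honours non-negativity to rounding error rather than to an NLP
solver's constraint tolerance.  A consequence worth knowing: with i.i.d.
noise at every sample the hard constraint set is *empty* (at wavelengths
where both matching functions vanish, noisy rows point in all
directions), and the variant raises an infeasibility error.  It is the
appropriate tool when negativity enters through structured artefacts
(calibration drifts, smooth digitization error), not dense noise.

## Diagnostics and degeneracy

The ratio of the smallest to the largest singular value of the joined
matrix measures how well the two planes actually intersect: < 1e−12 for
noiseless synthetic data, rising with noise.  If the *second*-smallest
singular value also falls below 1e−8 of the largest, the null space is
(numerically) at least two-dimensional — e.g. the same observer supplied
twice — and no unique shared ray exists; this raises a degeneracy error
rather than returning an arbitrary vector.  The threshold separates the
intended one-dimensional null space from pathological inputs and is
deliberately far (four orders) from both the noiseless floor and
realistic noise levels.

## Virtual channels

The same null-space computation applied to the joined matrix J = [C, C̃]
of two camera sensor sets.  The numerical rank (singular values above a
relative tolerance, default 1e−9) gives the number of shared channels as
(k₁ + k₂) − rank(J); each null vector w yields the coefficient pair
v = w[:k₁], ṽ = −w[k₁:] with Cv = C̃ṽ.  For two 3-channel cameras the rank
3/4/5/6 cases are labelled identical_space / plane / single / none; other
channel counts report the raw rank only.  When the intersection has
dimension > 1 any basis is equally valid; the returned basis is
orthonormalized (QR on the A-side reconstructions, the coefficient
vectors transformed consistently) and then peak-normalized per channel.
Near-commonality in real cameras is not thresholded for the user: the
full singular spectrum is reported and the tolerance is exposed.

## Synthetic data

The generator produces the structures the estimators assume, so the whole
pipeline is testable from a seed with no external files.

* **Fundamentals** are split Gaussians in log-wavelength: Gaussian in
  ln λ with independent left/right widths for asymmetry.  Defaults — peaks
  565/535/440 nm, bandwidths 55/50/35 nm, asymmetries 0.15/0.15/0.10 —
  sit in the neighbourhood of human cone sensitivities with the familiar
  long-wavelength skew.  This is a smooth, non-negative, unimodal
  stand-in chosen because the estimators are shape-agnostic; it is *not*
  a photopigment template and carries no lens or macular pigment
  screening, so agreement on synthetic data demonstrates the algebra, not
  colorimetric accuracy on real observers.
* **Dichromat CMFs** are the appropriate fundamental pair right-multiplied
  by a 2×2 mixing matrix (given, or drawn with entries uniform on [−1,1]
  and redrawn until the condition number is ≤ 50, keeping noiseless tests
  numerically clean) plus optional i.i.d. Gaussian noise per sample,
  expressed as a fraction of peak since curves are peak-normalized.  Real
  matching data have smooth, wavelength-correlated errors; i.i.d. noise is
  the simplest stand-in and is the reason the non-negative variant's
  infeasibility behaviour (above) differs between synthetic and real data.
  No noise magnitude is canonical; the test sweep spans 1e−4–1e−2 of peak.
* **Camera pairs** plant a chosen number (0–3) of shared smooth curves
  plus independent smooth fillers (sums of random Gaussian bumps), hide
  them behind random invertible per-camera mixes, and verify the joined
  rank before returning, so the taxonomy tests have exact ground truth.

## Numerical choices

* Interpolation is piecewise linear, never extrapolating; all pairwise
  work happens on the common axis (the finer grid restricted to the
  overlap), which is how a narrower tritan measurement range restricts
  the L and M estimates without touching S.
* Angular error between estimate and truth is computed as
  atan2(‖rejection‖, cosine) rather than arccos of the cosine, which
  saturates near 1 and cannot resolve angles below ~1.5e−8 rad.
* CSV round-tripping uses shortest round-trip float formatting on write
  and round-trip parsing on read, so seeded runs are byte-reproducible.
* Packing noisy estimates into the non-negative `ConeFundamentals`
  container clips negative excursions up to 1% of peak (configurable);
  the signed estimates are always retained on the per-pair results.
* The log10 comparison floor (default 0.05 of the reference peak)
  applies to the reference curve only; non-positive estimate values at
  unmasked samples are flagged as undefined rather than fatal.

## Problem sizes

The verification suite and `scripts/acceptance.py` use the default 81-
sample grid with 100 seeds for exact recovery, 20 for primary invariance,
50 noisy instances for the oracle check, 200 replicates per noise level,
and 50 seeds per planted shared dimension for the rank taxonomy — sizes
at which every quantity is stable to re-seeding while the whole run
completes in seconds.

## Limitations

* The estimators assume *reduction* dichromacy: a dichromat whose two
  pigments differ from the trichromat norm breaks the shared-subspace
  premise, and nothing in the algebra detects it.
* Individual differences in pre-receptoral screening (lens, macular
  pigment) are not modelled; estimates from real group-average data
  inherit whatever averaging artefacts the data carry.
* The virtual-channel taxonomy is stated for two cameras; more systems,
  and principled thresholding of near-shared subspaces under camera
  noise, are out of scope.
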
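# Methods

## The metric

For point sets X (estimates) and S (ground truth) in R^n, the mean
square minimum distance pools the squared nearest-neighbor distances in
both directions and normalizes by the total point count:

    D²(X, S) = ( Σ_{s∈S} min_{x∈X} ‖x − s‖² + Σ_{x∈X} min_{s∈S} ‖s − x‖² ) / (|X| + |S|).

Both directions are required: a single estimate sitting exactly on one
of many emitters would otherwise score perfectly. RMSMD = D(X, S) is
symmetric, non-negative, invariant under shared rigid motions, and
continuous in every coordinate — in particular across Voronoi-cell
boundaries, where the argmin switches but the minimum itself is
continuous. Ties in the argmin are broken by lowest index; the value
never depends on the choice. Repeated points are legal (frame-by-frame
localization produces many estimates per emitter).

Three independent evaluation routes are maintained: the KD-tree /
vectorized fast path, a deliberately naive double loop
(`metrics.naive_msmd`, the shipped oracle), and the Voronoi-cell
decomposition, which assigns each point to the nearest site of the
other set by argmin rather than constructing explicit cell geometry
(explicit diagrams degenerate for collinear or duplicate sites and do
not generalize across dimensions). Tests require agreement to 1e−12
relative on random instances in dimensions 1–4.

**Triangle inequality.** The pooled normalization by |X| + |S| breaks
the usual proof strategy, and random search finds genuine
counterexamples: `metrics.sample_triangle_inequality` reports, e.g., 3
violations in 200 random triples (worst excess ≈ 73 nm at coordinate
scale 1000 nm, seed 0). RMSMD should therefore be treated as a
fitness measure, not a true metric satisfying D(X,S) ≤ D(X,Y) + D(Y,S);
the sampler surfaces violations rather than asserting the inequality.

**Zero-distance characterization.** D = 0 whenever every point of each
set coincides with some point of the other; with repeats this is weaker
than "equal up to permutation" (X = {a, a}, S = {a} also gives 0), and
tests assert only the literally true direction.

Kernel pairs are mutual nearest neighbors; at least one always exists
(the globally closest pair is mutual under consistent lowest-index tie
breaking, which the implementation asserts). Removing "far non-kernel"
points from X provably lowers the metric when (i) no ground-truth point
has a removed point as nearest neighbor, and (ii) the removed terms'
mean exceeds the mean of the remaining terms; `far_point_removal`
checks both conditions and returns both values.

## Detection metrics

The challenge-style metrics classify each estimate by a closed disk of
radius FWHM around any emitter (boundary points are TP; the boundary
has measure zero, the convention only matters for constructed tests).
Each estimate is classified once (|TP| + |FP| = |X|) even if it lies in
several circles, and a single estimate inside two overlapping circles
rescues both emitters from FN — the literal reading of "its TP region
contains no estimate". Accuracy with no TP points is undefined and is
represented by `None` / "NA", not an exception or a number. Ratios with
empty denominators are 0 by convention.

## Photoswitching chain

States 0 (dark) and 1–4 (activated); from dark, stay with probability
r00 or activate; from state j, return to dark with r0j or advance. With
r01..r04 = (0.5, 0.7, 0.8, 1) fixed, r00 sets the duty cycle. The
closed-form stationary solution p0 = 1/(1 + Σ_j Π_k r_{k+1,k}) is
cross-checked against the transition-matrix eigenvector to 1e−12. The
frame count for a target mean of 30 activations per emitter uses
N = floor(30/p_a): the floor convention reproduces the full published
table of N values (922, 625, 476, 387, 327, 285, 253), where rounding
would not (923 at r00 = 0.98). Initial states are drawn from the
stationary distribution, so per-frame statistics are stationary from
frame 0; per-emitter streams are spawned from one seed so enlarging the
experiment never perturbs existing paths.

## Frame model

Pixel-integrated Gaussian PSF: the landing probability in a pixel is
the product of 1D error-function differences, not a center sample —
at 128 nm pixels and σ = 78.26 nm the difference is material. Defaults:
3000 detected photons per activated emitter per frame, 2048×2048 nm
field, 16×16 pixels.

SPNR and SGNR (0.2 and 0.3 µm² per emitter) are interpreted as
signal-to-noise-*density* ratios: Poisson background mean per pixel
= IηΔt·(ΔxΔy)/SPNR ≈ 245.8 photons, Gaussian read-noise variance per
pixel = IηΔt·(ΔxΔy)/SGNR ≈ 163.8. Both live behind single functions
(`FrameModel.poisson_background`, `.gaussian_noise_var`) so an
alternate reading is a one-line change; none of the headline
reproduced quantities depends on these constants. Frames are stored as
real-valued arrays (read noise makes counts non-integer); there is no
ADC/EMCCD model.

The helix phantom places emitters at equal 25 nm arc length along an
Archimedean spiral (inner radius 200 nm, 120 nm between turns, centred
in the frame). Since the curvature radius is ≥ 200 nm, chord and arc
lengths agree to well under 1 %; the constructor verifies the phantom
stays inside the frame.

## Fisher information and the benchmark estimator

For K activated emitters, F = Σ_pixels (∂µ/∂θ)(∂µ/∂θ)ᵀ/(µ + v_g) with
analytic PSF-integral derivatives (finite-difference checked at 1e−6
relative). The (µ + v_g) denominator is the standard
Gaussian-approximation treatment of mixed Poisson + additive Gaussian
noise; the exact mixed-noise information has no closed form. Inversion
goes through the symmetric eigendecomposition (F = VwVᵀ,
F⁻¹ = V w⁻¹ Vᵀ), keeping F⁻¹ positive semidefinite by construction;
configurations with condition number above 1e15 — where double
precision can no longer resolve the smallest information eigenvalue —
raise an explicit error carrying the condition number. In the
single-emitter, no-background, fine-pixel limit the CRLB approaches the
shot-noise limit σ²/N_photons ≈ 2.04 nm².

The benchmark estimator draws θ̂ = θ + UΛ^½g, g ~ N(0, I), i.e.
θ̂ ~ N(θ, F⁻¹): unbiased, covariance exactly F⁻¹, so it attains the
CRLB without any fitting. Estimates may fall outside the frame and are
kept. The 95 % error ellipse uses the 2-dof chi-square (Rayleigh)
radius R = √(−2 ln 0.05) ≈ 2.448; empirical coverage is verified by
sampling.

## Density benchmark and its statistics

`run_benchmark` sweeps r00 = 0.98 → 0.92 (activated-emitter densities
1.94 → 7.06 µm⁻²): derive sizes, simulate activation, compute the
per-frame Fisher matrix of all simultaneously active emitters, draw one
estimate per activation, pool into the image X, and score against the
helix. Runs are bit-for-bit reproducible from (seed, config); the full
default sweep (250 emitters, 30 activations per emitter, ≈ 3300 frames)
takes a few seconds since the estimator bypasses frame fitting.

The pooled MSMD at high density is dominated by rare frames in which a
run of adjacent 25 nm-spaced emitters is active simultaneously: their
Fisher matrix is nearly singular (resolving several sources within a
fraction of σ), the largest CRLB eigenvalues reach 1e6+ nm², and single
estimates land tens of µm away, each contributing ~‖error‖²/(|X|+|S|)
to the MSMD. The *expected* RMSMD therefore rises steeply — roughly
exponentially — with density, but any single replicate's 7-point sweep
is at the mercy of its worst frame and is not reliably strictly
monotone (measured: ≈ half of seeds at full scale, fewer at reduced
scale). Tests therefore assert the robust form of the trend — the
replicate-median RMSMD curve rises monotonically (Spearman ρ ≥ 0.9)
and spans more than a 5× range — alongside a literal single-replicate
monotonicity check at a fixed seed, which documents this variance
honestly when it trips. Precision, recall, and Jaccard move by under
10–20 % relative across the entire sweep, which is precisely the
insensitivity that motivates RMSMD.

The reduced benchmark used in tests (50 emitters, 10 activations per
emitter, 9 replicates) keeps the suite fast while preserving the
median trend.

## What the simulations do and do not show

The generator emulates: stationary Markov blinking with independent
emitters, Gaussian-PSF photon statistics, uniform background, white
read noise, and an estimator that is *exactly* unbiased and
information-achieving. It does not emulate: fitting artifacts of real
localization software, photobleaching or non-stationary duty cycles,
sample drift (the metric assumes rigid registration has been applied),
non-uniform background, camera gain/offset, or 3D/astigmatic PSFs (the
metric itself is dimension-agnostic; the simulator is 2D). Passing
tests therefore validate the metric's mathematics and the benchmark's
information-theoretic baseline, not the behavior of any practical
fitting algorithm on real data.
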
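# Methods

## Two-emitter localization from photobleaching

A diffraction-limited spot containing two fluorophores is modelled per frame
as the sum of two pixel-integrated symmetric 2D Gaussians (shared FWHM) over
Poisson photon noise, camera gain, and Gaussian read noise. Single-step
photobleaching creates a piecewise-constant intensity trace; the frames
between the two bleach steps expose the surviving emitter alone, which is
what makes sub-diffraction pair separations identifiable.

Traces are extracted as background-subtracted integrated intensity within a
disc around the detected spot (background = per-frame median outside the
disc). Change points come from binary segmentation on squared-error cost
with penalty 2·ln(n)·σ̂², σ̂ the robust (MAD) noise level of the first
differences. Two post-processing rules stabilize the segmentation: adjacent
levels closer than 3σ̂ are merged (sub-noise splits), and adjacent *bright*
levels differing by less than 20% of the larger are merged — a bleach step
removes a whole emitter's intensity (~50% for equal emitters), so small
fractional changes between bright segments are noise clusters, not
photophysics. A trace is rejected (monomer, incomplete bleaching, or no
signal) unless it shows at least two downward steps and ends at a level
consistent with background; when more than two downward steps occur, the
lowest two non-zero levels are analysed. Misplaced segment boundaries only
redistribute intensity between the two fitted amplitudes; they do not bias
the fitted positions, because the contaminated mean image is still exactly
a two-Gaussian image.

The global fit minimizes joint least squares over the mean image of the
two-emitter segment and the mean image of the one-emitter segment with
seven parameters {x₁, y₁, I₁, x₂, y₂, I₂, FWHM}; the survivor's intensity
and the FWHM are shared between segments (a config toggle can refit I₂ on
the one-emitter segment alone). The survivor is emitter 2 by construction —
identity comes from the one-emitter segment, not intensity ordering.
Levenberg–Marquardt with an analytic Jacobian is started from a photometric
moment guess; fitted separations below 0.02 px are flagged degenerate and
excluded downstream. The degeneracy guard is deliberately far below the
measurement resolution so that genuine short separations (the 0–6.5 nm bias
region) remain measurable; numerically collapsed fits are additionally
caught by the resolution filter through their exploding bootstrap error.

Localization errors are parametric bootstrap: the fitted model images are
re-noised under the camera model (Gaussian approximation to the mean-image
noise, variance = shot·gain·μ/n_frames + read²/n_frames) and refitted
(default 100 refits). Per-emitter σ₁, σ₂ are the per-axis standard
deviations of the refitted positions. The pair error σ_pair — the Rice
scale of the measurement — is taken directly from the per-axis spread of
the refitted *separation vector*, not as √(σ₁²+σ₂²): the two positions are
fitted jointly, so their errors are correlated (positively at
tetramer-scale separations, negatively near degeneracy), and the
independent combination mis-states the pair error by tens of percent. The
two definitions coincide for uncorrelated estimates. A Thompson-style
analytic precision formula serves as a cross-check oracle in tests (the
shot-noise 1/√N scaling of localization precision is asserted against the
generator).

## Separation posteriors and the resolution filter

The measured distance d between two positions with combined per-axis error
σ follows Rice(r, σ) around the true separation r. Under a uniform prior on
r ∈ [0, 60] nm (the method's reporting range) the posterior is the
normalized Rice likelihood, evaluated on a 1,200-point grid (trapezoid
integration; < 0.05 nm discretization at typical σ) with exponentially
scaled Bessel functions so large d·r/σ² never overflows. The per-measurement
precision is the 69% highest-posterior-density interval: the density level
set holding 69% of mass, with endpoints linearly interpolated to the exact
threshold crossings (grid-snapped endpoints systematically truncate the
interval by up to half a cell per side). HPD is the default because the
posterior is asymmetric; a central (equal-tail) interval is available as a
toggle. Measurements pass the resolution filter iff interval width <
threshold (strict), with thresholds of 4.8 nm for decompositions and 6–7 nm
for population-fraction analyses.

## Rician mixture decomposition

Retained point estimates {dᵢ, σᵢ} are modelled as a K-component mixture
whose k-th component is Rice(dᵢ | r_k, σᵢ) — each measurement's own σᵢ is
the component scale, i.e. peak widths are measurement-limited with no extra
per-component width. EM with 20 quantile-plus-jitter multi-starts maximizes
the likelihood; the weighted Rice ML position update uses the standard
I₁/I₀ fixed point (two inner iterations per M-step, ascent verified by a
monotonicity test). K = 1..8 are fitted and compared by
BIC = (2K−1)·ln n − 2·log L (K positions, K−1 free weights), ties toward
smaller K. Component position intervals come from a nonparametric bootstrap
(250 resamples, refit at fixed K, central-69% percentiles, asymmetric).
Components whose interval reaches into the 0–6.5 nm bias region are
reported interval-only: there the fitted position is biased upward because
the separation is comparable to the resolution. The summed-posterior curve
is rendered for display; the likelihood always uses the point estimates.

## Species population fractions

The fraction "consistent with species X" is the ratio of unit measurement
areas whose 69% interval intersects the species window (dimer
12.5 ± 0.3 nm, tetramer 19.6 ± 0.5 nm) to those intersecting the
dimer–tetramer region (0–20.1 nm); intersection is closed-interval, so one
measurement can count toward both species. Errors are the sd over 1,000
bootstrap resamples. This estimator is a *relative-population indicator*,
not an unbiased mixture-weight estimator: a ±0.3 nm target window misses a
fixed share of genuine same-species measurements whose interval falls just
outside it, so its expectation under a 70/30 dimer/tetramer truth is ~0.57,
not 0.70. The closed-loop test therefore checks the full imaging chain
against the estimator's own expectation computed by an ideal-measurement
oracle (direct Rice sampling at the generator truth), which isolates any
bias added by detection, segmentation or fitting.

## Oligomer chain model

Ligand-bound back-to-back dimers stack through a face-to-face interface;
only the two end monomers can bind ligand, so separation grows linearly:
tetramer anchor 18.5 nm + 7.5 nm per extra dimer, with a fixed 1.1 nm
dye/linker addition for fluorophore-to-fluorophore distances. Exact
linearity is assumed at all orders. The lone dimer's dye–dye distance
(12.5 ± 0.3 nm) is an independent accessible-volume-derived constant, not a
chain prediction. All constants live in a versioned plain-text config with
the published calibration as default.

## Plane-FRET distance of closest approach

Acceptors are a 2D Poisson process at areal density ρ (acceptors per R₀²)
in a disc of radius 10 R₀ around the donor's projection; the transfer rate
is S = Σᵢ (R₀/rᵢ)⁶ with rᵢ = √(h² + dᵢ²), plus the analytic far-field mean
πρ/(2(h² + r_cut²)²) (truncation error < 0.1%). Per-realization efficiency
is E = S/(1+S) in donor-lifetime units; the model curve is the mean over
2,000 realizations. Fitting shares acceptor configurations across the
60-point geometric height grid (h/R₀ ∈ [0.2, 5]), making the SSE smooth in
h; the grid argmin is refined by parabolic interpolation in log h. Errors
are the sd of the fitted height over 1,000 record-resampled bootstrap data
sets. All lengths are in units of R₀; nm conversion only when R₀ is given
explicitly, and the intensity-to-density calibration factor is always a
required input. Datasets whose efficiencies are all ≈ 0 are flagged
non-identifiable (h unbounded above). Measured efficiencies come from
lifetimes, E = 1 − τ_DA/τ_D; decay histograms are fitted with 1- or
2-exponential models plus offset, the mean lifetime amplitude-weighted, and
a degenerate two-component fit collapses to one with a notice.

## MSD and mobility

MSD(ΔT) averages squared displacements over all overlapping pairs separated
by ΔT within each track, pooled across tracks (pair-count weighted). The
instantaneous diffusion coefficient is D = m/4 with m the gradient of the
unconstrained line through the first two MSD points (an origin-constrained
toggle exists; the convention is a config choice, not estimated from data).
The triple bootstrap resamples, with replacement, data sets, tracks within
each data set, and displacement pairs within each track at every lag —
"time points within a track" is realized at the pair level because
resampling raw time points would destroy the lag structure. Per-lag sds
across 200 replicates are the MSD error bars; the sd of refitted D is σ(D).
Confinement shows as a concave-down MSD; the package quantifies this as the
relative shortfall of MSD at the largest lag below the two-point line
(≈ 0 for Brownian, → −1 at a plateau).

## Synthetic data: what it emulates, and what it does not

The generator produces (i) species mixtures at fixed separations with
uniform random orientation — default scenario: dimer/tetramer/hexamer/
octamer/decamer at the dye-corrected separations 12.5/19.6/27.1/34.6/42.1 nm
with weights 0.35/0.30/0.15/0.12/0.08; (ii) 15×15 px spot stacks at
100 nm/px, PSF FWHM 270 nm, frame interval 0.28 s, with exponential
single-step bleaching (mean 25 frames, per-emitter), Poisson shot noise,
gain, Gaussian read noise (1 e⁻) and a 10 photon/px background; an optional
Gamma approximation doubles the shot variance to emulate EM-register excess
noise (off by default so that error calibration is exact); (iii) Brownian
and reflected-boundary confined 2D tracks (per-axis step variance 2DΔt;
confined plateau box²/3); (iv) FRET records at the plane-model mean
efficiency with optional multiplicative log-normal lifetime noise. The
photon budget (5,000 photons/frame/emitter) is set so the combined pair
localization error is ~1–2 nm, matching the regime in which a 4.8 nm
resolution filter retains most two-step complexes.

Not emulated: stage drift and vibration, multi-frame tracking of mobile
complexes during bleaching, fluorophore blinking and re-activation,
fixation artefacts, heterogeneous photon rates between the two fluorophores
of one complex, TCSPC instrument response, and full-field scenes with
overlapping complexes. Passing closed-loop tests therefore demonstrates the
correctness of the inference chain under the stated noise model, not
robustness to these real-data effects.

## Problem sizes and numerical choices in the tests

The test suite exercises: 1,000 rendered complexes for the Rice-consistency
(KS) check with 60-refit bootstrap errors; 10,000 posteriors for 69% HPD
coverage; a 3×3 (d, σ) grid with 3×10⁷ Monte Carlo draws per point for the
brute-force conditioning oracle (total variation < 0.02); 50 seeded runs of
BIC selection at n = 150; a 200-complex closed-loop fraction recovery; and
20,000-realization plane-FRET closed-form checks. These sizes keep every
statistical tolerance a small multiple of its Monte Carlo error. All
randomness is explicitly seeded; reruns are bit-identical.

## Known limitations

- The two-emitter fit near the degeneracy (separations ≲ resolution) shows
  excess spread beyond the parametric bootstrap's estimate, since bootstrap
  around the fitted model captures variance but not estimator bias; this is
  the same physics behind the bias-region reporting rule.
- The BIC occasionally accepts a duplicated component (two peaks at the
  same position) at small n; positions remain correct, K may read high by
  one.
- The EM position update is a partial M-step (two fixed-point iterations);
  likelihood ascent holds to numerical precision but convergence is
  declared on parameter stationarity as well as likelihood change.
- The plane-FRET fit resolves heights only within the precomputed grid
  bounds (0.2–5 R₀); heights outside are clamped and flagged only through
  the non-identifiability check at the top end.
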
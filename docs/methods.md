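# Methods

This note documents the models, parameter choices and numerical decisions
behind `phasorplex`, and what the simulation-based tests do and do not
demonstrate about real microscope data.

## Phasor transforms

A voxel's photon arrival-time histogram `c_k` over one stimulation period
T = 1/f_rep is mapped to the first-harmonic Fourier coordinates

    g = Σ_k c_k cos(2π h t_k / T) / Σ_k c_k
    s = Σ_k c_k sin(2π h t_k / T) / Σ_k c_k

with bin-center times `t_k = (k + ½)·T/B`. For a *periodic* single-exponential
decay this converges exactly to `G = 1/(1+(ωτ)²)`, `S = ωτ/(1+(ωτ)²)` with
ω = 2π·h·f_rep — there is no incomplete-decay correction because the wrapped
tail of each pulse is included. At the default B = 256 bins the discretisation
bias is below 10⁻³ phasor units across τ ∈ [0.3, 10] ns at 78 MHz (measured in
the test suite); tests that only need chord geometry use 64–128 bins.

The spectral histogram over C detector channels maps analogously with channel
angles θ_c = 2π·h·(c + ½)/C spanning the full detector range. This
equal-angle convention is a local choice — different instruments normalise
their spectral phasor differently — and is documented here precisely so that
signatures computed by this package are reproducible. The harmonic h defaults
to 1 and is exposed as a parameter.

Voxels with fewer than `min_photons = 10` total photons are marked invalid and
excluded from all downstream clustering: below roughly 10 photons the phasor
estimate is noise-dominated (its standard error scales as ~1/√n photons).
Invalid voxels carry NaN phasors but never propagate NaN into the classifier.

No instrument response function is modelled: simulated decays are ideal
periodic exponentials. Convolution with a realistic IRF shifts phasor
positions along predictable trajectories but requires instrument-specific
calibration data this package does not assume.

## Codebooks

Targets are encoded as unordered pairs of dyes; capacity is (N²−N)/2. The
expected signature of a pair is the equal-photon (½:½) midpoint of the two
dyes' phasor positions, in both the lifetime and the spectral plane; real
labeling stoichiometry moves puncta along the chord, which the classifier
absorbs into its fitted covariances rather than the codebook constant.
Singleton (one-dye) codewords are supported for small panels that mix single-
and double-labelled targets, but they interact with error rejection: a
single-channel punctum is normally rejected as *undetermined*, and a singleton
codeword necessarily disables that rejection on its channel. Both behaviours
are available; panels using only pair codewords keep the full rejection rule.

## Synthetic data generator

The generator emulates the study conditions the pipeline is designed for:

* geometry: 33 slices of 1000 × 1000 px at 100 × 100 × 300 nm voxels
  (default volume 100 × 100 × 10 µm; tests and examples shrink the field of
  view, never the per-punctum statistics);
* puncta: 3D Gaussian intensity profiles with σ_xy = 200 nm, σ_z = 500 nm,
  peak intensity ~ Normal(1, 0.3) truncated below at 0.1 by resampling
  (the distribution's support is otherwise unbounded and non-positive
  intensities are unphysical);
* photon budget: `photons_per_unit_intensity = 50` expected photons at the
  peak voxel, i.e. ≈5×10³ photons per punctum integrated over the profile — a
  realistic confocal smFISH budget; the value is a package default, not a
  measured constant, and is exposed in `SimulationConfig`;
* background: 0.5 photons per voxel, uniform over channels and time bins; an
  optional broad-spectrum autofluorescence species with τ = 2 ns can be mixed
  in to exercise the classifier's extra noise component (the real tissue
  autofluorescence this stands in for is spectrally structured; no published
  parameters exist for it, so the values here are fixture choices);
* rendering: profiles are integrated over voxels (difference of Gaussian
  CDFs per axis), truncated at 4σ; photons split ½:½ between the codeword's
  dyes, then draw a spectral channel from the dye's Gaussian emission profile
  integrated over the channel edges and an arrival-time bin from its periodic
  exponential decay; all counts are Poisson.

Sampling is exact without materialising the 5D rate tensor: each punctum's
total photon count is Poisson with the analytic mean, and photons place
themselves independently by categorical draws per axis/dye/channel/bin — the
standard thinning identity for independent Poisson cells.

What the simulations do *not* reproduce: diffraction side lobes and PSF
asymmetry, detector afterpulsing and dead time, IRF convolution, spectral
bleed-through beyond Gaussian emission tails, photobleaching, and structured
(non-uniform) autofluorescence. Passing recovery tests on these simulations
therefore demonstrates the correctness of the algorithms under the stated
noise model, not instrument-level performance.

## Detection

1. **Background**: voxelwise median over a window 10× the expected punctum
   size (default 0.25 µm, the diffraction limit), odd-rounded per axis in
   voxel units, reflect padding. On stacks above ~4×10⁵ voxels the median is
   evaluated on a decimated grid and linearly interpolated back — the
   background is low-frequency by construction, so this is lossless in
   practice and an order of magnitude faster. A window larger than the stack
   falls back to the global median with a warning.
2. **Matched filter**: Gaussian smoothing of (intensity − background) with σ
   equal to the punctum size per axis in voxel units; negative values are
   clipped for the output map, but the *unclipped* field is used for noise
   estimation (clipping first would halve the distribution and bias the MAD
   low).
3. **Maxima**: strict maxima of the 26-neighborhood — the discrete fixed
   points of "gradient zero, divergence negative" on a voxel grid — with
   plateaus reduced to their centroid voxel.
4. **Threshold**: `min_prominence` defaults to the filtered field's median
   plus 8× its robust (MAD) noise scale. Two non-obvious choices here: the
   median offset, because a median-filter background under-reports the mean
   of skewed low-rate Poisson noise, leaving the filtered field a positive
   baseline; and the factor 8, because matched-filtered Poisson noise has a
   heavier-than-Gaussian upper tail (observed maxima reach ~6–7 robust sigmas
   on 10⁵-voxel photon-sparse stacks, where a Gaussian field would stay below
   5). Real puncta sit tens of sigmas above the threshold even at the dimmest
   simulated intensities, so the factor trades no recall for specificity.
5. **Measurement**: brightness is the background-subtracted photon sum over a
   2σ ellipsoid; size is the count of ellipsoid voxels above half the peak
   prominence; channel presence requires both SNR ≥ 3 against the local
   Poisson background *and* ≥ 10% of the punctum's photons in that channel.
   The fraction criterion is needed because bright puncta make the ~1%
   spillover of realistic Gaussian emission tails into adjacent channels
   statistically significant; presence is meant to capture "the dye emits
   here", not "photons are detectable here". Edge puncta are measured over
   the clipped ellipsoid and flagged, not dropped.

## Classification and decoding

Puncta-mean phasors (intensity-weighted over the member voxels) are clustered
with a full-covariance Gaussian mixture with K = (number of codewords) + 1
components, the extra component absorbing autofluorescence and noise.
Numerical choices: covariance floor 10⁻⁶ against EM degeneracy on tight
clusters; deterministic seeding; component means initialised at the expected
codeword signatures (plus the data mean for the extra component) when a
codebook is available, which removes EM label-switching, otherwise k-means++
with 5 restarts. Components are matched to codewords by Hungarian assignment
on mean–signature distance; unmatched components map to the noise label.
A per-pixel assignment path is kept for pseudocolour images.

Decoding applies rules in order: (1) more than two channels present →
*overlapping*; (2) fewer than two channels and no singleton codeword on that
channel → *undetermined*; (3) otherwise the codeword of the maximum-posterior
component whose channel set equals the punctum's channel presence, provided
the posterior ≥ 0.5; sub-threshold posteriors and noise-component assignments
are *undetermined*. Low-confidence puncta keep their posterior in the output
table rather than being silently dropped, and counts are conserved at every
stage: assigned + undetermined + overlapping = total detected. The rule order
is configurable because different panels (singleton-bearing vs pair-only)
legitimately want different rejection behaviour.

For single-channel panels the spectral phasor is degenerate and clustering
runs on the 2D lifetime phasor alone (`use_spectral=False`).

The multicomponent fraction of a two-species punctum is its phasor's scalar
projection onto the chord between the pure-component positions, clamped to
[0, 1] — off-chord displacement (noise, background pull) projects
orthogonally and does not bias the fraction to first order.

## Cells

Nuclei: Otsu's criterion as the concrete two-class histogram split, 3D
connected components, debris below 30 µm³ removed (configurable; a G1 human
nucleus is ~200–500 µm³). Territories: the fixed point of simultaneous
uniform surface growth from all nuclei equals the nearest-surface partition,
so it is computed directly as an argmin over per-nucleus anisotropic
Euclidean distance transforms, with ties to the lower cell id — identical to
the iterative 3×3×3 dilation construction away from metric-vs-chamfer
boundary voxels, and exactly matching a brute-force nearest-surface oracle in
the tests. Distances honour anisotropic voxels in physical units.

Counts: per-territory tallies for assigned puncta with undetermined and
overlapping tracked separately; for imaged slabs thinner than a cell, counts
are normalised as counts / imaged cellular volume × 3000 µm³ (an estimated
mean cell volume). Both outputs are provided without asserting that they are
biologically equivalent.

## Optical crowding

The isolated fraction of N uniform puncta of PSF volume v_i in volume V_T is
`n/N = (1 − v_i/V_T)^(N−1)`. Inversion for N given n uses bracketed root
finding on [n, N*], where N* = 1/ln(1/(1−v_i/V_T)) maximises N(1−p)^(N−1);
the smaller root is the physical one (the larger sits near 1/p, a regime
where almost everything overlaps), relative tolerance 10⁻⁸. A detected count
above the curve's maximum raises an error — the density is beyond the model's
validity. The headline loss is reported relative to detected counts,
100·(N−n)/n, with 100·(N−n)/N also available.

The Monte-Carlo check places N points uniformly with periodic (toroidal)
boundaries and counts a point as isolated when no other point lies within the
radius of the sphere of volume v_i — the exclusion volume the formula
removes per competing punctum. With the periodic wrap the formula is exact
(no edge corrections), so observed and predicted fractions agree to Monte-
Carlo error; the test grid uses 10 densities × 10 iterations up to ~5%
crowding loss, a scaled-down version of the full 20,000-iteration study that
the formula's N-independence of per-pair geometry makes statistically
equivalent per point.

## Problem sizes in tests

The default test and example stacks are 15–20 µm fields of view with 32–128
time bins and tens of puncta; mixture-recovery tests use 3×10⁴ samples;
the crowding Monte-Carlo uses up to 3.5×10⁴ points. These sizes give every
statistical assertion comfortable margins (3σ or better) while keeping the
whole suite around three minutes on one core; all are plain parameters, so
full-scale runs only change the configuration.

## Known limitations

* No IRF modelling or deconvolution; phasor positions from real instruments
  need calibration against a reference dye.
* No sub-punctum unmixing: a maximum containing several transcripts is
  *overlapping*, counted but not resolved (higher-harmonic unmixing would be
  the natural extension).
* Spectral spillover is modelled only as Gaussian emission tails; real dye
  spectra are asymmetric with long red tails.
* The crowding model assumes spatially uniform transcript density; clustered
  expression (e.g. transcription bursts) violates it locally and the loss
  estimate becomes a lower bound.
* `segment_nuclei` expects a bimodal intensity histogram; dense tissue with
  touching nuclei needs a dedicated instance-segmentation front end, after
  which the territory and counting stages apply unchanged.
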
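# phasorplex

Analysis and simulation toolkit for **combinatorial spectral / fluorescence-lifetime
encoded spatial transcriptomics**. Individual mRNA transcripts are labeled with
an unordered *pair* of fluorophores drawn from a panel of N dyes, imaged on a
spectral FLIM microscope, and decoded from the joint spectral + lifetime phasor
signature of each diffraction-limited punctum. Pairing gives

```
capacity(N) = C(N, 2) = (N² − N) / 2
```

distinguishable codewords — 10 targets from 5 dyes, 66 from 12 — in a single
round of staining and imaging.

The package is aimed at microscopists and computational biologists who want to
prototype, validate or run such pipelines: every stage is an importable library
function, a thin `phasorplex` CLI wraps the pipeline stages, and a built-in
simulator produces ground-truth-annotated synthetic stacks for end-to-end
validation.

## The method in brief

* **Phasor transforms.** Each voxel's photon arrival-time histogram maps to the
  lifetime phasor `g = Σc_k cos(ωt_k)/Σc_k`, `s = Σc_k sin(ωt_k)/Σc_k`
  (ω = 2π·f_rep, first harmonic); its spectral histogram maps analogously onto
  the spectral phasor circle. Single-exponential decays lie on the universal
  semicircle at `(1/(1+(ωτ)²), ωτ/(1+(ωτ)²))`; mixtures fall on chords at the
  photon-fraction position. The transform is fit-free and photon-count
  invariant.
* **Detection.** Median-filter background estimation (window 10× the punctum
  size), Gaussian matched filtering, strict 26-neighborhood local maxima, and
  per-punctum measurement (size, brightness, prominence, per-channel presence).
* **Decoding.** Puncta-mean phasors are clustered with a full-covariance
  Gaussian mixture (one extra component for autofluorescence/noise), components
  are matched to codeword signatures, and rejection rules run in order:
  \>2 spectral channels → *overlapping* (optical crowding); a single channel
  with no singleton codeword → *undetermined*; otherwise the
  maximum-posterior consistent codeword, if the posterior clears the threshold.
* **Cells.** Nuclei are segmented by histogram splitting (Otsu); the volume is
  tiled into cell territories by simultaneous nucleus-surface growth (a surface
  Voronoi tessellation); counts are tallied per territory or normalised to a
  3000 µm³ mean cell volume for thin imaged slabs.
* **Crowding.** With N puncta of PSF volume v_i in total volume V_T, the
  expected isolated fraction is `n/N = (1 − v_i/V_T)^(N−1)`; numerically
  inverting it for the detected count n estimates the true N and the percent of
  puncta lost to overlap.

## Worked example

`examples/03_simulate_and_decode.py` renders a 10-plex synthetic stack
(Gaussian puncta with σ_xy = 200 nm, σ_z = 500 nm, peak intensity 1 ± 0.3,
Poisson photons, 5 spectral channels × 64 time bins at 78 MHz) and decodes it:

```
simulated 50 transcripts, 435,490 photons
detected 46 puncta: 43 assigned, 0 undetermined, 3 overlapping
ground truth recovered: 46/50 matched within 0.5 µm, 43 decoded to the correct gene (93%)
```

The three "overlapping" events are pairs of simulated transcripts that landed
within one PSF volume of each other — exactly the loss mode the crowding model
quantifies. `examples/05_crowding.py` runs that model on the detected counts of
a real-scale experiment (n = 13,500 puncta in 68,000 µm³ of cellular volume):

```
PSF volume 0.1 µm³: true count ≈ 13,776, loss 2.0% of detected
PSF volume 0.3 µm³: true count ≈ 14,384, loss 6.6% of detected
estimated crowding-loss interval: [2.0, 6.6]%
```

i.e. between 2.0% and 6.6% of detected puncta are expected to be lost to
optical crowding depending on the instrument's PSF volume. The other examples
cover the phasor transforms (`01`), codebook construction (`02`) and per-cell
counting (`04`).

The same stages are available from the shell:

```bash
phasorplex simulate --n-targets 10 --counts-per-target 5 --out stack.tif
phasorplex decode stack.tif --codebook codebook.yaml --out puncta.csv
phasorplex crowding --n 13500 --vt 68000
```

## Layout

```
src/phasorplex/
  phasor.py     lifetime/spectral phasor transforms, universal circle
  codebook.py   fluorophore panels, pair codewords, expected signatures
  simulate.py   synthetic spectral/FLIM stacks + nuclei with ground truth
  detect.py     3D blob detection and puncta measurement
  classify.py   GMM clustering, posterior assignment, decoding rules
  cells.py      nuclei segmentation, territory growth, per-cell counts
  crowding.py   optical-crowding model, inversion, Monte-Carlo check
  io.py         TIFF/YAML stack I/O, run configuration, pipeline
  cli.py        thin command-line interface
docs/methods.md detailed model and parameter documentation
```
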
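# Methods

This note records the models, numerical choices and limitations behind
`ptychospa`, in the order data flows through the pipeline.

## Synthetic specimens (`phantom`)

The reference specimen is a hollow spherical shell (outer radius and radial
thickness in nm) decorated with Gaussian protrusions placed on a
Fibonacci-sphere lattice with seeded angular jitter — a stand-in for a
double-layered virus capsid whose trimer texture puts structure at mid/high
spatial frequencies. Shell edges are smoothed over ~1.5 voxels and, when
bumps are present, the shell is scaled to 0.6 with 0.4-amplitude bumps so
the sum stays below 1 without clipping; both choices keep the phantom
band-limited enough that interpolation-based projection conserves the
integral to better than 1e-6 relative. `make_blob_phantom` (sums of 3D
Gaussians) exists because its projections and Fourier transforms have
closed forms, which the test suite uses as independent oracles.

**Projection.** `project_volume` resamples the volume on the pose-rotated
grid with quintic spline interpolation and sums along the beam (lab-z) axis.
A forward-splat projector was rejected: splatting a rotated lattice produces
Moiré-like weight interference that is worst for pure in-plane rotations
(every z-layer shares the same lateral offsets, so nothing averages out).
Pull-based spline resampling has no such artefact; quintic order brings the
mass-conservation error of the sharp-edged shell phantom below 1e-6 (cubic
leaves ~1e-5). Sharp-edged volumes can acquire small interpolation
under/overshoot (≲1% of peak), so projections of non-negative volumes are
non-negative only up to that ringing. The rotation centre is voxel
`n // 2` on every axis — the single centre convention shared by the phantom
builders, the projector and the 3D reconstructor.

**Weak-phase mapping.** Transmission t = exp(−a·p)·exp(i·φ·p) with projected
density p; the phase scale φ is a free parameter of the synthetic model (the
physical constant linking projected potential to phase is
instrument-dependent), chosen per scenario to give peak phases of 0.6–2 rad.

**CSA bandpass emulation.** The transfer of one convergence semi-angle is
modelled as a radial filter on the 3D transform: hard-edged by default so
that maps filtered over a disjoint covering partition sum back to the input
exactly (the oracle the tests rely on), with an optional raised-cosine
roll-off for realism. When `q_hi` equals the grid Nyquist frequency the band
is open at the top so the cube-corner frequencies (|q| > Nyquist along
diagonals) are kept; covering partitions are then exact. White Gaussian
noise of configurable RMS is added in real space after filtering.

## Probe and protocol (`probe_scan`)

The probe is a top-hat condenser aperture of semi-angle α with a quadratic
defocus phase χ(q) = π λ Δf q², inverse-transformed and power-normalised;
aberrations beyond defocus are excluded (defocus is the controlling
parameter, and residual aberrations are absorbed by the ePIE probe update).
The overlap ratio of adjacent illuminated areas uses the area of
intersection of two discs of diameter D = 2|Δf|α + 1.22 λ/α (geometric cone
plus one diffraction-limited radius); a linear 1 − s/D variant is available.
`protocol_report` flags configurations whose overlap leaves the 60–95%
operating window. Dose uses the interior-of-field approximation: each
step² cell receives one pattern's electrons, so dose = N_e/(10·step)² e/Å².
Experimental defocus/step pairings are not prescribed; defaults were chosen
once to satisfy the overlap window.

## Forward 4D model (`forward4d`)

Thin-specimen multiplicative interaction: I_j = |FT(P(r−r_j)·O(r))|², with
the orthonormal FT so a vacuum pattern integrates to 1 before dose scaling.
Sub-pixel positions shift the probe by a Fourier phase ramp — exact because
the probe is aperture-limited below Nyquist. Counting noise is Poisson at
the requested electrons per pattern; `electrons_per_pattern = 0` is the
noiseless sentinel. Beam-induced motion is an incoherent average over
`n_motion_draws` (default 8) rigid in-plane displacements drawn with RMS
magnitude equal to the motion factor (per-axis σ = factor/√2) — a
draw-average rather than a Gaussian envelope multiplication, exact for any
object. Thick-specimen multiple scattering, detector MTF/gain and
beam-current fluctuations are out of scope.

## ePIE (`epie`)

Standard extended-PIE updates (modulus replacement, object and probe steps
with β ∈ (0,1]) in a seeded random position order per iteration. The object
starts as unit transmission on a canvas covering the scan plus a probe
margin; the probe starts from `make_probe` at the nominal defocus and is
frozen for the first two iterations (configurable) to avoid early
cross-talk. The per-iteration error is the mean normalised Fourier-magnitude
error; growth to 10× its running minimum aborts with diagnostics.
Dose-scaled datasets are divided by electrons-per-pattern before matching so
data and model share the vacuum normalisation.

**Scan-position work relies on the shadow-image regime.** For a strongly
defocused probe (many Fresnel fringes across the aperture, e.g. Δf ≈ 20 μm
at α = 1 mrad) the bright-field disc displays the specimen at
r = p + λ·Δf·q, so a probe displacement δ translates the in-disc features by
−δ/(λ·Δf·dq) detector pixels — several pixels per nm, a strong lever for
sub-pixel measurement. Both position operations exploit it:

* `estimate_positions_xcorr` measures pairwise shifts between raster
  neighbours by plain cross-correlation (parabolic sub-pixel peak) of
  mean-subtracted patterns masked to the eroded disc interior — the static
  disc edge would otherwise pin the correlation at zero, and
  phase-correlation whitening suppresses exactly the smooth shadow features
  that carry the signal. A single detector-px-per-nm scale is fitted against
  the nominal grid with one round of 3×-median outlier rejection, and
  positions are integrated by least squares with the centroid anchored to
  the nominal centroid (pairwise data are blind to a global shift).
  Featureless or inconsistent data fall back to the nominal grid with a
  warning. The method needs features in most windows; the scene builder can
  add an ice-like textured background precisely because real specimens are
  never embedded in featureless vacuum.
* In-iteration refinement cross-correlates each measured √pattern with the
  current model modulus over the same masked disc, converts the shift to nm
  with the closed-form shadow scale (using the prior defocus), damps it by a
  gain (default 0.5) and caps it (default 0.3 px per iteration). With
  0.5-pixel injected errors this removes ~85–90% of the RMS within 50
  iterations on noiseless data.

An earlier candidate — cross-correlating the object window before and after
its update and amplifying the tiny displacement — measured essentially zero
signal at these problem sizes and was discarded.

**Redundancy.** `data_redundancy` = measured intensity values / unknowns,
with unknowns = 2·object pixels + 2·probe pixels (pass 0 probe pixels for a
known-probe convention). This ratio definition is this package's own; its
absolute scale need not match other conventions.

## Particle handling (`particles`)

Picking is scale-normalised negative Laplacian-of-Gaussian at
σ = diameter/(2√2) (the scale whose LoG response peaks for a blob of that
diameter) with greedy non-maximum suppression; it is parameter-light and
translation-equivariant. Phase and amplitude picks are merged by greedy
nearest-pair matching within a tolerance, midpoint coordinates, unmatched
picks flagged and kept or dropped per call. Extraction drops boxes that
would leave the image and reports the count. Coordinates are 0-based (y, x)
pixels, origin at the image corner, documented in every CSV.

## Known-pose 3D reconstruction (`spa3d`)

Direct Fourier inversion: each image transform is inserted as a central
slice at its pose (and at each symmetry-rotated pose) with trilinear
weights; the accumulator is normalised by accumulated weights with a
Wiener-style floor of 1e-3 of the maximum weight, and inverse-transformed.
Images are de-centred (`ifftshift`) before the 2D transform and the volume
re-centred after inversion — slice spectra are smooth only when the particle
sits at the array origin, and interpolating an oscillatory spectrum destroys
the insertion. In-plane shifts are removed by a conjugate phase ramp before
insertion. No CTF/MTF division is applied: the ptychographic phase has no
contrast reversals to correct at this scale. Orientation search, 2D/3D
classification and B-factor sharpening are out of scope — poses are known by
construction for synthetic data, which is exactly what this stand-in is for.
FSC uses contiguous shells of one reciprocal voxel by default; resolution is
the linearly interpolated first crossing below 0.143, with an explicit
"not reached" sentinel.

## Multi-band synthesis (`bandsynth`)

Eqs. in README: radially averaged amplitude spectra (mean shell modulus,
default bin width one reciprocal voxel), per-bin argmax assignment with ties
to the lowest source index (the result is always an exact partition),
compositing that takes the winning source's **full complex coefficient**
per radial bin — the winner is chosen by radially averaged modulus, not by a
voxelwise modulus max, which would scramble phases and be uninvertible —
and inverse transformation with a ≤1e-10 imaginary-residual check.
Cube-corner frequencies beyond Nyquist fold into the last radial bin so the
bins cover the whole reciprocal grid. `prepare_maps` registers maps to the
first by 3D phase-correlation translation plus optional local Powell
rotation refinement, then matches each map's global scale to the reference
over shells 1–4 (skipping DC); maps whose registration correlation stays
below a floor are passed through unaligned with a warning. Whether
real-world inputs need registration at all depends on how they were
reconstructed; the step is a no-op for already-aligned maps.

## Pipeline (`cli`)

`run-all` executes phantom → 4D simulation → ePIE → picking → per-branch
known-pose reconstruction with half-set FSC → per-branch CSA bandpass
emulation → synthesis, into a fresh versioned run directory with a SHA-256
manifest; stage failures halt with the stage name and retain partial
artefacts. Because the thin-object forward model transfers all frequencies
(the real CSA-dependent transfer arises from partial coherence physics
outside this model), the pipeline's "per-CSA" branches are emulated by
applying the configured bandpass to each branch's reconstructed map before
synthesis — the pseudo-CSA design. Picked particles inherit the pose of the
nearest planted ground-truth particle, which is the known-pose stand-in for
orientation refinement.

## Problem sizes and what the tests show

Default study conditions: 64³ phantoms at 0.5 nm voxels (0.8 nm in the
shadow regime), 64² detectors, 16×16 scans, 100 ePIE iterations, doses of
~10⁴ electrons per pattern where noise is wanted (≈25 e/Å² at a 2 nm step),
motion factors 0–0.7 nm. These sizes exercise every algorithm at full
fidelity while each suite stage stays in the seconds-to-minutes range on a
single CPU. Passing tests demonstrate internal consistency and recovery on
synthetic thin weak-phase specimens; they do not demonstrate performance on
thick specimens (multislice scattering), real detector physics (MTF, gain),
partial coherence, or experimental-scale datasets, and the pseudo-CSA
emulation stands in for — rather than reproduces — the physical
CSA-dependent transfer.

## Known limitations

* The thin-object multiplicative approximation breaks down for specimens
  thicker than a few tens of nm; no optical sectioning is provided.
* Position estimation requires the shadow-imaging (large-defocus) regime
  and textured specimens; weakly defocused or featureless data fall back to
  the nominal raster.
* The known-pose reconstructor cannot process experimental particles of
  unknown orientation.
* `prepare_maps` rotation refinement is local; grossly misoriented maps
  need an external coarse alignment first.
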
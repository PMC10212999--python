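# ptychospa

Desk-scale single-particle analysis (SPA) for cryo-electron **ptychography**:
simulate 4D scanning-diffraction data of weak-phase specimens, retrieve the
complex object wave with ePIE, pick and extract particles from the phase and
amplitude images, build 3D maps from known poses with gold-standard Fourier
shell correlation (FSC), and synthesise a wide-bandwidth 3D map from maps
acquired at different probe convergence semi-angles (CSAs) by **multi-band
Fourier synthesis**.

Ptychography scans a defocused convergent electron probe over a cryo
specimen and records a far-field diffraction pattern at every position (a 4D
dataset). Iterative phase retrieval recovers the complex specimen
transmission — for weak-phase biological material the *phase* is the
contrast signal, with no contrast-transfer-function reversals to correct.
The transfer acts as a bandpass controlled by the CSA α, so maps
reconstructed at different α carry their best information in different
radial frequency bands; combining the strongest band from each yields one
map with wide-bandwidth transfer. The package is aimed at methods developers
who want every stage of that chain testable on synthetic data on one CPU.

## The core algorithm

For maps V_αi(r) reconstructed at CSAs {α_i}, with 3D transforms
W_αi(q) = FT[V_αi]:

1. **Radial amplitude spectra** — mean shell modulus with bin width b:
   l_αi(q) = Σ_{q−b/2<|q⃗|≤q+b/2} |W_αi(q⃗)| / N_shell(q).
2. **Band assignment** — each shell belongs to the source whose transfer is
   strongest there: B_αi = {q : l_αi(q) ≥ l_αj(q) ∀ j ≠ i} (ties to the
   lowest index), an exact partition of the radial axis.
3. **Compositing** — W_max(q⃗) = W_αi(q⃗) for |q⃗| ∈ B_αi: the winning
   source contributes its *full complex* coefficient, so phases are
   preserved.
4. **Synthesis** — V_max(r) = FT⁻¹[W_max], real up to numerical residual.

Everything upstream exists to produce and validate the V_αi: a virus-like
phantom generator (hollow shell with deterministic surface bumps),
projection via the Fourier-slice-consistent line integral, the defocused
aperture-limited probe, a thin-object multiplicative forward model with
Poisson counting noise at stated doses (~20–25 e/Å²) and isotropic
beam-induced motion blur (0–0.7 nm RMS), the ePIE object/probe update with
cross-correlation scan-position initialisation and in-iteration refinement,
Laplacian-of-Gaussian particle picking cross-checked between phase and
amplitude, and a known-pose direct-Fourier 3D reconstructor with FSC = 0.143
resolution estimation.

## Worked example

```python
import numpy as np
from ptychospa.core import Volume3D
from ptychospa.phantom import make_virus_phantom, make_bandpassed_map
from ptychospa.bandsynth import synthesize_multiband, radial_amplitude_spectrum, assign_bands, band_edges

vol = make_virus_phantom(64, 0.5, outer_radius=10.0, shell_thickness=2.0, n_bumps=30, seed=5)
b = 1.0 / (64 * 0.5)                       # one reciprocal voxel, nm^-1
parts = [(0.0, 10*b), (10*b, 20*b), (20*b, vol.nyquist)]
rng = np.random.default_rng(1)
maps = [Volume3D(make_bandpassed_map(vol, lo, hi).values
                 + rng.normal(0, 0.004, (64,)*3), 0.5) for lo, hi in parts]

vmax = synthesize_multiband(maps)
bands = assign_bands([radial_amplitude_spectrum(m) for m in maps])
print(band_edges(bands)[["source", "q_lo_nm_inv", "q_hi_nm_inv"]])
def corr(a, b):
    a = a - a.mean(); b = b - b.mean()
    return (a*b).sum() / np.sqrt((a*a).sum() * (b*b).sum())
print("single-band:", [float(round(corr(m.values, vol.values), 4)) for m in maps])
print("synthesised:", round(corr(vmax.values, vol.values), 4))
```

prints

```
   source  q_lo_nm_inv  q_hi_nm_inv
0       0       0.0000      0.31250
1       1       0.3125      0.62500
2       2       0.6250      1.03125
single-band: [0.9639, 0.2124, 0.1545]
synthesised: 0.9996
```

Each noisy single-band map correlates with the ground-truth phantom only as
well as its band allows (the low-frequency map dominates a real-space
correlation); the synthesised map recovers signal in every band and beats
all three. The band table shows each source winning exactly its own band,
in nm⁻¹.

A full end-to-end run (phantom → 4D simulation → ePIE → picking → per-branch
3D maps with FSC → synthesis) is one command:

```bash
ptychospa run-all            # writes runs/run-000/ with a manifest
```

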
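"""Synthetic specimens: virus-like phantoms, projections and object waves.

The generator stands in for a rotavirus double-layered particle at desk
scale: a hollow protein shell decorated with smooth surface protrusions that
put structure at mid/high spatial frequencies (mimicking capsid trimer
texture).  Projections follow the thin-specimen line-integral model, and the
weak-phase mapping turns projected density into a complex transmission
function for the ptychographic forward model.
"""

from __future__ import annotations

import numpy as np

from ptychospa.core import ObjectWave, Pose, Projection2D, Volume3D, radial_frequency_grid

__all__ = [
    "make_virus_phantom",
    "make_blob_phantom",
    "project_volume",
    "projection_to_object_wave",
    "make_bandpassed_map",
    "place_projections",
]


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (golden-spiral lattice)."""
    if n == 0:
        return np.zeros((0, 3))
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.stack(
        [np.cos(phi), np.sin(phi) * np.sin(theta), np.sin(phi) * np.cos(theta)], axis=1
    )  # (z, y, x)


def make_virus_phantom(
    n_vox: int,
    voxel_size: float,
    outer_radius: float,
    shell_thickness: float,
    n_bumps: int = 60,
    seed: int = 0,
) -> Volume3D:
    """Hollow spherical shell with seeded surface protrusions, values in [0, 1].

    Parameters
    ----------
    n_vox
        Cube edge in voxels.
    voxel_size
        Voxel edge in nm.
    outer_radius, shell_thickness
        Shell outer radius and radial thickness in nm.
    n_bumps
        Number of smooth Gaussian protrusions placed deterministically on a
        Fibonacci-sphere lattice over the outer surface, with seeded angular
        jitter.
    seed
        Seeds the jitter; the same seed reproduces the volume bit for bit.
    """
    if n_bumps < 0:
        raise ValueError("n_bumps must be >= 0")
    half_box = n_vox * voxel_size / 2.0
    if outer_radius + shell_thickness >= half_box:
        raise ValueError(
            f"phantom does not fit: outer_radius + shell_thickness = "
            f"{outer_radius + shell_thickness:g} nm >= half box {half_box:g} nm"
        )
    ax = (np.arange(n_vox) - n_vox // 2) * voxel_size
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(z**2 + y**2 + x**2)

    # smoothed annulus between inner and outer radius; the ~1.5-voxel edge
    # keeps the phantom band-limited enough for interpolation-based
    # projection to conserve mass to high precision
    w = 1.5 * voxel_size
    inner = outer_radius - shell_thickness

    def smoothstep(t):
        t = np.clip(t, 0.0, 1.0)
        return t * t * (3.0 - 2.0 * t)

    shell = smoothstep((r - inner) / w + 0.5) * smoothstep((outer_radius - r) / w + 0.5)

    rng = np.random.default_rng(seed)
    if n_bumps > 0:
        # bumps at 0.4 amplitude over a 0.6 shell: the sum stays below 1
        # without clipping, which would re-introduce sharp plateaus
        shell *= 0.6
        dirs = _fibonacci_sphere(n_bumps)
        jitter = rng.normal(0.0, 0.03, size=dirs.shape)
        dirs = dirs + jitter
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        sigma = max(shell_thickness / 2.0, voxel_size)
        centres = dirs * outer_radius
        for cz, cy, cx in centres:
            d2 = (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2
            shell += 0.4 * np.exp(-0.5 * d2 / sigma**2)
    return Volume3D(np.clip(shell, 0.0, 1.0), voxel_size)


def make_blob_phantom(
    n_vox: int, voxel_size: float, centres, sigmas, amplitudes
) -> Volume3D:
    """Sum of isotropic 3D Gaussians (centres in nm relative to box centre).

    Smooth by construction, with closed-form projections and Fourier
    transforms, so it is the fixture of choice for interpolation-tolerance
    checks.
    """
    ax = (np.arange(n_vox) - n_vox // 2) * voxel_size
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    vol = np.zeros((n_vox,) * 3)
    for (cz, cy, cx), s, a in zip(np.atleast_2d(centres), np.atleast_1d(sigmas), np.atleast_1d(amplitudes)):
        d2 = (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2
        vol += a * np.exp(-0.5 * d2 / s**2)
    return Volume3D(vol, voxel_size)


def project_volume(vol: Volume3D, pose: Pose, order: int = 5) -> Projection2D:
    """Rotated line integral of ``vol`` along the lab z-axis.

    The pose rotation maps particle-frame to lab-frame coordinates; the
    volume is resampled on the rotated grid (spline interpolation of the
    given ``order``, quintic by default) and summed along z.  Rotation is
    about voxel ``n // 2`` on each axis, the same centre convention used by
    the phantom builders and the 3D reconstructor.  For band-limited
    volumes the projection integral matches the volume integral to high
    precision; sharp-edged volumes incur small interpolation under/overshoot.
    """
    from scipy.ndimage import affine_transform

    n = vol.n
    c = n // 2
    centre = np.full(3, float(c))
    # values are indexed (z, y, x) while the rotation acts on (x, y, z):
    # express the inverse rotation in reversed-axis order for affine_transform
    m = np.linalg.inv(pose.matrix()[::-1, ::-1])
    rotated = affine_transform(
        vol.values, m, offset=centre - m @ centre, order=order, mode="constant"
    )
    proj = rotated.sum(axis=0)
    if np.any(pose.shift):
        from scipy.ndimage import shift as nd_shift

        proj = nd_shift(proj, pose.shift / vol.voxel_size, order=order, mode="constant")
    return Projection2D(proj, vol.voxel_size)


def projection_to_object_wave(
    proj: Projection2D, phase_scale: float, amplitude_decay: float = 0.0
) -> ObjectWave:
    """Weak-phase/attenuation mapping of projected density to transmission.

    ``t(r) = exp(-amplitude_decay * p(r)) * exp(i * phase_scale * p(r))``;
    for a non-negative projection ``|t| <= 1``.
    """
    if phase_scale < 0 or amplitude_decay < 0:
        raise ValueError("phase_scale and amplitude_decay must be >= 0")
    p = proj.values
    t = np.exp(-amplitude_decay * p) * np.exp(1j * phase_scale * p)
    return ObjectWave(t, proj.pixel_size)


def _band_mask(q: np.ndarray, q_lo: float, q_hi: float, nyquist: float, rolloff_width: float):
    open_top = q_hi >= nyquist * (1.0 - 1e-9)
    if rolloff_width <= 0:
        mask = (q > q_lo) & ((q <= q_hi) | open_top)
        if q_lo <= 0:
            mask |= q == 0.0
        return mask.astype(float)
    # raised-cosine roll-off of the given width centred on each edge
    lo = np.clip((q - (q_lo - rolloff_width / 2)) / rolloff_width, 0.0, 1.0)
    hi = np.clip(((q_hi + rolloff_width / 2) - q) / rolloff_width, 0.0, 1.0)
    m = 0.5 * (1 - np.cos(np.pi * lo)) * (0.5 * (1 - np.cos(np.pi * hi)) if not open_top else 1.0)
    if q_lo <= 0:
        m = np.where(q <= q_lo, 0.5 * (1 - np.cos(np.pi * hi)) if not open_top else 1.0, m)
    return m


def make_bandpassed_map(
    vol: Volume3D,
    q_lo: float,
    q_hi: float,
    noise_rms: float = 0.0,
    seed: int = 0,
    rolloff_width: float = 0.0,
) -> Volume3D:
    """Emulate a single-CSA SPA map: radial bandpass plus white Gaussian noise.

    The ptychographic transfer function at one convergence semi-angle acts as
    a bandpass in spatial frequency; this models that transfer as a hard-edged
    (default) or raised-cosine radial filter on the 3D Fourier transform.
    With the hard edge, maps filtered over a disjoint covering partition of
    frequency bands sum back to the input exactly.

    When ``q_hi`` equals the grid Nyquist frequency the band is open at the
    top so that corner frequencies (|q| > Nyquist along diagonals) are kept;
    this makes covering partitions exact.
    """
    if not (0 <= q_lo < q_hi):
        raise ValueError("need 0 <= q_lo < q_hi")
    if q_hi > vol.nyquist * (1.0 + 1e-9):
        raise ValueError(f"q_hi {q_hi:g} beyond Nyquist {vol.nyquist:g} nm^-1")
    q = radial_frequency_grid(vol.n, vol.voxel_size, ndim=3)
    mask = _band_mask(q, q_lo, q_hi, vol.nyquist, rolloff_width)
    filtered = np.fft.ifftn(np.fft.fftn(vol.values) * mask).real
    if noise_rms > 0:
        rng = np.random.default_rng(seed)
        filtered = filtered + rng.normal(0.0, noise_rms, size=filtered.shape)
    return Volume3D(filtered, vol.voxel_size)


def place_projections(
    projections,
    centres_px,
    canvas_px: int,
    pixel_size: float,
    background_rms: float = 0.0,
    background_corr_px: float = 2.0,
    seed: int = 0,
) -> Projection2D:
    """Additively place projection images on a square canvas (scene builder).

    ``centres_px`` are (y, x) pixel centres for each projection; images are
    placed at the nearest-pixel position.  Used to build a field of view
    containing several particles for the forward 4D simulation.

    ``background_rms > 0`` adds a vitreous-ice-like background: seeded
    Gaussian noise smoothed to a correlation length of
    ``background_corr_px`` pixels, scaled to the given RMS (density units)
    and offset to be non-negative.  Real cryo specimens are never embedded
    in perfect vacuum, and the textured background is what makes
    cross-correlation position estimation possible between particles.
    """
    canvas = np.zeros((canvas_px, canvas_px))
    if background_rms > 0:
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(seed)
        bg = gaussian_filter(rng.normal(0.0, 1.0, canvas.shape), background_corr_px)
        bg *= background_rms / bg.std()
        canvas += bg - bg.min()
    for proj, (cy, cx) in zip(projections, centres_px):
        img = proj.values
        h, w = img.shape
        y0 = int(round(cy)) - h // 2
        x0 = int(round(cx)) - w // 2
        if y0 < 0 or x0 < 0 or y0 + h > canvas_px or x0 + w > canvas_px:
            raise ValueError("projection does not fit on the canvas at this centre")
        canvas[y0 : y0 + h, x0 : x0 + w] += img
    return Projection2D(canvas, pixel_size)
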
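"""Known-pose 3D reconstruction, gold-standard FSC and resolution.

Particle images are inserted as central slices into a 3D Fourier
accumulator at their (known) poses — the desk-scale stand-in for a full
orientation-refinement package.  Half-sets are split at random and
reconstructed independently so the Fourier shell correlation between them is
unbiased ("gold standard"); resolution is quoted at the FSC = 0.143
threshold.  No transfer-function (CTF/MTF) division is applied: the
ptychographic transfer has no contrast reversals, so none is needed at this
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from ptychospa.core import Pose, Volume3D, radial_frequency_grid
from ptychospa.particles import ParticleStack

__all__ = [
    "FSCCurve",
    "reconstruct_known_pose",
    "split_halves",
    "fsc_curve",
    "resolution_at_threshold",
    "icosahedral_rotations",
    "NOT_REACHED",
]

NOT_REACHED = float("inf")


@dataclass
class FSCCurve:
    q_bins: np.ndarray  # shell centres, nm^-1
    correlation: np.ndarray
    bin_width: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"q_nm_inv": self.q_bins, "fsc": self.correlation})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def icosahedral_rotations() -> list[Rotation]:
    """The 60 proper rotations of the icosahedral group."""
    return list(Rotation.create_group("I"))


def _insert_slice(acc, wgt, f2d, rot_matrix, n_out):
    """Trilinear insertion of one 2D transform as a central slice."""
    n_img = f2d.shape[0]
    k = np.fft.fftfreq(n_img) * n_img  # signed integer frequencies
    ky, kx = np.meshgrid(k, k, indexing="ij")
    scale = n_out / n_img
    plane = np.stack([kx.ravel(), ky.ravel(), np.zeros(kx.size)]) * scale
    q3 = rot_matrix.T @ plane  # (x, y, z) reciprocal-voxel coords in the volume
    vals = f2d.ravel()
    lim = n_out / 2 - 1
    ok = np.all(np.abs(q3) <= lim, axis=0)
    q3 = q3[:, ok]
    vals = vals[ok]
    base = np.floor(q3).astype(np.intp)
    frac = q3 - base
    for corner in range(8):
        w = np.ones(q3.shape[1])
        idx = np.empty_like(base)
        for axis in range(3):
            bit = (corner >> axis) & 1
            w = w * (frac[axis] if bit else 1.0 - frac[axis])
            idx[axis] = (base[axis] + bit) % n_out
        flat = (idx[2] * n_out + idx[1]) * n_out + idx[0]  # (z, y, x) C-order
        np.add.at(acc, flat, w * vals)
        np.add.at(wgt, flat, w)


def reconstruct_known_pose(
    stack: ParticleStack,
    poses: list[Pose],
    symmetry_ops: list[Rotation] | None = None,
    box_out: int | None = None,
    wiener_eps: float = 1e-3,
) -> Volume3D:
    """Direct Fourier inversion of a particle stack at known poses.

    Each image's 2D transform is inserted as a central slice at its pose
    (and at every symmetry-rotated pose) with trilinear weights; the
    accumulator is normalised by the accumulated weights with a Wiener-style
    floor ``wiener_eps * max(weight)`` and inverse-transformed.
    """
    if stack.n_particles == 0:
        raise ValueError("empty particle stack")
    if len(poses) != stack.n_particles:
        raise ValueError("one pose per particle required")
    if symmetry_ops is None:
        symmetry_ops = [Rotation.identity()]
    if not symmetry_ops:
        raise ValueError("symmetry_ops must be non-empty (identity allowed)")
    n_img = stack.boxes.shape[-1]
    n_out = box_out or n_img
    acc = np.zeros(n_out**3, dtype=np.complex128)
    wgt = np.zeros(n_out**3)
    k = np.fft.fftfreq(n_img) * n_img
    ky, kx = np.meshgrid(k, k, indexing="ij")
    for img, pose in zip(stack.boxes, poses):
        # de-centre so the particle sits at the array origin: the slice
        # spectra are then smooth and trilinear insertion is accurate
        f2d = np.fft.fft2(np.fft.ifftshift(img))
        if np.any(pose.shift):
            sy, sx = pose.shift / stack.pixel_size
            f2d = f2d * np.exp(2j * np.pi * (ky * sy + kx * sx) / n_img)
        for sym in symmetry_ops:
            _insert_slice(acc, wgt, f2d, (pose.rotation * sym).as_matrix(), n_out)
    floor = wiener_eps * wgt.max()
    vol_f = (acc / (wgt + floor)).reshape(n_out, n_out, n_out)
    # re-centre the particle at voxel (n//2, n//2, n//2)
    vol = np.fft.fftshift(np.fft.ifftn(vol_f).real)
    return Volume3D(vol, stack.pixel_size)


def split_halves(stack: ParticleStack, poses: list[Pose], seed: int = 0):
    """Seeded random disjoint half-sets of near-equal size (gold standard)."""
    n = stack.n_particles
    if n < 2:
        raise ValueError("need at least 2 particles to split")
    perm = np.random.default_rng(seed).permutation(n)
    halves = []
    for sel in (perm[: n // 2], perm[n // 2 :]):
        sub = ParticleStack(
            stack.boxes[sel], stack.coordinates[sel], stack.pixel_size, stack.source_id
        )
        halves.append((sub, [poses[i] for i in sel]))
    return halves[0], halves[1]


def fsc_curve(vol_a: Volume3D, vol_b: Volume3D, bin_width: float | None = None) -> FSCCurve:
    """Fourier shell correlation between two maps on identical grids.

    Per shell: Re(sum F_A conj(F_B)) / sqrt(sum |F_A|^2 sum |F_B|^2), in
    contiguous bins of ``bin_width`` nm^-1 (default one reciprocal voxel)
    from 0 to the Nyquist frequency.
    """
    if vol_a.values.shape != vol_b.values.shape or abs(vol_a.voxel_size - vol_b.voxel_size) > 1e-12:
        raise ValueError("FSC requires identical grids and voxel sizes")
    n = vol_a.n
    if bin_width is None:
        bin_width = 1.0 / (n * vol_a.voxel_size)
    fa = np.fft.fftn(vol_a.values)
    fb = np.fft.fftn(vol_b.values)
    q = radial_frequency_grid(n, vol_a.voxel_size, ndim=3).ravel()
    nbins = int(np.floor(vol_a.nyquist / bin_width)) + 1
    idx = np.minimum((q / bin_width).astype(np.intp), nbins)  # overflow bin for corners
    cross = np.bincount(idx, weights=(fa * np.conj(fb)).real.ravel(), minlength=nbins + 1)
    pa = np.bincount(idx, weights=(np.abs(fa) ** 2).ravel(), minlength=nbins + 1)
    pb = np.bincount(idx, weights=(np.abs(fb) ** 2).ravel(), minlength=nbins + 1)
    denom = np.sqrt(pa[:nbins] * pb[:nbins])
    corr = np.where(denom > 0, cross[:nbins] / np.where(denom > 0, denom, 1.0), 0.0)
    centres = (np.arange(nbins) + 0.5) * bin_width
    return FSCCurve(centres, corr, bin_width)


def resolution_at_threshold(curve: FSCCurve, threshold: float = 0.143) -> float:
    """Resolution (nm) at the first crossing below ``threshold``.

    Linearly interpolated between shell centres; returns ``NOT_REACHED``
    (inf on the frequency axis, i.e. better than Nyquist) when the curve
    never drops below the threshold.
    """
    if len(curve.q_bins) == 0:
        raise ValueError("empty FSC curve")
    c = curve.correlation
    q = curve.q_bins
    below = np.nonzero(c < threshold)[0]
    if len(below) == 0:
        return NOT_REACHED
    i = below[0]
    if i == 0:
        q_cross = q[0]
    else:
        f = (c[i - 1] - threshold) / (c[i - 1] - c[i])
        q_cross = q[i - 1] + f * (q[i] - q[i - 1])
    return float(1.0 / q_cross)
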
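"""Forward 4D scanning-diffraction simulation.

Thin-specimen (multiplicative) interaction: at each scan position the probe
window multiplies the object transmission and the far-field intensity is the
squared modulus of the 2D Fourier transform.  Patterns are normalised so a
vacuum pattern integrates to 1 before dose scaling; counting statistics are
Poisson at the requested electrons per pattern.  Beam-induced motion is an
incoherent average over rigid in-plane displacements drawn with RMS equal to
the motion factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from ptychospa.core import ObjectWave
from ptychospa.probe_scan import ProbeField, ScanPlan

__all__ = ["FourDDataset", "simulate_pattern", "simulate_dataset", "save_dataset", "load_dataset"]


@dataclass
class FourDDataset:
    """J diffraction patterns with positions and acquisition metadata.

    ``positions`` are the true probe positions used in the simulation;
    ``nominal_positions`` are the raster the operator believes was scanned.
    Reconstruction starts from the nominal grid, as on the instrument.
    """

    intensities: np.ndarray  # (J, n, n) counts (or vacuum-normalised if noiseless)
    positions: np.ndarray  # (J, 2) (y, x) nm
    nominal_positions: np.ndarray  # (J, 2) nm
    pixel_size: float  # object/probe sampling, nm
    wavelength: float  # pm
    electrons_per_pattern: float  # 0 = noiseless sentinel
    motion_factor: float  # nm RMS
    step: float  # nm
    seed: int

    def __post_init__(self) -> None:
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (J, Ny, Nx)")
        if len(self.positions) != len(self.intensities):
            raise ValueError("positions and intensities disagree on J")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_patterns(self) -> int:
        return len(self.intensities)

    @property
    def detector_pixel_angle_mrad(self) -> float:
        """Scattering angle per detector pixel, mrad (dq * lambda)."""
        n = self.intensities.shape[-1]
        dq = 1.0 / (n * self.pixel_size)  # nm^-1 per pixel
        return dq * (self.wavelength * 1e-3) * 1e3


def _shift_probe(probe_values: np.ndarray, dy_px: float, dx_px: float) -> np.ndarray:
    """Sub-pixel probe shift by Fourier phase ramp.

    Exact for the aperture-limited probe, whose spectrum vanishes at and
    beyond Nyquist.
    """
    if dy_px == 0.0 and dx_px == 0.0:
        return probe_values
    n = probe_values.shape[0]
    f = np.fft.fftfreq(n)
    ramp = np.exp(-2j * np.pi * (f[:, None] * dy_px + f[None, :] * dx_px))
    return np.fft.ifft2(np.fft.fft2(probe_values) * ramp)


def _window_origin(position, pixel_size, n_probe, obj_shape):
    """Integer window origin and fractional probe offset for a position (nm)."""
    py, px = position
    iy = int(round(py / pixel_size)) - n_probe // 2
    ix = int(round(px / pixel_size)) - n_probe // 2
    fy = py / pixel_size - round(py / pixel_size)
    fx = px / pixel_size - round(px / pixel_size)
    if iy < 0 or ix < 0 or iy + n_probe > obj_shape[0] or ix + n_probe > obj_shape[1]:
        raise ValueError(
            f"probe window at position ({py:g}, {px:g}) nm falls outside the object "
            f"(origin ({iy}, {ix}), object {obj_shape})"
        )
    return iy, ix, fy, fx


def simulate_pattern(obj: ObjectWave, probe: ProbeField, position) -> np.ndarray:
    """Noiseless far-field intensity |FT(P(r - r_j) O(r))|^2 at one position.

    Normalised (orthonormal FT) so the vacuum pattern sums to 1.  Raises when
    the probe window would leave the object support — no silent wraparound.
    """
    if abs(obj.pixel_size - probe.pixel_size) > 1e-12 * probe.pixel_size:
        raise ValueError("object and probe must share pixel_size")
    n = probe.n
    iy, ix, fy, fx = _window_origin(position, probe.pixel_size, n, obj.values.shape)
    p = _shift_probe(probe.values, fy, fx)
    exit_wave = p * obj.values[iy : iy + n, ix : ix + n]
    return np.abs(np.fft.fft2(exit_wave, norm="ortho")) ** 2


def simulate_dataset(
    obj: ObjectWave,
    probe: ProbeField,
    scan: ScanPlan,
    electrons_per_pattern: float = 0.0,
    motion_factor: float = 0.0,
    n_motion_draws: int = 8,
    seed: int = 0,
) -> FourDDataset:
    """Simulate the full 4D dataset over a scan plan.

    Per position the noiseless pattern is the average over ``n_motion_draws``
    patterns with the specimen rigidly displaced by isotropic Gaussian
    offsets of RMS ``motion_factor`` (a specimen shift of +d equals a probe
    shift of -d).  With ``electrons_per_pattern > 0`` the pattern is scaled
    to that expectation and Poisson-sampled; 0 is the noiseless sentinel.
    """
    if electrons_per_pattern < 0 or motion_factor < 0:
        raise ValueError("electrons_per_pattern and motion_factor must be >= 0")
    rng = np.random.default_rng(seed)
    n = probe.n
    j = scan.n_positions
    out = np.empty((j, n, n))
    for k, pos in enumerate(scan.positions):
        if motion_factor > 0:
            offsets = rng.normal(0.0, motion_factor / np.sqrt(2.0), size=(n_motion_draws, 2))
            acc = np.zeros((n, n))
            for dy, dx in offsets:
                acc += simulate_pattern(obj, probe, (pos[0] - dy, pos[1] - dx))
            out[k] = acc / n_motion_draws
        else:
            out[k] = simulate_pattern(obj, probe, pos)
    if electrons_per_pattern > 0:
        out = rng.poisson(out * electrons_per_pattern).astype(np.float64)
    return FourDDataset(
        intensities=out,
        positions=np.asarray(scan.positions, dtype=float),
        nominal_positions=np.asarray(scan.nominal, dtype=float),
        pixel_size=probe.pixel_size,
        wavelength=probe.wavelength,
        electrons_per_pattern=electrons_per_pattern,
        motion_factor=motion_factor,
        step=scan.step,
        seed=seed,
    )


def save_dataset(path, ds: FourDDataset) -> None:
    """Write the dataset to HDF5 (/intensities, /positions_nm + attributes)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("intensities", data=ds.intensities, track_times=False)
        f.create_dataset("positions_nm", data=ds.positions, track_times=False)
        f.create_dataset("nominal_positions_nm", data=ds.nominal_positions, track_times=False)
        f.attrs["pixel_size_nm"] = ds.pixel_size
        f.attrs["wavelength_pm"] = ds.wavelength
        f.attrs["electrons_per_pattern"] = ds.electrons_per_pattern
        f.attrs["motion_factor_nm"] = ds.motion_factor
        f.attrs["step_nm"] = ds.step
        f.attrs["seed"] = ds.seed
        f.attrs["detector_pixel_angle_mrad"] = ds.detector_pixel_angle_mrad


def load_dataset(path) -> FourDDataset:
    """Read and validate a dataset written by :func:`save_dataset`."""
    with h5py.File(path, "r") as f:
        inten = f["intensities"][...]
        pos = f["positions_nm"][...]
        nom = f["nominal_positions_nm"][...]
        attrs = dict(f.attrs)
    if pos.shape != (len(inten), 2) or nom.shape != pos.shape:
        raise ValueError("positions_nm inconsistent with intensities")
    ds = FourDDataset(
        intensities=inten,
        positions=pos,
        nominal_positions=nom,
        pixel_size=float(attrs["pixel_size_nm"]),
        wavelength=float(attrs["wavelength_pm"]),
        electrons_per_pattern=float(attrs["electrons_per_pattern"]),
        motion_factor=float(attrs["motion_factor_nm"]),
        step=float(attrs["step_nm"]),
        seed=int(attrs["seed"]),
    )
    stored = float(attrs["detector_pixel_angle_mrad"])
    if abs(stored - ds.detector_pixel_angle_mrad) > 1e-9 * max(stored, 1.0):
        raise ValueError("angular calibration attribute inconsistent with grid")
    return ds
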
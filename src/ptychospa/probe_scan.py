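"""Defocused convergent probe, scan plans, and protocol bookkeeping.

The acquisition protocol constrains two derived quantities: the fractional
overlap of adjacent illuminated areas (kept between 60% and 95% so the
iterative reconstruction converges) and the accumulated electron dose per
unit area.  Both are computed here from first principles, together with the
aperture-limited defocused probe itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import constants

__all__ = [
    "ProbeField",
    "ScanPlan",
    "electron_wavelength",
    "make_probe",
    "probe_diameter",
    "overlap_ratio",
    "dose_per_area",
    "scan_grid",
    "protocol_report",
]

OVERLAP_RANGE = (0.60, 0.95)


@dataclass
class ProbeField:
    """Complex probe wave at the specimen plane.

    ``values`` is power-normalised (sum |P|^2 = 1) and aperture-limited: its
    Fourier support is confined to scattering angles <= ``csa_mrad``.
    """

    values: np.ndarray
    pixel_size: float  # nm
    csa_mrad: float
    defocus: float  # nm
    kv: float
    wavelength: float  # pm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("probe grid must be square")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ScanPlan:
    """Raster scan positions (nm), nominal and jittered-actual."""

    positions: np.ndarray  # (J, 2) actual (y, x) nm
    nominal: np.ndarray  # (J, 2) nominal (y, x) nm
    step: float
    jitter_rms: float
    seed: int

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(self.n_positions),
                "nominal_x": self.nominal[:, 1],
                "nominal_y": self.nominal[:, 0],
                "actual_x": self.positions[:, 1],
                "actual_y": self.positions[:, 0],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def electron_wavelength(kv: float) -> float:
    """Relativistic de Broglie wavelength in pm for a beam energy in kV.

    lambda = h / sqrt(2 m0 e V (1 + e V / (2 m0 c^2))); 300 kV -> ~1.97 pm.
    """
    if kv <= 0:
        raise ValueError("accelerating voltage must be positive")
    v = kv * 1e3
    h, m0, e, c = constants.h, constants.m_e, constants.e, constants.c
    lam = h / np.sqrt(2 * m0 * e * v * (1 + e * v / (2 * m0 * c**2)))
    return lam * 1e12


def make_probe(
    kv: float, csa_mrad: float, defocus: float, n_pix: int, pixel_size: float
) -> ProbeField:
    """Defocused aperture-limited probe.

    A top-hat condenser aperture of semi-angle ``csa_mrad`` with a quadratic
    defocus phase chi(q) = pi * lambda * defocus * q^2 is inverse-transformed
    to the specimen plane and power-normalised.  Raises if the aperture falls
    beyond the Nyquist frequency of the requested grid.
    """
    lam_nm = electron_wavelength(kv) * 1e-3
    alpha = csa_mrad * 1e-3
    q_max = alpha / lam_nm  # aperture radius in nm^-1
    nyq = 0.5 / pixel_size
    if q_max > nyq:
        needed = 0.5 / q_max
        raise ValueError(
            f"aperture ({q_max:.3g} nm^-1) beyond grid Nyquist ({nyq:.3g} nm^-1); "
            f"need pixel_size <= {needed:.4g} nm"
        )
    f = np.fft.fftfreq(n_pix, d=pixel_size)
    qy, qx = np.meshgrid(f, f, indexing="ij")
    q2 = qx**2 + qy**2
    aperture = (q2 <= q_max**2).astype(float)
    chi = np.pi * lam_nm * defocus * q2
    a = aperture * np.exp(-1j * chi)
    p = np.fft.ifft2(a)
    p /= np.sqrt(np.sum(np.abs(p) ** 2))
    return ProbeField(
        np.fft.fftshift(p), pixel_size, csa_mrad, defocus, kv, electron_wavelength(kv)
    )


def probe_diameter(kv: float, csa_mrad: float, defocus: float) -> float:
    """Probe footprint diameter in nm for overlap bookkeeping.

    Geometric disc of a defocused cone, 2 |defocus| alpha, plus one
    diffraction-limited radius 1.22 lambda / alpha.
    """
    lam_nm = electron_wavelength(kv) * 1e-3
    alpha = csa_mrad * 1e-3
    return 2.0 * abs(defocus) * alpha + 1.22 * lam_nm / alpha


def overlap_ratio(probe_diam: float, step: float, definition: str = "area") -> float:
    """Fractional overlap of two probe discs of diameter D at centre distance step.

    ``definition="area"`` (default) is the lens-area formula
    [2 R^2 acos(d/2R) - (d/2) sqrt(4R^2 - d^2)] / (pi R^2); ``"linear"`` is
    the simpler 1 - step/D.
    """
    if probe_diam <= 0 or step < 0:
        raise ValueError("probe_diameter must be > 0 and step >= 0")
    if step >= probe_diam:
        return 0.0
    if definition == "linear":
        return 1.0 - step / probe_diam
    if definition != "area":
        raise ValueError("definition must be 'area' or 'linear'")
    r = probe_diam / 2.0
    d = step
    lens = 2 * r**2 * np.arccos(d / (2 * r)) - (d / 2.0) * np.sqrt(4 * r**2 - d**2)
    return float(lens / (np.pi * r**2))


def dose_per_area(electrons_per_pattern: float, step: float) -> float:
    """Accumulated dose in e/A^2 for a raster of the given step (nm).

    Interior-of-FOV approximation: each step x step cell receives one
    pattern's electrons on average, so dose = electrons / (10 * step)^2.
    """
    if electrons_per_pattern < 0:
        raise ValueError("electrons_per_pattern must be >= 0")
    if step <= 0:
        raise ValueError("step must be positive")
    return electrons_per_pattern / (10.0 * step) ** 2


def scan_grid(fov: float, step: float, jitter_rms: float = 0.0, seed: int = 0) -> ScanPlan:
    """Square raster over ``fov`` nm with seeded isotropic Gaussian jitter.

    ``jitter_rms`` is the RMS of the 2D displacement magnitude (per-axis
    sigma = jitter_rms / sqrt(2)).
    """
    if fov < step:
        raise ValueError("fov must be at least one step")
    n_side = int(np.floor(fov / step)) + 1
    ax = np.arange(n_side) * step
    gy, gx = np.meshgrid(ax, ax, indexing="ij")
    nominal = np.stack([gy.ravel(), gx.ravel()], axis=1)
    rng = np.random.default_rng(seed)
    jitter = rng.normal(0.0, jitter_rms / np.sqrt(2.0), size=nominal.shape) if jitter_rms > 0 else 0.0
    return ScanPlan(nominal + jitter, nominal, step, jitter_rms, seed)


def protocol_report(
    kv: float, csa_mrad: float, defocus: float, step: float, electrons_per_pattern: float
) -> dict:
    """Configuration gate: overlap/dose bookkeeping with a compliance flag.

    Flags the configuration non-compliant when the area overlap falls outside
    the protocol operating window [0.60, 0.95].
    """
    d = probe_diameter(kv, csa_mrad, defocus)
    ov = overlap_ratio(d, step)
    return {
        "probe_diameter_nm": d,
        "overlap": ov,
        "dose_e_per_A2": dose_per_area(electrons_per_pattern, step),
        "overlap_compliant": OVERLAP_RANGE[0] <= ov <= OVERLAP_RANGE[1],
    }
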
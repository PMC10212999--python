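"""Shared containers passed between pipeline stages.

All real-space lengths are in nanometres; reciprocal-space frequencies in
nm^-1.  Volumes are cubic grids indexed ``(z, y, x)``; 2D images are indexed
``(y, x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass
class Volume3D:
    """Cubic 3D density map.

    Parameters
    ----------
    values
        Real scalar grid of shape ``(n, n, n)`` (arbitrary density units).
    voxel_size
        Edge length of one voxel in nm.
    origin
        Physical position of voxel ``(0, 0, 0)`` in nm, ``(z, y, x)`` order.
    """

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or len(set(self.values.shape)) != 1:
            raise ValueError(f"volume must be cubic, got shape {self.values.shape}")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.origin = np.asarray(self.origin, dtype=np.float64)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def nyquist(self) -> float:
        """Nyquist frequency of the grid in nm^-1."""
        return 0.5 / self.voxel_size

    def copy(self) -> "Volume3D":
        return Volume3D(self.values.copy(), self.voxel_size, self.origin.copy())


@dataclass
class Pose:
    """Particle orientation and in-plane shift.

    ``rotation`` maps particle-frame coordinates to the lab frame; the
    projection direction is the lab z-axis.  ``shift`` is an ``(y, x)``
    translation of the projection in nm.
    """

    rotation: Rotation
    shift: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        if not isinstance(self.rotation, Rotation):
            raise TypeError("rotation must be a scipy Rotation")
        if np.isscalar(self.rotation.magnitude()) is False:
            raise ValueError("Pose holds a single rotation, not a batch")
        self.shift = np.asarray(self.shift, dtype=np.float64)
        if self.shift.shape != (2,):
            raise ValueError("shift must be a 2-vector (y, x) in nm")

    @classmethod
    def identity(cls) -> "Pose":
        return cls(Rotation.identity())

    @classmethod
    def from_euler_zyz(cls, angles_rad, shift=(0.0, 0.0)) -> "Pose":
        return cls(Rotation.from_euler("ZYZ", angles_rad), np.asarray(shift))

    def matrix(self) -> np.ndarray:
        """3x3 proper rotation matrix acting on (x, y, z) column vectors."""
        return self.rotation.as_matrix()


@dataclass
class Projection2D:
    """Line-integral projection of a volume (projected density)."""

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("projection must be 2D")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class ObjectWave:
    """Complex specimen transmission function.

    The phase is the contrast signal for weak-phase specimens; physical
    transmissions satisfy ``|values| <= 1``.
    """

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ValueError("object wave must be 2D")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("object wave contains non-finite values")

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)


def radial_frequency_grid(n: int, voxel_size: float, ndim: int = 3) -> np.ndarray:
    """|q| on the unshifted FFT grid of an ``n``-per-side array, in nm^-1."""
    f = np.fft.fftfreq(n, d=voxel_size)
    if ndim == 3:
        qz, qy, qx = np.meshgrid(f, f, f, indexing="ij")
        return np.sqrt(qz**2 + qy**2 + qx**2)
    if ndim == 2:
        qy, qx = np.meshgrid(f, f, indexing="ij")
        return np.hypot(qy, qx)
    raise ValueError("ndim must be 2 or 3")
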
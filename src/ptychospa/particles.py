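"""Particle picking and stack extraction from reconstructed phase/amplitude.

Picking uses a scale-matched Laplacian-of-Gaussian blob response with greedy
non-maximum suppression.  Because ptychography recovers both phase and
amplitude of the specimen wave, picks from the two channels can be
cross-checked and merged before extraction into positionally coordinated
stacks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_laplace
from skimage.feature import peak_local_max

__all__ = ["ParticleStack", "pick_particles", "cross_check_picks", "extract_stack", "write_star"]


@dataclass
class ParticleStack:
    """N boxed particle images with their source coordinates.

    Coordinates are 0-based (y, x) pixel indices in the source image, origin
    at the image corner.
    """

    boxes: np.ndarray  # (N, box, box)
    coordinates: np.ndarray  # (N, 2) (y, x) pixels
    pixel_size: float  # nm
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.boxes) != len(self.coordinates):
            raise ValueError("boxes and coordinates disagree on N")

    @property
    def n_particles(self) -> int:
        return len(self.boxes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x_px": self.coordinates[:, 1], "y_px": self.coordinates[:, 0]}
        )


def pick_particles(
    image: np.ndarray,
    particle_diameter: float,
    pixel_size: float,
    threshold: float,
    min_separation: float | None = None,
) -> pd.DataFrame:
    """Pick blob centres of roughly ``particle_diameter`` (nm) from an image.

    The response is the scale-normalised negative Laplacian of Gaussian at
    sigma = diameter / (2 sqrt(2)) (the scale whose LoG response peaks for a
    blob of that diameter); maxima above ``threshold`` are kept with greedy
    non-maximum suppression at ``min_separation`` (defaults to one diameter).
    Returns a DataFrame with columns ``x_px, y_px, score`` (0-based pixel
    coordinates, origin at the corner, x fastest).
    """
    diameter_px = particle_diameter / pixel_size
    if diameter_px < 3:
        raise ValueError("particle_diameter must be at least 3 pixels")
    if min_separation is None:
        min_separation = particle_diameter
    sigma = diameter_px / (2.0 * np.sqrt(2.0))
    response = -(sigma**2) * gaussian_laplace(np.asarray(image, float), sigma)
    min_dist = max(int(round(min_separation / pixel_size)), 1)
    peaks = peak_local_max(
        response, min_distance=min_dist, threshold_abs=threshold, exclude_border=False
    )
    scores = response[tuple(peaks.T)] if len(peaks) else np.empty(0)
    order = np.argsort(scores)[::-1]
    peaks = peaks[order]
    scores = scores[order]
    return pd.DataFrame({"x_px": peaks[:, 1], "y_px": peaks[:, 0], "score": scores})


def cross_check_picks(
    phase_coords: pd.DataFrame,
    amplitude_coords: pd.DataFrame,
    tolerance: float,
    pixel_size: float = 1.0,
    keep_unmatched: bool = False,
) -> pd.DataFrame:
    """Merge picks seen in both channels; flag channel-unique picks.

    Pairs within ``tolerance`` (nm) are merged at the coordinate midpoint
    (greedy nearest-pair matching).  Unmatched picks are dropped unless
    ``keep_unmatched``; the output carries a ``matched`` flag either way.
    """
    pa = phase_coords[["y_px", "x_px"]].to_numpy(float)
    pb = amplitude_coords[["y_px", "x_px"]].to_numpy(float)
    tol_px = tolerance / pixel_size
    merged, matched_flags = [], []
    if len(pa) and len(pb):
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        used_a, used_b = set(), set()
        for k in np.argsort(d, axis=None):
            i, j = divmod(k, d.shape[1])
            if d[i, j] > tol_px:
                break
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            merged.append((pa[i] + pb[j]) / 2.0)
            matched_flags.append(True)
    else:
        used_a, used_b = set(), set()
    if keep_unmatched:
        for i in range(len(pa)):
            if i not in used_a:
                merged.append(pa[i])
                matched_flags.append(False)
        for j in range(len(pb)):
            if j not in used_b:
                merged.append(pb[j])
                matched_flags.append(False)
    if not merged:
        return pd.DataFrame(columns=["x_px", "y_px", "matched"])
    merged = np.asarray(merged)
    return pd.DataFrame(
        {"x_px": merged[:, 1], "y_px": merged[:, 0], "matched": matched_flags}
    )


def extract_stack(
    image: np.ndarray,
    coords: pd.DataFrame,
    box_size: int,
    pixel_size: float,
    source_id: str = "",
) -> tuple[ParticleStack, int]:
    """Extract ``box_size`` boxes centred on the picks.

    Coordinates whose box would leave the image are dropped; the dropped
    count is returned alongside the stack so callers can report it.
    """
    image = np.asarray(image, float)
    if box_size > min(image.shape):
        raise ValueError("box_size larger than image")
    half = box_size // 2
    boxes, kept = [], []
    dropped = 0
    for _, row in coords.iterrows():
        y = int(round(row["y_px"]))
        x = int(round(row["x_px"]))
        y0, x0 = y - half, x - half
        if y0 < 0 or x0 < 0 or y0 + box_size > image.shape[0] or x0 + box_size > image.shape[1]:
            dropped += 1
            continue
        boxes.append(image[y0 : y0 + box_size, x0 : x0 + box_size])
        kept.append((y, x))
    boxes_arr = np.asarray(boxes) if boxes else np.empty((0, box_size, box_size))
    coords_arr = np.asarray(kept, dtype=float) if kept else np.empty((0, 2))
    return ParticleStack(boxes_arr, coords_arr, pixel_size, source_id), dropped


def write_star(path, coords: pd.DataFrame) -> None:
    """Minimal STAR coordinate table (rlnCoordinateX/Y) for interoperability."""
    with open(path, "w") as fh:
        fh.write("\ndata_particles\n\nloop_\n_rlnCoordinateX #1\n_rlnCoordinateY #2\n")
        for _, row in coords.iterrows():
            fh.write(f"{row['x_px']:.2f} {row['y_px']:.2f}\n")
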
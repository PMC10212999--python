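"""ePIE phase retrieval with position initialisation and refinement.

The extended ptychographic iterative engine sweeps the scan positions in a
seeded random order; at each position the exit wave psi = P * O has its
Fourier modulus replaced by the measured one and both object and probe are
updated from the difference:

    O <- O + beta_o * conj(P) / max|P|^2 * (psi' - psi)
    P <- P + beta_p * conj(O) / max|O|^2 * (psi' - psi)

The defocus (hence the initial probe) is treated as prior knowledge; the
probe update is frozen for the first few iterations to avoid early
cross-talk.  Scan positions can be initialised from the data by
cross-correlation of adjacent patterns and refined during the iterations by
a serial cross-correlation step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import lsqr

from ptychospa.core import ObjectWave
from ptychospa.forward4d import FourDDataset, _shift_probe
from ptychospa.probe_scan import ProbeField

__all__ = [
    "EpieConfig",
    "EpieResult",
    "epie_update",
    "epie_run",
    "estimate_positions_xcorr",
    "data_redundancy",
    "complex_correlation",
    "align_global_phase",
]

_EPS = 1e-12


@dataclass
class EpieConfig:
    n_iter: int = 100
    beta_object: float = 1.0
    beta_probe: float = 1.0
    probe_update_start: int = 3  # 1-based iteration at which the probe starts updating
    position_refine: bool = False
    position_refine_start: int = 5
    position_gain: float = 0.5  # damping on each measured correction
    position_cap_px: float = 0.3  # per-iteration correction cap, pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not (0 < self.beta_object <= 1):
            raise ValueError("beta_object must be in (0, 1]")
        if not (0 <= self.beta_probe <= 1):
            raise ValueError("beta_probe must be in [0, 1]")


@dataclass
class EpieResult:
    object: ObjectWave
    probe: ProbeField
    error_trace: np.ndarray
    refined_positions: np.ndarray  # (J, 2) nm, same frame as the input positions
    object_origin: np.ndarray  # (y, x) nm of object pixel (0, 0)
    coverage: np.ndarray  # summed probe power per object pixel

    def scanned_mask(self, rel_threshold: float = 0.1) -> np.ndarray:
        return self.coverage > rel_threshold * self.coverage.max()


def epie_update(
    obj_window: np.ndarray,
    probe: np.ndarray,
    pattern: np.ndarray,
    beta_object: float,
    beta_probe: float,
):
    """Single-position ePIE update on an object window.

    Returns ``(new_window, new_probe, error)`` where ``error`` is the
    normalised Fourier-magnitude error sum(( |Psi| - sqrt(I) )^2) / sum(I).
    A consistent (object, probe, pattern) triple is a fixed point.
    """
    if np.any(pattern < 0):
        raise ValueError("pattern must be non-negative")
    max_p2 = np.max(np.abs(probe) ** 2)
    if max_p2 <= _EPS:
        raise ZeroDivisionError("degenerate (all-zero) probe")
    psi = probe * obj_window
    psi_f = np.fft.fft2(psi, norm="ortho")
    modulus = np.sqrt(pattern)
    abs_f = np.abs(psi_f)
    err = float(np.sum((abs_f - modulus) ** 2) / max(np.sum(pattern), _EPS))
    psi_f_new = modulus * psi_f / (abs_f + _EPS)
    diff = np.fft.ifft2(psi_f_new, norm="ortho") - psi
    new_window = obj_window + beta_object * np.conj(probe) / max_p2 * diff
    if beta_probe > 0:
        max_o2 = np.max(np.abs(obj_window) ** 2)
        new_probe = probe + beta_probe * np.conj(obj_window) / max(max_o2, _EPS) * diff
    else:
        new_probe = probe
    return new_window, new_probe, err


def _xcorr_peak_shift(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Sub-pixel shift of ``a`` relative to ``b`` from the plain
    cross-correlation peak with parabolic interpolation.

    Plain (unwhitened) correlation is deliberate: the diffraction patterns
    are dominated by smooth shadow-image features inside the bright-field
    disc, which phase-correlation whitening suppresses.
    """
    cc = np.fft.ifft2(np.fft.fft2(a) * np.conj(np.fft.fft2(b))).real
    iy, ix = np.unravel_index(np.argmax(cc), cc.shape)
    out = []
    for axis, i in ((0, iy), (1, ix)):
        m = cc.shape[axis]
        if axis == 0:
            cm, c0, cp = cc[(i - 1) % m, ix], cc[iy, ix], cc[(i + 1) % m, ix]
        else:
            cm, c0, cp = cc[iy, (i - 1) % m], cc[iy, ix], cc[iy, (i + 1) % m]
        denom = cm - 2 * c0 + cp
        v = i + (0.5 * (cm - cp) / denom if denom != 0 else 0.0)
        if v > m / 2:
            v -= m
        out.append(v)
    return np.array(out)


def _bright_field_mask(envelope: np.ndarray, erode: int = 3) -> np.ndarray:
    """Interior of the bright-field disc, eroded to exclude its static edge."""
    return binary_erosion(envelope > 0.1 * envelope.max(), iterations=erode)


def _shadow_scale_px_per_nm(probe: ProbeField, n_det: int) -> float:
    """Detector-pixel shift of the in-disc shadow image per nm of probe motion.

    For a strongly defocused probe the far-field pattern at reciprocal pixel
    q displays the specimen at r = p + lambda * defocus * q, so moving the
    probe by delta shifts the shadow by -delta / (lambda * defocus * dq).
    """
    lam_nm = probe.wavelength * 1e-3
    dq = 1.0 / (n_det * probe.pixel_size)
    return -1.0 / (lam_nm * probe.defocus * dq)


def _canvas_geometry(positions: np.ndarray, pixel_size: float, n_probe: int):
    """Object canvas origin (nm) and size covering all probe windows + margin."""
    margin = 2
    lo = positions.min(axis=0)
    hi = positions.max(axis=0)
    origin = lo - (n_probe // 2 + margin) * pixel_size
    extent = hi - origin + (n_probe - n_probe // 2 + margin) * pixel_size
    n_canvas = int(np.ceil(extent.max() / pixel_size)) + 1
    return origin, n_canvas


def _window(position, origin, pixel_size, n_probe, n_canvas):
    rel = (np.asarray(position) - origin) / pixel_size
    iy = int(round(rel[0])) - n_probe // 2
    ix = int(round(rel[1])) - n_probe // 2
    fy = rel[0] - round(rel[0])
    fx = rel[1] - round(rel[1])
    if iy < 0 or ix < 0 or iy + n_probe > n_canvas or ix + n_probe > n_canvas:
        raise ValueError("scan position outside the object canvas")
    return iy, ix, fy, fx


def epie_run(
    data: FourDDataset,
    probe_init: ProbeField,
    config: EpieConfig,
    initial_positions: np.ndarray | None = None,
) -> EpieResult:
    """Run ePIE over the dataset.

    Positions default to the dataset's nominal raster (instrument prior);
    pass :func:`estimate_positions_xcorr` output or the true positions to
    start elsewhere.  The error trace holds the mean normalised
    Fourier-magnitude error per iteration; growth to 10x its running minimum
    aborts with diagnostics.
    """
    n = probe_init.n
    if data.intensities.shape[-1] != n:
        raise ValueError("probe grid does not match detector sampling")
    scale = data.electrons_per_pattern if data.electrons_per_pattern > 0 else 1.0
    patterns = data.intensities / scale
    positions = np.array(
        data.nominal_positions if initial_positions is None else initial_positions,
        dtype=float,
    )
    px = data.pixel_size
    origin, n_canvas = _canvas_geometry(positions, px, n)
    obj = np.ones((n_canvas, n_canvas), dtype=np.complex128)
    probe = probe_init.values.copy()
    moduli = np.sqrt(patterns)
    refine_enabled = config.position_refine
    if refine_enabled and probe_init.defocus == 0:
        warnings.warn("position refinement needs a defocused probe; disabled")
        refine_enabled = False
    if refine_enabled:
        vac = np.abs(np.fft.fft2(probe_init.values, norm="ortho")) ** 2
        bf_mask = _bright_field_mask(vac)
        shadow_scale = _shadow_scale_px_per_nm(probe_init, n)
    rng = np.random.default_rng(config.seed)
    trace = []
    for it in range(1, config.n_iter + 1):
        beta_p = config.beta_probe if it >= config.probe_update_start else 0.0
        refine = refine_enabled and it >= config.position_refine_start
        errs = np.empty(data.n_patterns)
        for j in rng.permutation(data.n_patterns):
            iy, ix, fy, fx = _window(positions[j], origin, px, n, n_canvas)
            p_shifted = _shift_probe(probe, fy, fx)
            window = obj[iy : iy + n, ix : ix + n]
            if refine:
                model = np.abs(np.fft.fft2(p_shifted * window, norm="ortho"))
                a = (moduli[j] - moduli[j][bf_mask].mean()) * bf_mask
                b = (model - model[bf_mask].mean()) * bf_mask
                shift_px = _xcorr_peak_shift(a, b)
                corr_nm = np.clip(
                    config.position_gain * shift_px / shadow_scale,
                    -config.position_cap_px * px,
                    config.position_cap_px * px,
                )
                positions[j] += corr_nm
                iy, ix, fy, fx = _window(positions[j], origin, px, n, n_canvas)
                p_shifted = _shift_probe(probe, fy, fx)
                window = obj[iy : iy + n, ix : ix + n]
            new_window, new_p_shifted, errs[j] = epie_update(
                window, p_shifted, patterns[j], config.beta_object, beta_p
            )
            obj[iy : iy + n, ix : ix + n] = new_window
            if beta_p > 0:
                probe = _shift_probe(new_p_shifted, -fy, -fx)
        trace.append(errs.mean())
        if trace[-1] > 10.0 * min(trace):
            raise RuntimeError(
                f"ePIE diverged at iteration {it}: error {trace[-1]:.3e} "
                f"(minimum so far {min(trace):.3e})"
            )
    # probe-power coverage of the canvas, for masking accuracy metrics
    coverage = np.zeros((n_canvas, n_canvas))
    p2 = np.abs(probe) ** 2
    for j in range(data.n_patterns):
        iy, ix, _, _ = _window(positions[j], origin, px, n, n_canvas)
        coverage[iy : iy + n, ix : ix + n] += p2
    return EpieResult(
        object=ObjectWave(obj, px),
        probe=ProbeField(
            probe, px, probe_init.csa_mrad, probe_init.defocus, probe_init.kv, probe_init.wavelength
        ),
        error_trace=np.asarray(trace),
        refined_positions=positions,
        object_origin=origin,
        coverage=coverage,
    )


def _grid_edges(nominal: np.ndarray, step: float):
    """Adjacent (row/column neighbour) index pairs on the nominal raster."""
    ij = np.round(nominal / step).astype(int)
    lookup = {tuple(v): k for k, v in enumerate(ij)}
    edges = []
    for k, (r, c) in enumerate(ij):
        for dr, dc in ((0, 1), (1, 0)):
            nb = lookup.get((r + dr, c + dc))
            if nb is not None:
                edges.append((k, nb))
    return edges


def estimate_positions_xcorr(data: FourDDataset) -> np.ndarray:
    """Initial probe positions from cross-correlation of adjacent patterns.

    The bright-field disc of a strongly defocused probe carries a shadow
    image of the specimen, so a probe displacement translates the in-disc
    features.  Pairwise sub-pixel shifts between raster neighbours are
    measured by plain cross-correlation of mean-subtracted patterns masked
    to the disc interior (the static disc edge is excluded); a single
    detector-pixel-per-nm scale is fitted against the nominal grid with one
    round of outlier rejection, and positions are recovered by least-squares
    integration of the pairwise differences with the centroid anchored to
    the nominal centroid.  Featureless or inconsistent data fall back to the
    nominal grid with a warning.
    """
    if data.n_patterns < 2:
        raise ValueError("need at least 2 patterns")
    nominal = data.nominal_positions
    edges = _grid_edges(nominal, data.step)
    if not edges:
        warnings.warn("could not infer raster adjacency; returning nominal positions")
        return nominal.copy()
    mean_pat = data.intensities.mean(axis=0)
    mask = _bright_field_mask(mean_pat)
    if mask.mean() < 0.02:
        warnings.warn("no usable bright-field disc; returning nominal positions")
        return nominal.copy()
    centred = (data.intensities - mean_pat) * mask
    shifts = np.array(
        [_xcorr_peak_shift(centred[a], centred[b]) for a, b in edges]
    )
    dnom = np.array([nominal[a] - nominal[b] for a, b in edges])
    good = np.ones(len(edges), dtype=bool)
    scale = 0.0
    for _ in range(2):  # fit scale, reject outlier edges, refit
        scale = np.sum(shifts[good] * dnom[good]) / np.sum(dnom[good] * dnom[good])
        resid = np.linalg.norm(shifts - scale * dnom, axis=1)
        good = resid < 3.0 * max(np.median(resid), 1e-9)
    signal = np.sqrt(np.mean(shifts[good] ** 2))
    if signal < 1e-6 or abs(scale) * data.step < 0.05 or good.mean() < 0.5:
        warnings.warn("featureless or inconsistent patterns; returning nominal positions")
        return nominal.copy()
    # least-squares integration of p_a - p_b = shift / scale over kept edges
    kept = [e for e, g in zip(edges, good) if g]
    n = data.n_patterns
    rows, cols, vals = [], [], []
    rhs = np.empty((len(kept) + 1, 2))
    for k, (a, b) in enumerate(kept):
        rows += [k, k]
        cols += [a, b]
        vals += [1.0, -1.0]
        rhs[k] = shifts[good][k] / scale
    # centroid anchor (pairwise estimates are invariant to a global shift)
    rows += list(np.full(n, len(kept)))
    cols += list(range(n))
    vals += [1.0 / n] * n
    rhs[len(kept)] = nominal.mean(axis=0)
    a_mat = coo_matrix((vals, (rows, cols)), shape=(len(kept) + 1, n)).tocsr()
    est = np.empty_like(nominal)
    for axis in range(2):
        est[:, axis] = lsqr(a_mat, rhs[:, axis])[0]
    return est


def data_redundancy(
    data: FourDDataset, object_pixels: int, probe_pixels: int | None = None
) -> float:
    """Measured intensity values per unknown (dimensionless ratio).

    Unknowns are two real numbers per complex object pixel plus two per
    probe pixel; pass ``probe_pixels=0`` for a known-probe convention.
    """
    if object_pixels <= 0:
        raise ValueError("object_pixels must be positive")
    if probe_pixels is None:
        probe_pixels = data.intensities.shape[-1] * data.intensities.shape[-2]
    measured = data.intensities.size
    return measured / (2.0 * object_pixels + 2.0 * probe_pixels)


def complex_correlation(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """|<a, b>| / (||a|| ||b||) — gauge-invariant complex correlation."""
    if mask is not None:
        a = a[mask]
        b = b[mask]
    num = np.abs(np.vdot(a, b))
    den = np.sqrt(np.vdot(a, a).real * np.vdot(b, b).real)
    return float(num / max(den, _EPS))


def align_global_phase(
    recon: np.ndarray, reference: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Remove the global phase gauge: rotate ``recon`` to best match ``reference``."""
    a, b = (recon[mask], reference[mask]) if mask is not None else (recon, reference)
    phi = np.angle(np.vdot(b, a))
    return recon * np.exp(-1j * phi)
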
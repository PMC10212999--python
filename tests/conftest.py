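"""Shared fixtures: phantoms, probes and simulated 4D datasets.

Heavy simulate-then-reconstruct products are session-scoped so several
tests can interrogate one computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ptychospa.core import Pose
from ptychospa.forward4d import simulate_dataset
from ptychospa.phantom import (
    make_virus_phantom,
    place_projections,
    project_volume,
    projection_to_object_wave,
)
from ptychospa.probe_scan import make_probe, probe_diameter, scan_grid


@pytest.fixture(scope="session")
def virus_phantom():
    """Reference 64^3 phantom at 0.5 nm voxels (shell + 30 bumps)."""
    return make_virus_phantom(64, 0.5, 10.0, 2.0, n_bumps=30, seed=5)


# --- weakly defocused imaging fixture: good for ePIE object recovery ------


@pytest.fixture(scope="session")
def imaging_setup(virus_phantom):
    """Probe/scene/scan tuned for object-wave recovery (overlap ~62%)."""
    px = 0.5
    probe = make_probe(300.0, 1.5, 1300.0, 64, px)
    proj = project_volume(virus_phantom, Pose(Rotation.from_euler("ZYZ", [0.4, 1.0, -0.2])))
    canvas = place_projections([proj], [(64, 64)], 128, px)
    obj = projection_to_object_wave(canvas, 0.6 / proj.values.max(), 0.06 / proj.values.max())
    step = 1.7
    scan = scan_grid(15 * step, step, 0.0, 0)
    offset = 64 * px - 15 * step / 2
    scan.positions = scan.positions + offset
    scan.nominal = scan.nominal + offset
    return obj, probe, scan


@pytest.fixture(scope="session")
def noiseless_dataset(imaging_setup):
    obj, probe, scan = imaging_setup
    return simulate_dataset(obj, probe, scan, electrons_per_pattern=0.0)


# --- strongly defocused (shadow-image) fixture: good for position work ----


@pytest.fixture(scope="session")
def shadow_setup():
    """Micron-defocus probe whose bright-field disc carries a shadow image.

    Five particles on an ice-textured background give cross-correlation
    features everywhere in the 16x16 scan field (overlap ~87%).
    """
    px = 0.8
    probe = make_probe(300.0, 1.0, 20000.0, 64, px)
    step = 0.10 * probe_diameter(300.0, 1.0, 20000.0)
    vol = make_virus_phantom(48, px, 14.0, 3.0, n_bumps=40, seed=5)
    proj = project_volume(vol, Pose(Rotation.from_euler("ZYZ", [0.4, 1.0, -0.2])))
    centres = [(120, 120), (120, 250), (250, 140), (260, 260), (190, 190)]
    canvas = place_projections(
        [proj] * 5, centres, 384, px,
        background_rms=0.15 * proj.values.max(), seed=11,
    )
    obj = projection_to_object_wave(canvas, 2.0 / proj.values.max(), 0.15 / proj.values.max())
    scan = scan_grid(15 * step, step, 0.0, 0)
    offset = 384 * px / 2 - 15 * step / 2
    scan.positions = scan.positions + offset
    scan.nominal = scan.nominal + offset
    return obj, probe, scan, step


@pytest.fixture(scope="session")
def shadow_dataset(shadow_setup):
    obj, probe, scan, _ = shadow_setup
    return simulate_dataset(obj, probe, scan, electrons_per_pattern=0.0)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float).ravel() - np.mean(a)
    b = np.asarray(b, float).ravel() - np.mean(b)
    return float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))
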
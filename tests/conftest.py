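import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import golgiscreen as gs

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def clean_scene() -> gs.SceneBundle:
    """Three-cell, noise-free fixed-cell scene with default dispersion."""
    return gs.generate_cell_scene(3, seed=5)


@pytest.fixture(scope="session")
def clean_segmentation(clean_scene):
    return gs.segment_scene(clean_scene)


def brute_force_pds(xs, ys, cx, cy, n_bins=8):
    """Explicit-loop reference implementation of the polar score.

    Independent of the vectorized path: plain Python floats, manual
    wrapping, manual binning (sectors centred on the zero mean).
    """
    angles = []
    for x, y in zip(xs, ys):
        angles.append(math.atan2(y - cy, x - cx))
    s = c = 0.0
    for a in angles:
        s += math.sin(a)
        c += math.cos(a)
    s /= len(angles)
    c /= len(angles)
    mean = 0.0 if math.hypot(s, c) < 1e-9 else math.atan2(s, c)
    width = 2 * math.pi / n_bins
    counts = [0] * n_bins
    for a in angles:
        shifted = (a - mean + width / 2.0) % (2 * math.pi)
        counts[int(shifted // width)] += 1
    n = sum(counts)
    return sum(abs(k / n - 1.0 / n_bins) for k in counts)


def match_cells_to_truth(cells, truth_cells):
    """Index of the nearest truth cell (by centroid) for each detected cell."""
    out = []
    for c in cells:
        out.append(
            min(
                range(len(truth_cells)),
                key=lambda i: (truth_cells[i].cell_centroid[0] - c.cell_centroid[0]) ** 2
                + (truth_cells[i].cell_centroid[1] - c.cell_centroid[1]) ** 2,
            )
        )
    return out


def truth_angles(scene: gs.SceneBundle, cell_index: int) -> np.ndarray:
    """Ground-truth fragment angles about the truth cell centroid."""
    cell = scene.truth_cells[cell_index]
    pts = scene.truth_fragments[cell_index].centroids
    return np.arctan2(pts[:, 1] - cell.cell_centroid[1], pts[:, 0] - cell.cell_centroid[0])
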
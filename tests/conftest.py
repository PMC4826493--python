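import numpy as np
import pytest
from scipy.spatial.distance import cdist
from shapely.geometry import Polygon

from mitospot import PhantomSpec, detect_cells, render_phantom


def greedy_match(detected: np.ndarray, truth: np.ndarray, tol_um: float = 5.0):
    """One-to-one greedy nearest-centroid matching within tol_um.

    Returns (n_matched, n_detected, n_truth).
    """
    detected = np.asarray(detected, float).reshape(-1, 2)
    truth = np.asarray(truth, float).reshape(-1, 2)
    if len(detected) == 0 or len(truth) == 0:
        return 0, len(detected), len(truth)
    dist = cdist(detected, truth)
    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
    used_d, used_t = set(), set()
    for i, j in order:
        if dist[i, j] > tol_um:
            break
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
    return len(used_t), len(detected), len(truth)


def clean_spec(**overrides) -> PhantomSpec:
    """Phantom spec tuned so truth counts are exactly recoverable (no split
    chromatin beyond the fusion radius, generous nucleus spacing)."""
    base = dict(
        width_um=1000.0,
        height_um=1000.0,
        um_per_px=0.8,
        n_tumor_nuclei=60,
        n_positive=30,
        cluster_fraction=0.6,
        cluster_sd_um=150.0,
        min_distance_um=25.0,
        chromatin_gap_um=(2.0, 4.0),
        noise_sd=0.0,
        seed=11,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def noisefree_phantom():
    spec = clean_spec()
    image, truth = render_phantom(spec)
    cells, tumor = detect_cells(image, spec.lesion())
    return spec, image, truth, cells, tumor


@pytest.fixture(scope="session")
def confounder_phantom():
    spec = clean_spec(
        seed=7,
        n_positive=40,
        n_lymphocytes=6,
        n_pigment=20,
        n_dark_mart1=2,
        pale_mart1_fraction=0.2,
        noise_sd=2.0,
    )
    image, truth = render_phantom(spec)
    cells, tumor = detect_cells(image, spec.lesion())
    return spec, image, truth, cells, tumor


@pytest.fixture(scope="session")
def cohort_phantoms():
    """Small noise-free phantom cohort for agreement statistics."""
    out = []
    for seed, n_pos in [(21, 5), (22, 12), (23, 0), (24, 20)]:
        spec = clean_spec(
            seed=seed, n_positive=n_pos, n_tumor_nuclei=30,
            width_um=700.0, height_um=700.0,
        )
        image, truth = render_phantom(spec)
        cells, tumor = detect_cells(image, spec.lesion())
        out.append((spec, truth, cells, tumor))
    return out


@pytest.fixture
def unit_square_mm() -> Polygon:
    return Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
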
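import warnings

import numpy as np
import pandas as pd
import pytest

from phenonet.synthetic import default_archetypes, sample_frequency_vectors


@pytest.fixture(autouse=True)
def _quiet_model_fits():
    """Tiny-n model fits legitimately warn about convergence; keep logs readable."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning, module="lifelines")
        try:
            from lifelines.exceptions import ConvergenceWarning

            warnings.filterwarnings("ignore", category=ConvergenceWarning)
        except ImportError:
            pass
        yield


@pytest.fixture(scope="session")
def archetypes():
    return default_archetypes()


@pytest.fixture(scope="session")
def planted_vectors(archetypes):
    """100 frequency vectors per archetype at the default concentration."""
    return sample_frequency_vectors(archetypes, 100, concentration=150.0, seed=7)


def brute_force_delaunay_edges(points: np.ndarray) -> set[tuple[int, int]]:
    """Independent Delaunay oracle: an edge (a, b) belongs to the
    triangulation iff some circle through a and b has no other point
    strictly inside.  Checks every circumcircle through a third point
    plus the diametral circle of (a, b)."""
    n = len(points)
    edges = set()
    for a in range(n):
        for b in range(a + 1, n):
            if _has_empty_circle(points, a, b):
                edges.add((a, b))
    return edges


def _circumcircle(p, q, r):
    ax, ay = p
    bx, by = q
    cx, cy = r
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, np.linalg.norm(p - center)


def _has_empty_circle(points, a, b, tol=1e-9):
    n = len(points)
    others = [i for i in range(n) if i not in (a, b)]
    if not others:
        return True
    # diametral circle of (a, b)
    center = (points[a] + points[b]) / 2.0
    radius = np.linalg.norm(points[a] - center)
    if all(np.linalg.norm(points[i] - center) >= radius - tol for i in others):
        return True
    for c in others:
        circ = _circumcircle(points[a], points[b], points[c])
        if circ is None:
            continue
        center, radius = circ
        inside = [
            i
            for i in others
            if i != c and np.linalg.norm(points[i] - center) < radius - tol
        ]
        if not inside:
            return True
    return False


@pytest.fixture(scope="session")
def delaunay_oracle():
    return brute_force_delaunay_edges


def make_cells(coords, types, case_id="case"):
    return pd.DataFrame(
        {
            "case_id": case_id,
            "x_um": [c[0] for c in coords],
            "y_um": [c[1] for c in coords],
            "cell_type": list(types),
        }
    )
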
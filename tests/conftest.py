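"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own algorithms: peers are found
by an O(n^2) pairwise dominance scan, and the ceiling zone by column-wise
numerical integration of the empty-space indicator over the scope rectangle.
"""

import numpy as np
import pytest

from ncarigor import BivariateSample


def peers_bruteforce(x, y):
    """All points not weakly dominated toward the upper-left, O(n^2)."""
    pts = sorted(set(zip(x.tolist(), y.tolist())))
    keep = []
    for xi, yi in pts:
        dominated = any(
            (xj <= xi and yj >= yi) and (xj < xi or yj > yi) for xj, yj in pts
        )
        if not dominated:
            keep.append((xi, yi))
    return np.array(sorted(keep))


def ceiling_zone_grid(x, y, m=20000):
    """Column-wise integration of the area above the step ceiling.

    For each of ``m`` x-midpoints the ceiling is recomputed by brute force as
    max{y_i : x_i <= x}; the error is bounded by the columns containing a
    jump, at most n * (x_range/m) * y_range.
    """
    x_min, x_max = x.min(), x.max()
    y_max = y.max()
    edges = np.linspace(x_min, x_max, m + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    dx = (x_max - x_min) / m
    mask = x[None, :] <= mids[:, None]
    ceil = np.where(mask, y[None, :], -np.inf).max(axis=1)
    return float(np.sum((y_max - ceil) * dx))


def random_sample(rng, n_max=50):
    """A random sample with positive scope (continuous, so almost surely)."""
    n = rng.integers(3, n_max + 1)
    x = rng.uniform(-5, 5, n)
    y = rng.uniform(-5, 5, n)
    return BivariateSample(x, y)


@pytest.fixture
def toy_csv(tmp_path):
    """The four-point worked example as a CSV table."""
    path = tmp_path / "toy.csv"
    path.write_text("X,Y\n1,1\n2,3\n3,2\n4,4\n")
    return path
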
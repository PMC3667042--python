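"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library code paths they check:
flood-fill labeling instead of scipy.ndimage, all-pairs Python loops instead
of vectorized distance code, power iteration instead of dense eigensolvers,
and a numeric recurrence that constructs patch areas whose cumulative curve
lies exactly on a power law.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from fragcap.landscape import HabitatGrid, PatchSet


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def flood_fill_label(mask: np.ndarray, connectivity: int) -> list[frozenset[tuple[int, int]]]:
    """Connected components of a binary mask by explicit-stack flood fill.

    Returns the partition as a list of cell-sets (unordered), independent of
    any labeling convention.
    """
    nrows, ncols = mask.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for r0 in range(nrows):
        for c0 in range(ncols):
            if mask[r0, c0] and not seen[r0, c0]:
                stack = [(r0, c0)]
                seen[r0, c0] = True
                comp = []
                while stack:
                    r, c = stack.pop()
                    comp.append((r, c))
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < nrows and 0 <= cc < ncols and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
                components.append(frozenset(comp))
    return components


def brute_force_min_distances(patches: PatchSet) -> np.ndarray:
    """All-pairs minimum boundary-cell distance by plain Python loops."""
    n = patches.n_patches
    s = patches.source_cell_size_km
    out = np.zeros((n, n))
    for i in range(n):
        bi = patches.boundary_cells[i]
        for j in range(i + 1, n):
            bj = patches.boundary_cells[j]
            best = math.inf
            for (ri, ci) in bi:
                for (rj, cj) in bj:
                    d = math.hypot((ri - rj) * s, (ci - cj) * s)
                    if d < best:
                        best = d
            out[i, j] = out[j, i] = best
    return out


def power_iteration(M: np.ndarray, n_steps: int = 10_000) -> tuple[float, np.ndarray]:
    """Leading eigenpair of a nonnegative matrix by plain power iteration."""
    n = M.shape[0]
    v = np.full(n, 1.0 / n)
    lam = 0.0
    for _ in range(n_steps):
        w = M @ v
        lam = np.linalg.norm(w)
        if lam == 0:
            return 0.0, v
        v = w / lam
    return float(lam), v / v.sum()


def power_law_areas(slope: float = 0.7, n_points: int = 8, multiplicity: int = 10) -> list[float]:
    """Patch areas whose merged cumulative curve lies exactly on a power law.

    ``multiplicity`` unit-area patches pin the first merged point at
    (1, multiplicity), fixing the prefactor C = multiplicity; every further
    single patch of area a_k must satisfy C*(a_k**slope - a_{k-1}**slope) =
    a_k, solved by bisection on the increasing branch.  Valid merged points
    exist only while the target stays below the branch maximum, which bounds
    n_points for a given multiplicity.
    """
    C = float(multiplicity)
    areas = [1.0] * multiplicity
    prev = 1.0
    a_max = (slope * C) ** (1.0 / (1.0 - slope))  # maximum of C*a^s - a
    for _ in range(n_points - 1):
        h = lambda a: C * a**slope - a - C * prev**slope
        if h(a_max) <= 0:
            raise ValueError("power-law construction infeasible; lower n_points")
        prev = brentq(h, prev * (1 + 1e-12), a_max, xtol=1e-14, rtol=1e-15)
        areas.append(prev)
    return areas


# ---------------------------------------------------------------------------
# Landscape fixtures
# ---------------------------------------------------------------------------


def random_grid(seed: int, shape=(50, 50), p: float = 0.4, cell_size_km: float = 1.0) -> HabitatGrid:
    """Bernoulli habitat grid; deterministic under seed."""
    rng = np.random.default_rng(seed)
    return HabitatGrid(cells=(rng.random(shape) < p).astype(np.uint8), cell_size_km=cell_size_km)


def random_patch_config(seed: int, n_max: int = 12) -> tuple[np.ndarray, np.ndarray]:
    """Random (areas, distance matrix) pair from scattered patch centers.

    Areas are log-normal; distances are Euclidean between random planar
    points, hence a valid symmetric zero-diagonal matrix.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    areas = np.exp(rng.normal(1.0, 1.2, n))
    pts = rng.uniform(0, 50, (n, 2))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return areas, d


@pytest.fixture
def small_grid() -> HabitatGrid:
    """Hand-countable 3x3 grid with two 2-cell patches."""
    return HabitatGrid(cells=np.array([[1, 1, 0], [0, 0, 0], [0, 1, 1]]), cell_size_km=1.0)
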
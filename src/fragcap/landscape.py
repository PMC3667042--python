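"""Habitat rasters, patch extraction and inter-patch distances.

This module turns a binary habitat map (1 = habitat, 0 = matrix) into the
objects the capacity calculation needs: a set of labeled habitat patches with
areas in km², and the symmetric matrix of minimum edge-to-edge distances
between patches.

Conventions
-----------
* Grids are indexed ``(row, col)``, row-major, 0-based; cell ``(0, 0)`` is the
  top-left cell of the raster, per common raster practice.
* Distances are planar Euclidean in projected km, measured between the
  *centers* of boundary cells.  A boundary cell is a habitat cell with at
  least one non-habitat (or off-grid) neighbor under the labeling
  connectivity.
* Patch ids are consecutive integers ``1..n`` assigned in decreasing area
  order; ties are broken by the smallest row-major index of the patch's first
  cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

__all__ = [
    "HabitatGrid",
    "PatchSet",
    "DistanceMatrix",
    "read_habitat_grid",
    "read_ascii_grid",
    "write_ascii_grid",
    "label_patches",
    "filter_patches",
    "min_edge_distances",
    "patch_table",
    "write_labeled_tiff",
    "write_distance_csv",
]

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclass(frozen=True)
class HabitatGrid:
    """Binary habitat lattice with georeferencing metadata.

    Parameters
    ----------
    cells
        2-D array of 0/1; 1 marks habitat.
    cell_size_km
        Edge length of one square cell in km (area of one cell is
        ``cell_size_km ** 2``).
    origin
        ``(x, y)`` of the lower-left grid corner in projected km.
    crs_note
        Free-text note on the coordinate reference of the source raster.
    """

    cells: np.ndarray
    cell_size_km: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_note: str = ""

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells)
        if cells.ndim != 2 or cells.size == 0:
            raise ValueError("habitat grid must be a non-empty 2-D lattice")
        if not np.isin(cells, (0, 1)).all():
            raise ValueError("habitat grid cells must all be 0 or 1")
        if not self.cell_size_km > 0:
            raise ValueError("cell_size_km must be positive")
        object.__setattr__(self, "cells", cells.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    @property
    def habitat_cells(self) -> int:
        return int(self.cells.sum())

    @property
    def habitat_area_km2(self) -> float:
        return self.habitat_cells * self.cell_size_km**2


@dataclass(frozen=True)
class PatchSet:
    """Labeled habitat patches extracted from one grid.

    ``labels`` holds the full label image (0 = matrix, ids ``1..n``);
    ``boundary_cells[i]`` is an ``(m, 2)`` array of (row, col) boundary cells
    of patch ``i + 1``.
    """

    labels: np.ndarray
    patch_ids: np.ndarray
    areas_km2: np.ndarray
    boundary_cells: tuple[np.ndarray, ...]
    connectivity: int
    source_cell_size_km: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if (np.asarray(self.areas_km2) <= 0).any():
            raise ValueError("patch areas must be positive")

    @property
    def n_patches(self) -> int:
        return len(self.patch_ids)

    @property
    def total_area_km2(self) -> float:
        return float(np.sum(self.areas_km2))

    @property
    def largest_patch_km2(self) -> float:
        return float(self.areas_km2[0]) if self.n_patches else 0.0

    def to_mask(self) -> np.ndarray:
        """Reconstruct the binary habitat mask this PatchSet was built from."""
        return (self.labels > 0).astype(np.uint8)

    def patch_cells(self, patch_id: int) -> np.ndarray:
        """(row, col) cells of one patch, row-major order."""
        return np.argwhere(self.labels == patch_id)

    def centroids_km(self) -> np.ndarray:
        """Per-patch centroid ``(x, y)`` in projected km (y up from origin)."""
        nrows = self.labels.shape[0]
        s, (x0, y0) = self.source_cell_size_km, self.origin
        out = np.empty((self.n_patches, 2))
        for k, pid in enumerate(self.patch_ids):
            rc = self.patch_cells(int(pid))
            out[k, 0] = x0 + (rc[:, 1].mean() + 0.5) * s
            out[k, 1] = y0 + (nrows - rc[:, 0].mean() - 0.5) * s
        return out


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric minimum edge-to-edge distances between patches, km."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if v.size and (np.diag(v) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if v.size and (v[~np.eye(len(v), dtype=bool)] <= 0).any():
            raise ValueError("off-diagonal distances must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# Raster ingestion
# ---------------------------------------------------------------------------


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, tuple[float, float], float | None]:
    """Parse an ESRI ASCII grid; returns (data, cellsize, (xll, yll), nodata)."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"ASCII grid {path} missing required header key {req!r}")
    data = np.array(rows, dtype=float)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"ASCII grid {path}: data shape {data.shape} disagrees with header")
    origin = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0))
    return data, header["cellsize"], origin, header.get("nodata_value")


def write_ascii_grid(grid: HabitatGrid, path: str | Path) -> None:
    """Write a HabitatGrid as an ESRI ASCII grid (cellsize in km)."""
    nrows, ncols = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]}\n")
        fh.write(f"yllcorner {grid.origin[1]}\n")
        fh.write(f"cellsize {grid.cell_size_km}\n")
        for row in grid.cells:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_habitat_grid(
    source,
    habitat_values=(1,),
    *,
    cell_size_km: float | None = None,
    origin: tuple[float, float] | None = None,
    crs_note: str = "",
) -> HabitatGrid:
    """Read a habitat map from a raster file or an in-memory lattice.

    Cells whose value is in ``habitat_values`` become 1; everything else,
    including no-data, becomes 0 (no-data is treated as non-habitat, which is
    conservative for connectivity).

    Parameters
    ----------
    source
        Path to a single-band raster (``.asc`` ESRI ASCII grid, or
        ``.tif``/``.tiff`` read via :mod:`tifffile`), or an array-like lattice.
    habitat_values
        Raster values coded as habitat.
    cell_size_km
        Cell edge length; required for TIFF and in-memory sources, optional
        override for ASCII grids (whose header carries ``cellsize``).
    """
    habitat_values = set(habitat_values)
    file_origin: tuple[float, float] | None = None
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(path)
        suffix = path.suffix.lower()
        if suffix in (".asc", ".txt", ".grd"):
            data, cellsize, file_origin, nodata = read_ascii_grid(path)
            if nodata is not None:
                habitat_values.discard(nodata)
            if cell_size_km is None:
                cell_size_km = cellsize
        elif suffix in (".tif", ".tiff"):
            import tifffile

            data = np.asarray(tifffile.imread(path))
            if cell_size_km is None:
                raise ValueError(
                    "cell_size_km must be given explicitly for TIFF sources"
                )
        else:
            raise ValueError(f"unsupported raster format: {path.suffix!r}")
    else:
        data = np.asarray(source)
        if cell_size_km is None:
            cell_size_km = 1.0
    if data.ndim != 2:
        raise ValueError("raster must be single-band (2-D)")
    if data.size == 0:
        raise ValueError("raster is empty")
    cells = np.isin(data, list(habitat_values)).astype(np.uint8)
    return HabitatGrid(
        cells=cells,
        cell_size_km=float(cell_size_km),
        origin=origin if origin is not None else (file_origin or (0.0, 0.0)),
        crs_note=crs_note,
    )


# ---------------------------------------------------------------------------
# Patch labeling
# ---------------------------------------------------------------------------


def label_patches(grid: HabitatGrid, connectivity: int = 8) -> PatchSet:
    """Extract maximal connected habitat patches.

    Patch areas equal component cell count times the cell area.  Ids are
    assigned in decreasing area order (row-major first-cell tie-break), so
    ``areas_km2`` is sorted descending.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCTURES[connectivity]
    mask = grid.cells.astype(bool)
    raw, n_raw = ndimage.label(mask, structure=structure)

    if n_raw == 0:
        return PatchSet(
            labels=np.zeros(grid.shape, dtype=np.int32),
            patch_ids=np.empty(0, dtype=int),
            areas_km2=np.empty(0),
            boundary_cells=(),
            connectivity=connectivity,
            source_cell_size_km=grid.cell_size_km,
            origin=grid.origin,
        )

    flat = raw.ravel()
    counts = np.bincount(flat, minlength=n_raw + 1)
    uniq, first_idx = np.unique(flat, return_index=True)
    first = np.full(n_raw + 1, flat.size, dtype=np.int64)
    first[uniq] = first_idx
    order = sorted(range(1, n_raw + 1), key=lambda l: (-counts[l], first[l]))

    remap = np.zeros(n_raw + 1, dtype=np.int32)
    for new_id, old in enumerate(order, start=1):
        remap[old] = new_id
    labels = remap[raw]

    cell_area = grid.cell_size_km**2
    areas = counts[order] * cell_area

    # boundary: habitat cell with >=1 non-habitat/off-grid neighbor under the
    # labeling connectivity (erosion border_value=0 makes off-grid non-habitat)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    boundary_mask = mask & ~eroded
    boundary = tuple(
        np.argwhere(boundary_mask & (labels == pid)) for pid in range(1, n_raw + 1)
    )

    return PatchSet(
        labels=labels,
        patch_ids=np.arange(1, n_raw + 1),
        areas_km2=areas.astype(float),
        boundary_cells=boundary,
        connectivity=connectivity,
        source_cell_size_km=grid.cell_size_km,
        origin=grid.origin,
    )


def filter_patches(patches: PatchSet, min_area_km2: float) -> PatchSet:
    """Drop patches smaller than ``min_area_km2`` (strict), renumbering ids.

    Motivated by fragment-viability recommendations of a minimum fragment
    size; no filter is applied by default anywhere in the package.
    """
    keep = np.flatnonzero(patches.areas_km2 >= min_area_km2)
    remap = np.zeros(patches.n_patches + 1, dtype=np.int32)
    for new_id, k in enumerate(keep, start=1):
        remap[patches.patch_ids[k]] = new_id
    return PatchSet(
        labels=remap[patches.labels],
        patch_ids=np.arange(1, len(keep) + 1),
        areas_km2=patches.areas_km2[keep],
        boundary_cells=tuple(patches.boundary_cells[k] for k in keep),
        connectivity=patches.connectivity,
        source_cell_size_km=patches.source_cell_size_km,
        origin=patches.origin,
    )


# ---------------------------------------------------------------------------
# Inter-patch distances
# ---------------------------------------------------------------------------

_KDTREE_CUTOFF = 40_000  # boundary-pair count above which a k-d tree is used


def min_edge_distances(patches: PatchSet) -> DistanceMatrix:
    """Minimum edge-to-edge distance between every patch pair, in km.

    The distance between patches i and j is the minimum Euclidean distance
    between centers of their boundary cells; the diagonal is zero by
    definition (self-distance, supporting self-colonization).  Small pairs use
    a direct distance matrix; large ones a k-d tree — both are exact and agree
    with the all-pairs brute force.
    """
    n = patches.n_patches
    if n < 1:
        raise ValueError("need at least one patch")
    s = patches.source_cell_size_km
    points = [b.astype(float) * s for b in patches.boundary_cells]
    trees: dict[int, cKDTree] = {}
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = points[i], points[j]
            if pi.shape[0] * pj.shape[0] <= _KDTREE_CUTOFF:
                d = cdist(pi, pj).min()
            else:
                small, large = (pi, pj) if pi.shape[0] <= pj.shape[0] else (pj, pi)
                if id(large) not in trees:
                    trees[id(large)] = cKDTree(large)
                d = trees[id(large)].query(small)[0].min()
            values[i, j] = values[j, i] = d
    return DistanceMatrix(values=values)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def patch_table(patches: PatchSet) -> pd.DataFrame:
    """Patch summary table: id, area, cell count, centroid coordinates."""
    cell_area = patches.source_cell_size_km**2
    cents = patches.centroids_km() if patches.n_patches else np.empty((0, 2))
    return pd.DataFrame(
        {
            "patch_id": patches.patch_ids,
            "area_km2": patches.areas_km2,
            "n_cells": (patches.areas_km2 / cell_area).round().astype(int),
            "centroid_x_km": cents[:, 0],
            "centroid_y_km": cents[:, 1],
        }
    )


def write_labeled_tiff(patches: PatchSet, path: str | Path) -> None:
    """Write the patch label image as a single-band int32 TIFF."""
    import tifffile

    tifffile.imwrite(path, patches.labels.astype(np.int32))


def write_distance_csv(dists: DistanceMatrix, patches: PatchSet, path: str | Path) -> None:
    """Square distance-matrix CSV with patch ids as header row/column."""
    ids = patches.patch_ids
    pd.DataFrame(dists.values, index=ids, columns=ids).to_csv(path, index_label="patch_id")
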
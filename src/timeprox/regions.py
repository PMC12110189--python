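"""Tumor/stroma delineation from pan-CK+ cell aggregation.

Tissue is partitioned on a regular grid: a Gaussian kernel density of
pan-CK+ centroids is thresholded at a fraction of its peak, small
components are dropped and enclosed holes filled, giving the tumor
parenchyma mask; the tissue mask is the same fractional rule applied to
the density of *all* cells.  A cell is "tumor" iff the grid cell holding
its centroid (half-open cells, [x, x+step)) is in the tumor mask.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .config import RegionParams
from .io import CellTable

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


@dataclass
class RegionPartition:
    """Per-cell tumor/stroma labels, region masks and areas for one slide."""

    cell_is_tumor: np.ndarray       # bool per cell, row order of the table
    tumor_mask: np.ndarray          # grid bool, shape (nx, ny)
    tissue_mask: np.ndarray
    origin: tuple[float, float]     # μm coordinates of grid cell (0, 0)
    grid_step_um: float

    @property
    def cell_labels(self) -> np.ndarray:
        return np.where(self.cell_is_tumor, "tumor", "stroma")

    @property
    def tumor_area_mm2(self) -> float:
        return float(self.tumor_mask.sum()) * self.grid_step_um ** 2 / 1e6

    @property
    def stroma_area_mm2(self) -> float:
        return float((self.tissue_mask & ~self.tumor_mask).sum()) * self.grid_step_um ** 2 / 1e6

    @property
    def tissue_area_mm2(self) -> float:
        return float(self.tissue_mask.sum()) * self.grid_step_um ** 2 / 1e6

    def tumor_polygons(self):
        """Tumor mask as a shapely (multi)polygon in μm coordinates."""
        step = self.grid_step_um
        x0, y0 = self.origin
        ii, jj = np.nonzero(self.tumor_mask)
        cells = [box(x0 + i * step, y0 + j * step,
                     x0 + (i + 1) * step, y0 + (j + 1) * step)
                 for i, j in zip(ii, jj)]
        return unary_union(cells) if cells else None

    def to_geojson(self, path: str | Path) -> None:
        poly = self.tumor_polygons()
        feature = {
            "type": "Feature",
            "properties": {"region": "tumor", "units": "um",
                           "tumor_area_mm2": self.tumor_area_mm2},
            "geometry": mapping(poly) if poly is not None else None,
        }
        Path(path).write_text(json.dumps(
            {"type": "FeatureCollection", "features": [feature]}))


def _density_mask(counts: np.ndarray, sigma_cells: float, fraction: float) -> np.ndarray:
    density = ndimage.gaussian_filter(counts.astype(float), sigma=sigma_cells,
                                      mode="constant")
    peak = density.max()
    if peak <= 0:
        return np.zeros_like(counts, dtype=bool)
    return density >= fraction * peak


def delineate_regions(table: CellTable, ck_flags: np.ndarray,
                      params: RegionParams) -> RegionPartition:
    """Partition one slide into tumor parenchyma and stroma.

    ``ck_flags`` is the pan-CK positivity vector from the gating step.  The
    procedure is deterministic given ``params`` and scale-equivariant: scaling
    coordinates, grid step and bandwidth together leaves labels unchanged.
    """
    xy = table.coords()
    if len(xy) == 0:
        raise ValueError("delineate_regions requires at least one cell")
    ck_flags = np.asarray(ck_flags, dtype=bool)
    step = params.grid_step_um
    bw = params.kde_bandwidth_um

    pad = bw
    x0 = xy[:, 0].min() - pad
    y0 = xy[:, 1].min() - pad
    nx = int(np.floor((xy[:, 0].max() + pad - x0) / step)) + 1
    ny = int(np.floor((xy[:, 1].max() + pad - y0) / step)) + 1
    ix = np.floor((xy[:, 0] - x0) / step).astype(int)
    iy = np.floor((xy[:, 1] - y0) / step).astype(int)

    def bincount(mask):
        counts = np.zeros((nx, ny))
        np.add.at(counts, (ix[mask], iy[mask]), 1.0)
        return counts

    sigma = bw / step
    if not ck_flags.any():
        warnings.warn("no pan-CK+ cells: tumor area 0, all cells labeled stroma")
        tumor = np.zeros((nx, ny), dtype=bool)
    else:
        tumor = _density_mask(bincount(ck_flags), sigma, params.threshold_fraction)
        # drop fragments below the minimum region area, then fill enclosed holes
        lab, nlab = ndimage.label(tumor, structure=_FOUR_CONNECTED)
        if nlab:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nlab + 1))
            keep = np.flatnonzero(sizes * step ** 2 >= params.min_region_area_um2) + 1
            tumor = np.isin(lab, keep)
        tumor = ndimage.binary_fill_holes(tumor, structure=_FOUR_CONNECTED)

    tissue = _density_mask(bincount(np.ones(len(xy), dtype=bool)), sigma,
                           params.threshold_fraction)
    tissue |= tumor  # tumor parenchyma is tissue by definition; keeps areas additive

    cell_is_tumor = tumor[ix, iy]
    return RegionPartition(cell_is_tumor=cell_is_tumor, tumor_mask=tumor,
                           tissue_mask=tissue, origin=(x0, y0), grid_step_um=step)


def region_areas(partition: RegionPartition) -> tuple[float, float, float]:
    """(tumor, stroma, tissue) areas in mm²; additive by construction."""
    return (partition.tumor_area_mm2, partition.stroma_area_mm2,
            partition.tissue_area_mm2)
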
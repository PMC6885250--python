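"""Cortical-complexity metrics under the search surface: lGI and fractal dimension.

The local gyrification index (lGI) compares the full pial surface —
including cortex buried in sulci — with a smoothed outer hull that only
sees the visible envelope: lGI = pial area / hull area, so an unfolded
cortex scores 1 and folding pushes it up.  The hull is obtained by
morphological closing of the brain mask with a 15 mm spherical element, a
deterministic stand-in for interactive smoothed-surface tracing.

The fractal dimension (FD) of the cortical mask is estimated by box
counting on aligned grids: each scale ``s`` partitions the volume into
s-voxel cubes, ``count(s)`` is the number of cubes intersecting the mask,
and

    FD = - d log2(count) / d log2(size)

is the negated least-squares slope over the scales (sizes 1, 2, 4, 8, 16
by default).  A filled solid scores ~3, a sheet ~2, a line ~1.

Both metrics are evaluated on the tissue under the 4 x 4 cm^2 coil search
surface: voxels (or mesh faces) whose tangent-plane coordinates relative
to the patch center stay within the patch half-extent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .model_io import VoxelModel, _mesh_from_mask
from .coil import tangent_reference

logger = logging.getLogger("tmscoilopt")

BRAIN_TISSUES = {"Grey matter", "White matter", "Cerebellum", "Hippocampus",
                 "Thalamus", "Midbrain", "Pons"}
CORTEX_TISSUES = {"Grey matter"}

HULL_CLOSING_RADIUS_MM = 15.0
DEFAULT_BOX_SIZES = (1, 2, 4, 8, 16)


@dataclass
class PatchRegion:
    """The column under the square search surface."""

    center: np.ndarray               # world mm (patch center on the surface)
    normal: np.ndarray               # outward normal of the search surface
    half_extent_mm: float = 20.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        self.normal /= np.linalg.norm(self.normal)
        self.e1 = tangent_reference(self.normal)
        self.e2 = np.cross(self.normal, self.e1)

    def contains(self, points: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(points) - self.center
        u = rel @ self.e1
        v = rel @ self.e2
        return (np.abs(u) <= self.half_extent_mm) & \
               (np.abs(v) <= self.half_extent_mm)


@dataclass
class CortexMetrics:
    lgi: float
    fd: float
    fd_r_squared: float
    fd_counts: dict[int, int]


def _tissue_mask(model: VoxelModel, tissues: set[str]) -> np.ndarray:
    ids = [k for k, v in model.label_names.items() if v in tissues]
    return np.isin(model.labels, ids)


def _close_mask(mask: np.ndarray, radius_mm: float, spacing: float) -> np.ndarray:
    """Morphological closing via two Euclidean distance transforms."""
    r = radius_mm
    dilated = ndimage.distance_transform_edt(~mask, sampling=spacing) <= r
    return ndimage.distance_transform_edt(dilated, sampling=spacing) > r


def _patch_area(mesh, region: PatchRegion) -> float:
    inside = region.contains(mesh.triangles_center)
    return float(mesh.area_faces[inside].sum())


def local_gyrification_index(model: VoxelModel, region: PatchRegion,
                             closing_radius_mm: float = HULL_CLOSING_RADIUS_MM
                             ) -> float:
    """Pial-over-hull surface-area ratio within the patch."""
    if not _tissue_mask(model, CORTEX_TISSUES).any():
        raise ValueError("no grey matter in the model")
    brain = _tissue_mask(model, BRAIN_TISSUES)
    pial = _mesh_from_mask(brain, model.spacing, model.origin)
    hull_mask = _close_mask(brain, closing_radius_mm, model.spacing)
    hull = _mesh_from_mask(hull_mask, model.spacing, model.origin)
    a_pial = _patch_area(pial, region)
    a_hull = _patch_area(hull, region)
    if a_hull <= 0:
        raise ValueError("patch does not intersect the brain hull")
    return a_pial / a_hull


def box_counts(mask: np.ndarray, sizes=DEFAULT_BOX_SIZES) -> dict[int, int]:
    """Number of aligned size^3 cubes intersecting the mask, per size."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    # crop to the bounding box so aligned cubes track the structure
    nz = np.nonzero(mask)
    lo = [int(a.min()) for a in nz]
    hi = [int(a.max()) + 1 for a in nz]
    mask = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    counts: dict[int, int] = {}
    for s in sizes:
        if s > max(mask.shape):
            warnings.warn(f"box size {s} exceeds the mask extent; dropped")
            continue
        pad = [(0, (-d) % s) for d in mask.shape]
        m = np.pad(mask, pad)
        view = m.reshape(m.shape[0] // s, s, m.shape[1] // s, s,
                         m.shape[2] // s, s)
        counts[s] = int(view.any(axis=(1, 3, 5)).sum())
    return counts


def fractal_dimension(mask: np.ndarray, sizes=DEFAULT_BOX_SIZES
                      ) -> tuple[float, float, dict[int, int]]:
    """Box-counting dimension: negated OLS slope of log2 count vs log2 size.

    Returns ``(fd, r_squared, counts)``.
    """
    counts = box_counts(mask, sizes)
    if len(counts) < 2:
        raise ValueError("need at least two usable box sizes")
    x = np.log2(np.array(list(counts.keys()), dtype=float))
    y = np.log2(np.array(list(counts.values()), dtype=float))
    slope, _icpt, r, _p, _se = stats.linregress(x, y)
    return float(-slope), float(r ** 2), counts


def patch_cortex_mask(model: VoxelModel, region: PatchRegion) -> np.ndarray:
    """Grey-matter voxels inside the patch column (native grid)."""
    cortex = _tissue_mask(model, CORTEX_TISSUES)
    idx = np.argwhere(cortex)
    centers = model.index_to_world(idx)
    keep = region.contains(centers)
    out = np.zeros_like(cortex)
    out[tuple(idx[keep].T)] = True
    return out


FD_RASTER_PITCH_MM = 1.0


def pial_surface_mask(model: VoxelModel, region: PatchRegion,
                      pitch_mm: float = FD_RASTER_PITCH_MM) -> np.ndarray:
    """The extracted pial surface under the patch, rasterized for box counting.

    The marching-cubes pial surface has sub-voxel accuracy, so rasterizing
    it at a fixed 1 mm pitch yields an FD estimate that does not degrade
    with the label grid's spacing (coarser phantoms would otherwise smear
    the folding below the smallest box size).
    """
    brain = _tissue_mask(model, BRAIN_TISSUES)
    pial = _mesh_from_mask(brain, model.spacing, model.origin)
    keep = np.flatnonzero(region.contains(pial.triangles_center))
    if keep.size == 0:
        raise ValueError("patch does not intersect the pial surface")
    sub = pial.submesh([keep], append=True)
    return np.asarray(sub.voxelized(pitch=pitch_mm).matrix, dtype=bool)


def cortex_metrics(model: VoxelModel, region: PatchRegion,
                   sizes=DEFAULT_BOX_SIZES) -> CortexMetrics:
    """lGI and FD of the cortical surface under the search surface."""
    lgi = local_gyrification_index(model, region)
    fd, r2, counts = fractal_dimension(pial_surface_mask(model, region), sizes)
    return CortexMetrics(lgi=lgi, fd=fd, fd_r_squared=r2, fd_counts=counts)


def correlate_metrics(records: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlations of complexity metrics vs run outcomes.

    ``records`` needs columns ``lgi``, ``fd``, ``mean_enhancement_pct``,
    ``mean_iterations`` (one row per head model).  Returns one row per
    metric/outcome pair with Spearman r and p; a constant column yields an
    undefined correlation, reported as NaN.
    """
    required = {"lgi", "fd", "mean_enhancement_pct", "mean_iterations"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    if len(records) < 4:
        raise ValueError("need at least 4 records for a rank correlation")
    rows = []
    for metric in ("lgi", "fd"):
        for outcome in ("mean_enhancement_pct", "mean_iterations"):
            x = records[metric].to_numpy(dtype=float)
            y = records[outcome].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                r, p = float("nan"), float("nan")
                logger.warning("constant column in %s vs %s; correlation "
                               "undefined", metric, outcome)
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r, p = stats.spearmanr(x, y)
            rows.append({"metric": metric, "outcome": outcome,
                         "spearman_r": r, "p_value": p})
    return pd.DataFrame(rows)
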
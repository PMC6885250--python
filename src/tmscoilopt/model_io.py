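"""Voxel head models, conductivity mapping, and scalp/offset surfaces.

A head model is a 3-D grid of integer tissue labels on an isotropic lattice.
The world-coordinate convention used throughout the package is: the
bottom-center of the model sits at the origin and the long axis of the head
points along +Z.  A voxel with index ``(i, j, k)`` occupies the half-open box
``[origin + i*s, origin + (i+1)*s)`` per axis; fields are sampled at voxel
centers.

Tissue labels map to low-frequency conductivities through a table shipped
with the package (``data/conductivity.csv``); label 0 is external air and is
always non-conducting.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

logger = logging.getLogger("tmscoilopt")

EXTERNAL_AIR = 0


class ModelFormatError(ValueError):
    """Raised for malformed or unsupported voxel-model files."""


class UnknownTissueError(KeyError):
    """Raised when a label has no entry in the conductivity table."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VoxelModel:
    """Integer tissue-label grid with world-coordinate metadata.

    Parameters
    ----------
    labels
        3-D integer array of tissue IDs; 0 marks external (non-conducting)
        air.
    spacing
        Isotropic voxel edge length in mm.
    origin
        World position (mm) of the grid corner of voxel (0, 0, 0).
    label_names
        Mapping from label ID to tissue name; every nonzero label that
        occurs in ``labels`` must be present.
    """

    labels: np.ndarray
    spacing: float
    origin: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ModelFormatError("labels must be a 3-D array")
        if not self.spacing > 0:
            raise ModelFormatError("spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        n = self.labels.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world points (mm) to (fractional) voxel indices."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing - 0.5

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map voxel indices to the world coordinates of voxel centers."""
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.spacing


def default_origin(shape: tuple[int, int, int], spacing: float) -> np.ndarray:
    """Origin for the bottom-center world convention.

    The X/Y extent is centered on zero and the bottom (z = 0) plane
    coincides with the lower face of the first voxel slab.
    """
    nx, ny, _ = shape
    return np.array([-nx * spacing / 2.0, -ny * spacing / 2.0, 0.0])


@dataclass
class ConductivityTable:
    """Tissue name -> (conductivity S/m, density g/cm^3)."""

    entries: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (sigma, _dens) in self.entries.items():
            if sigma < 0:
                raise ValueError(f"negative conductivity for {name!r}")

    def conductivity(self, tissue: str) -> float:
        try:
            return self.entries[tissue][0]
        except KeyError:
            raise UnknownTissueError(
                f"tissue {tissue!r} not in conductivity table"
            ) from None

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConductivityTable":
        df = pd.read_csv(path)
        entries = {
            str(r.tissue): (float(r.conductivity_S_per_m), float(r.density_g_per_cm3))
            for r in df.itertuples()
        }
        return cls(entries)

    @classmethod
    def default(cls) -> "ConductivityTable":
        """The packaged low-frequency tissue table (2.24 kHz values)."""
        with resources.as_file(
            resources.files("tmscoilopt").joinpath("data/conductivity.csv")
        ) as p:
            return cls.from_csv(p)


@dataclass
class SigmaVolume:
    """Per-voxel conductivity grid (S/m), same lattice as its source model."""

    sigma: np.ndarray
    spacing: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if np.any(self.sigma < 0):
            raise ValueError("conductivity must be non-negative")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _labels_from_nifti(path: Path) -> tuple[np.ndarray, float, np.ndarray]:
    img = nib.load(str(path))
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if not np.allclose(zooms, zooms[0], rtol=1e-6):
        raise ModelFormatError(
            f"anisotropic spacing {tuple(zooms)}; the solver assumes cubic voxels"
        )
    labels = np.asarray(img.dataobj).astype(np.int64)
    origin = np.asarray(img.affine[:3, 3], dtype=float) - zooms[0] / 2.0
    return labels, float(zooms[0]), origin


def load_voxel_model(path: str | Path, label_names: dict[int, str] | None = None) -> VoxelModel:
    """Load a voxel head model from NIfTI or raw + JSON sidecar.

    For NIfTI files the label-name map comes either from the ``label_names``
    argument or from a ``<stem>.labels.json`` sidecar next to the volume.
    Raw files (``.raw``) require a ``<stem>.json`` sidecar giving ``shape``,
    ``spacing``, ``origin``, ``dtype`` and ``label_names``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if path.suffix in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        labels, spacing, origin = _labels_from_nifti(path)
        if label_names is None:
            stem = path.name[: -len(".nii.gz")] if path.name.endswith(".nii.gz") else path.stem
            sidecar = path.parent / f"{stem}.labels.json"
            if sidecar.exists():
                label_names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    elif path.suffix == ".raw":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ModelFormatError(f"raw volume {path} requires sidecar {sidecar}")
        hdr = json.loads(sidecar.read_text())
        dtype = np.dtype(hdr.get("dtype", "uint8"))
        if dtype not in (np.dtype("uint8"), np.dtype("uint16")):
            raise ModelFormatError(f"unsupported raw dtype {dtype}")
        spacing_arr = np.atleast_1d(np.asarray(hdr["spacing"], dtype=float))
        if spacing_arr.size > 1 and not np.allclose(spacing_arr, spacing_arr[0]):
            raise ModelFormatError(
                f"anisotropic spacing {tuple(spacing_arr)}; the solver assumes cubic voxels"
            )
        spacing = float(spacing_arr.flat[0])
        shape = tuple(hdr["shape"])
        labels = np.fromfile(path, dtype=dtype.newbyteorder("<")).reshape(shape).astype(np.int64)
        origin = np.asarray(hdr.get("origin", default_origin(shape, spacing)), dtype=float)
        label_names = {int(k): v for k, v in hdr.get("label_names", {}).items()}
    else:
        raise ModelFormatError(f"unsupported model format: {path.suffix!r}")

    label_names = dict(label_names or {})
    present = set(np.unique(labels).tolist()) - {EXTERNAL_AIR}
    missing = sorted(present - set(label_names))
    if missing:
        raise UnknownTissueError(f"labels {missing} have no name mapping")
    return VoxelModel(labels=labels, spacing=spacing, origin=np.asarray(origin, float),
                      label_names=label_names)


def save_voxel_model(model: VoxelModel, path: str | Path) -> Path:
    """Write a model as NIfTI (+ label sidecar) or raw uint8/uint16 + JSON."""
    path = Path(path)
    if path.name.endswith(".nii") or path.name.endswith(".nii.gz"):
        affine = np.eye(4)
        affine[:3, :3] *= model.spacing
        affine[:3, 3] = model.origin + model.spacing / 2.0
        dtype = np.uint8 if model.labels.max(initial=0) < 256 else np.uint16
        img = nib.Nifti1Image(model.labels.astype(dtype), affine)
        img.header.set_zooms((model.spacing,) * 3)
        nib.save(img, str(path))
        stem = path.name[: -len(".nii.gz")] if path.name.endswith(".nii.gz") else path.stem
        sidecar = path.parent / f"{stem}.labels.json"
        sidecar.write_text(json.dumps({str(k): v for k, v in model.label_names.items()}))
    elif path.suffix == ".raw":
        dtype = np.uint8 if model.labels.max(initial=0) < 256 else np.uint16
        model.labels.astype(np.dtype(dtype).newbyteorder("<")).tofile(path)
        hdr = {
            "shape": list(model.labels.shape),
            "spacing": model.spacing,
            "origin": list(map(float, model.origin)),
            "dtype": np.dtype(dtype).name,
            "label_names": {str(k): v for k, v in model.label_names.items()},
        }
        path.with_suffix(".json").write_text(json.dumps(hdr, indent=1))
    else:
        raise ModelFormatError(f"unsupported output format: {path.suffix!r}")
    return path


def save_field_volume(field_data: np.ndarray, spacing: float, origin: np.ndarray,
                      path: str | Path) -> Path:
    """Write a scalar field (e.g. |E|) as a float32 NIfTI volume."""
    affine = np.eye(4)
    affine[:3, :3] *= spacing
    affine[:3, 3] = np.asarray(origin, float) + spacing / 2.0
    nib.save(nib.Nifti1Image(np.asarray(field_data, dtype=np.float32), affine), str(path))
    return Path(path)


# ---------------------------------------------------------------------------
# Conductivity mapping
# ---------------------------------------------------------------------------

def map_conductivity(model: VoxelModel, table: ConductivityTable | None = None) -> SigmaVolume:
    """Elementwise label -> conductivity lookup.

    Label 0 (external air) maps to zero; every other label present in the
    volume must resolve through ``model.label_names`` into ``table``.
    """
    table = table or ConductivityTable.default()
    present = np.unique(model.labels)
    lut_size = int(present.max(initial=0)) + 1
    lut = np.zeros(lut_size, dtype=float)
    missing: list[int] = []
    for lab in present.tolist():
        if lab == EXTERNAL_AIR:
            continue
        name = model.label_names.get(lab)
        if name is None or name not in table.entries:
            missing.append(lab)
        else:
            lut[lab] = table.conductivity(name)
    if missing:
        raise UnknownTissueError(
            f"labels {missing} cannot be resolved in the conductivity table"
        )
    return SigmaVolume(sigma=lut[model.labels], spacing=model.spacing,
                       origin=model.origin.copy())


# ---------------------------------------------------------------------------
# Surfaces
# ---------------------------------------------------------------------------

def _largest_component(mask: np.ndarray) -> np.ndarray:
    # 6-connectivity: face-adjacent voxels only
    structure = ndimage.generate_binary_structure(3, 1)
    lab, n = ndimage.label(mask, structure=structure)
    if n == 0:
        raise ValueError("model has no conducting voxels")
    if n > 1:
        counts = np.bincount(lab.ravel())[1:]
        keep = int(np.argmax(counts)) + 1
        warnings.warn(
            f"model has {n} disjoint conducting components; "
            "keeping the largest and ignoring the rest",
            stacklevel=3,
        )
        logger.warning("scalp extraction: %d disjoint components, keeping largest", n)
        return lab == keep
    return lab == 1


def _mesh_from_mask(mask: np.ndarray, spacing: float, origin: np.ndarray,
                    smooth_sigma: float = 1.0, level: float = 0.5) -> trimesh.Trimesh:
    # Pad so the iso-surface closes at the volume border; smoothing tames the
    # staircase so surface areas approach the underlying smooth geometry.
    pad = 2
    vol = np.pad(mask.astype(float), pad)
    if smooth_sigma > 0:
        vol = ndimage.gaussian_filter(vol, smooth_sigma)
        level = min(level, vol.max() * 0.5)
    verts, faces, _normals, _vals = measure.marching_cubes(vol, level=level)
    # marching-cubes vertices are in (padded) index space at lattice points;
    # index p maps to world origin + (p - pad + 0.5) * spacing
    verts = (verts - pad + 0.5) * spacing + np.asarray(origin, float)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    # orient normals outward
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def extract_scalp_surface(model: VoxelModel) -> trimesh.Trimesh:
    """Triangulated outer boundary of the conducting (nonzero-label) region.

    The boundary of the largest 6-connected component is meshed with
    marching cubes on a lightly smoothed indicator volume, giving outward
    normals and surface areas close to the underlying smooth anatomy.
    """
    mask = _largest_component(model.labels != EXTERNAL_AIR)
    return _mesh_from_mask(mask, model.spacing, model.origin)


def head_distance_field(model: VoxelModel, pad_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean distance (mm) to the head mask on a padded grid.

    Returns ``(distance, origin)`` where distance is sampled at voxel
    centers of a grid padded by ``pad_mm`` on every side.
    """
    mask = _largest_component(model.labels != EXTERNAL_AIR)
    pad = int(np.ceil(pad_mm / model.spacing)) + 2
    padded = np.pad(mask, pad)
    dist = ndimage.distance_transform_edt(~padded, sampling=model.spacing)
    origin = model.origin - pad * model.spacing
    return dist, origin


def offset_surface(model: VoxelModel, distance_mm: float) -> trimesh.Trimesh:
    """Surface at a constant separation from the scalp.

    Built from the Euclidean distance transform of the head mask (iso-level
    at ``distance_mm``), which stays well defined over concave scalp
    regions where naively displacing vertices along normals would
    self-intersect.
    """
    if not distance_mm > 0:
        raise ValueError("offset distance must be positive")
    dist, origin = head_distance_field(model, pad_mm=distance_mm + 4 * model.spacing)
    pad = 2
    vol = np.pad(dist, pad, constant_values=dist.max() + distance_mm)
    # the EDT measures to mask voxel centers; the scalp surface lies half a
    # voxel further out, so shift the iso-level accordingly
    verts, faces, _n, _v = measure.marching_cubes(vol, level=distance_mm + model.spacing / 2)
    verts = (verts - pad + 0.5) * model.spacing + origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


class SurfaceQuery:
    """Nearest-point queries against a triangle mesh.

    A k-d tree over face centroids shortlists candidate triangles; the exact
    closest point is then found on those triangles. Avoids quadratic
    brute-force queries in the optimizer's inner loop.
    """

    def __init__(self, mesh: trimesh.Trimesh, k: int = 24):
        self.mesh = mesh
        self._tree = cKDTree(mesh.triangles_center)
        self._k = min(k, len(mesh.faces))

    def closest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (closest points, face normals there, distances)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        _d, idx = self._tree.query(points, k=self._k)
        idx = np.atleast_2d(idx)
        out_pts = np.empty_like(points)
        out_nrm = np.empty_like(points)
        out_dst = np.empty(len(points))
        for i, (p, cand) in enumerate(zip(points, idx)):
            tris = self.mesh.triangles[cand]
            close = trimesh.triangles.closest_point(tris, np.tile(p, (len(cand), 1)))
            d2 = np.einsum("ij,ij->i", close - p, close - p)
            j = int(np.argmin(d2))
            out_pts[i] = close[j]
            out_nrm[i] = self.mesh.face_normals[cand[j]]
            out_dst[i] = np.sqrt(d2[j])
        return out_pts, out_nrm, out_dst
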
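"""Figure-of-eight coil geometry, tangential placement, and vector potential.

The coil is a single-turn figure-of-eight: two tangent circular loops of
equal radius centered at ``(+R, 0, 0)`` and ``(-R, 0, 0)`` in the
coil-local frame, carrying opposite circulation so their fields add under
the intersection point at the local origin.  The long axis of the
figure-of-eight is the local X axis.

Each loop is discretized into straight current segments; the magnetic
vector potential is the Biot-Savart sum

    A(r) = (mu0 * I / 4 pi) * sum_seg dl / |r - r_seg|,

evaluated at the midpoints of the voxel-grid edges where the quasi-static
solver needs it (a staggered sampling that avoids interpolating the source
term).

Placement poses the coil tangentially on the 10 mm offset surface: the
coil plane is perpendicular to the outward surface normal, and rotation
``phi = 0`` aligns the coil's long axis with the projection of world +X
onto the tangent plane; ``phi`` rotates about the normal through the
figure-of-eight intersection point.  Because a 180-degree rotation maps
the coil onto itself with reversed current, the induced field magnitude is
periodic in ``phi`` with period 180 degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model_io import SigmaVolume, SurfaceQuery

logger = logging.getLogger("tmscoilopt")

MU0 = 4e-7 * np.pi  # T*m/A

DEFAULT_LOOP_RADIUS_MM = 20.0
DEFAULT_N_SEGMENTS = 64
DEFAULT_CURRENT_A = 1000.0
DEFAULT_FREQUENCY_HZ = 2240.0


@dataclass
class CoilGeometry:
    """Discretized figure-of-eight winding in the coil-local frame.

    ``midpoints`` (mm) and ``dl`` (directed segment vectors, mm) describe
    all straight segments of both loops; the two loops wind in opposite
    directions so each closes on itself (the directed segments of each loop
    sum to zero).
    """

    loop_radius: float
    n_segments: int
    current: float
    frequency: float
    midpoints: np.ndarray
    dl: np.ndarray
    turns: int = 1

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency


def build_foe_coil(
    loop_radius: float = DEFAULT_LOOP_RADIUS_MM,
    n_segments: int = DEFAULT_N_SEGMENTS,
    current: float = DEFAULT_CURRENT_A,
    frequency: float = DEFAULT_FREQUENCY_HZ,
    turns: int = 1,
) -> CoilGeometry:
    """Build the one-turn figure-of-eight coil.

    ``n_segments`` is the polygon count per loop; 64 keeps the on-axis
    field of each loop within ~1% of the circular-loop closed form.
    """
    if n_segments < 8:
        raise ValueError("need at least 8 segments per loop")
    if loop_radius <= 0:
        raise ValueError("loop radius must be positive")

    theta = np.linspace(0.0, 2.0 * np.pi, n_segments + 1)
    mids, dls = [], []
    for cx, sense in ((+loop_radius, +1.0), (-loop_radius, -1.0)):
        ang = sense * theta
        pts = np.column_stack([
            cx + loop_radius * np.cos(ang),
            loop_radius * np.sin(ang),
            np.zeros_like(ang),
        ])
        mids.append(0.5 * (pts[1:] + pts[:-1]))
        dls.append(np.diff(pts, axis=0))
    return CoilGeometry(
        loop_radius=loop_radius, n_segments=n_segments, current=current,
        frequency=frequency, midpoints=np.vstack(mids), dl=np.vstack(dls),
        turns=turns,
    )


@dataclass
class CoilPlacement:
    """Pose of the coil on the offset surface."""

    center: np.ndarray      # world mm, figure-of-eight intersection point
    normal: np.ndarray      # outward unit normal (coil plane is tangent)
    phi_deg: float          # rotation about the normal
    frame: np.ndarray       # columns: world directions of coil-local x, y, z


def tangent_reference(normal: np.ndarray) -> np.ndarray:
    """Tangent direction defining phi = 0: world +X projected onto the plane.

    Falls back to projecting +Y when the normal is (anti)parallel to X.
    """
    normal = np.asarray(normal, dtype=float)
    for ref in (np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])):
        t = ref - np.dot(ref, normal) * normal
        nrm = np.linalg.norm(t)
        if nrm > 1e-8:
            if ref[0] == 0.0:
                logger.warning(
                    "surface normal parallel to world X; using +Y as the "
                    "phi=0 tangent reference")
            return t / nrm
    raise ValueError("degenerate surface normal")


def place_coil(
    geom: CoilGeometry,
    surface: SurfaceQuery,
    candidate_point: np.ndarray,
    phi_deg: float,
    snap_radius_mm: float | None = None,
) -> CoilPlacement:
    """Snap a candidate point to the offset surface and build the pose frame.

    The candidate is replaced by the nearest surface point; an error is
    raised if it lies farther than ``snap_radius_mm`` away (a search
    particle escaped the patch).
    """
    pts, normals, dist = surface.closest(np.asarray(candidate_point, float))
    if snap_radius_mm is not None and dist[0] > snap_radius_mm:
        raise ValueError(
            f"candidate point is {dist[0]:.1f} mm from the search surface "
            f"(snap radius {snap_radius_mm} mm)")
    center, normal = pts[0], normals[0] / np.linalg.norm(normals[0])
    e1 = tangent_reference(normal)
    e2 = np.cross(normal, e1)
    phi = np.deg2rad(phi_deg)
    x_local = np.cos(phi) * e1 + np.sin(phi) * e2
    y_local = np.cross(normal, x_local)
    frame = np.column_stack([x_local, y_local, normal])
    return CoilPlacement(center=center, normal=normal,
                         phi_deg=float(phi_deg) % 360.0, frame=frame)


def world_segments(geom: CoilGeometry, placement: CoilPlacement
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Segment midpoints and directed lengths in world coordinates (mm)."""
    R = placement.frame
    mids = placement.center + geom.midpoints @ R.T
    dls = geom.dl @ R.T
    return mids, dls


def vector_potential_at(
    geom: CoilGeometry,
    placement: CoilPlacement,
    points_mm: np.ndarray,
    min_distance_mm: float | None = None,
    chunk: int = 65536,
) -> np.ndarray:
    """Biot-Savart vector potential (T*m) at arbitrary world points.

    ``min_distance_mm`` guards against near-singular samples; with the
    10 mm coil standoff no grid edge should ever come close to a segment,
    so a violation indicates a placement bug.
    """
    mids_mm, dls_mm = world_segments(geom, placement)
    mids = mids_mm * 1e-3
    dls = dls_mm * 1e-3
    pts = np.asarray(points_mm, dtype=float) * 1e-3
    coef = MU0 * geom.current * geom.turns / (4.0 * np.pi)

    m2 = np.einsum("ij,ij->i", mids, mids)
    out = np.empty((len(pts), 3))
    for lo in range(0, len(pts), chunk):
        p = pts[lo:lo + chunk]
        # |p - m|^2 expanded so the heavy part is a single GEMM
        d2 = np.einsum("ij,ij->i", p, p)[:, None] + m2[None, :] - 2.0 * (p @ mids.T)
        np.maximum(d2, 0.0, out=d2)
        dist = np.sqrt(d2)
        if min_distance_mm is not None and dist.size:
            dmin = dist.min()
            if dmin < min_distance_mm * 1e-3:
                raise ValueError(
                    f"sample point within {dmin * 1e3:.2f} mm of a coil "
                    "segment; the coil must stay off the grid")
        out[lo:lo + chunk] = coef * (1.0 / dist) @ dls
    return out


@dataclass
class AVolume:
    """Vector potential sampled at staggered grid-edge midpoints.

    ``edge[a]`` holds the a-component of A (T*m) at midpoints of edges
    directed along axis ``a``; the a-edge array has one fewer sample along
    ``a`` than the node grid and full node extent along the other axes.
    """

    edge: tuple[np.ndarray, np.ndarray, np.ndarray]
    spacing: float
    origin: np.ndarray
    placement: CoilPlacement | None = None
    frequency: float | None = None


def edge_midpoints(shape_vox: tuple[int, int, int], spacing: float,
                   origin: np.ndarray, axis: int) -> np.ndarray:
    """World midpoints (mm) of all grid edges along one axis, flattened."""
    nx, ny, nz = shape_vox
    node = [np.arange(n + 1) * spacing for n in (nx, ny, nz)]
    mid = [c.copy() for c in node]
    mid[axis] = (node[axis][:-1] + node[axis][1:]) / 2.0
    G = np.meshgrid(*mid, indexing="ij")
    pts = np.column_stack([g.ravel() for g in G])
    return pts + np.asarray(origin, float)


def edge_grid_shape(shape_vox: tuple[int, int, int], axis: int) -> tuple[int, int, int]:
    out = [n + 1 for n in shape_vox]
    out[axis] = shape_vox[axis]
    return tuple(out)


def vector_potential(
    geom: CoilGeometry,
    placement: CoilPlacement,
    grid: SigmaVolume,
    edge_masks: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    min_distance_mm: float | None = None,
) -> AVolume:
    """Sample the coil's vector potential on a voxel grid's edges.

    Only the along-edge component of A enters the solver, so each edge
    family stores a single scalar per edge.  ``edge_masks`` restricts
    evaluation to the (conducting) edges the solver will actually use;
    masked-out edges are stored as zero.
    """
    shape_vox = grid.sigma.shape
    comps = []
    if min_distance_mm is None:
        min_distance_mm = 0.25 * grid.spacing
    for axis in range(3):
        eshape = edge_grid_shape(shape_vox, axis)
        vals = np.zeros(eshape)
        pts = edge_midpoints(shape_vox, grid.spacing, grid.origin, axis)
        if edge_masks is not None:
            sel = edge_masks[axis].ravel()
            if sel.any():
                a = vector_potential_at(geom, placement, pts[sel],
                                        min_distance_mm=min_distance_mm)
                vals.ravel()[np.flatnonzero(sel)] = a[:, axis]
        else:
            a = vector_potential_at(geom, placement, pts,
                                    min_distance_mm=min_distance_mm)
            vals = a[:, axis].reshape(eshape)
        comps.append(vals)
    return AVolume(edge=tuple(comps), spacing=grid.spacing,
                   origin=np.asarray(grid.origin, float),
                   placement=placement, frequency=geom.frequency)


def uniform_field_avolume(grid: SigmaVolume, A_func,
                          frequency: float) -> AVolume:
    """Sample an analytic vector-potential field on the grid edges."""
    shape_vox = grid.sigma.shape
    comps = []
    for axis in range(3):
        pts = edge_midpoints(shape_vox, grid.spacing, grid.origin, axis)
        comps.append(A_func(pts)[:, axis].reshape(
            edge_grid_shape(shape_vox, axis)))
    return AVolume(edge=tuple(comps), spacing=grid.spacing,
                   origin=np.asarray(grid.origin, float), frequency=frequency)
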
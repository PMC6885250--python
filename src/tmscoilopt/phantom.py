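"""Layered-sphere head phantoms with tunable cortical gyrification.

The phantom stands in for segmented anatomical head models: concentric
shells of skin, skull (bone), CSF, grey matter and a white-matter core on a
sphere.  Cortical folding is emulated by a smooth radial modulation of the
pial and grey-white interfaces,

    r(u) = r0 + a * sin(2*pi*s(u)/lambda + phase),

where ``s`` is an arc-length coordinate along great circles around a fixed
oblique gyral axis, ``a`` the gyral amplitude and ``lambda`` the gyral
wavelength.  The axis is deliberately oblique to the world X axis (the
rotation-zero reference of the coil) so that the conventional initial
orientation is generically not the best one — mimicking the dependence of
the induced field on gyral orientation that makes optimization worthwhile
on real anatomy.  The modulation shifts both cortical interfaces together, so
the cortical ribbon keeps constant thickness while its area (and hence the
gyrification index) grows with the amplitude.

A "C4-like" scalp point — 45 degrees lateral from the apex in the +X
hemisphere, a fixed convention replacing the 10-20 EEG system — anchors the
scenario: the region of interest is a 2x2-voxel patch of outermost grey
matter on the gyral crown nearest that point, and the initial coil pose
sits on the 10 mm offset surface directly above the ROI with rotation 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import (
    SigmaVolume,
    SurfaceQuery,
    VoxelModel,
    offset_surface,
)

MU0 = 4e-7 * np.pi  # vacuum permeability, T*m/A

#: label IDs of the phantom tissues, outside-in
PHANTOM_LABELS = {
    1: "Skin",
    2: "Bone",
    3: "Cerebrospinal fluid",
    4: "Grey matter",
    5: "White matter",
}
GREY_LABEL = 4

#: default shell thicknesses in mm, outside-in (white matter fills the core)
DEFAULT_SHELLS = {"skin": 4.0, "bone": 6.0, "csf": 4.0, "grey": 6.0}

STANDOFF_MM = 10.0  # coil-scalp separation

#: polar angle (deg) of the C4-like anchor point from the apex, in +X
C4_LATERAL_DEG = 45.0

#: axis of the gyral band pattern (crowns/valleys are rings around it);
#: tilted 30 degrees from world Y toward X so gyri cross the search patch
#: obliquely to the coil's rotation-zero reference
GYRAL_AXIS = np.array([0.5, np.sqrt(3.0) / 2.0, 0.0])


@dataclass
class PhantomSpec:
    """Geometry of a layered-sphere phantom."""

    outer_radius: float = 50.0
    shell_thicknesses: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SHELLS))
    gyral_amplitude: float = 3.0
    gyral_wavelength: float = 12.0
    spacing: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        radii = self.interface_radii()
        order = ["skin", "bone", "csf", "grey"]
        prev = self.outer_radius
        for name in order:
            r = radii[name]
            if not r < prev:
                raise ValueError("shell radii must decrease strictly inward")
            if self.shell_thicknesses[name] < 2 * self.spacing:
                raise ValueError(
                    f"spacing {self.spacing} mm too coarse to resolve the "
                    f"{name} shell ({self.shell_thicknesses[name]} mm)")
            prev = r
        if self.gyral_amplitude >= self.shell_thicknesses["grey"]:
            raise ValueError("gyral amplitude must be below the grey thickness")
        if self.gyral_amplitude > self.shell_thicknesses["csf"]:
            raise ValueError("gyral amplitude must not exceed the CSF thickness")

    def interface_radii(self) -> dict[str, float]:
        """Nominal inner radius of each named shell."""
        r = self.outer_radius
        out = {}
        for name in ["skin", "bone", "csf", "grey"]:
            r -= self.shell_thicknesses[name]
            out[name] = r
        return out

    @property
    def center(self) -> np.ndarray:
        """Sphere center in world coordinates (bottom at z = 0)."""
        return np.array([0.0, 0.0, self.outer_radius])


@dataclass
class ROISpec:
    """Target patch: outermost grey-matter voxels on a gyral crown."""

    voxels: np.ndarray           # (n, 3) integer indices
    center: np.ndarray           # world mm
    extent_mm: float             # nominal lateral extent

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int)
        self.center = np.asarray(self.center, dtype=float)


@dataclass
class InitialPose:
    """Conventional starting pose: coil intersection above the ROI, phi=0."""

    center: np.ndarray
    normal: np.ndarray
    phi_deg: float = 0.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        self.normal = self.normal / np.linalg.norm(self.normal)


def _grid(spec: PhantomSpec) -> tuple[tuple[int, int, int], np.ndarray]:
    pad = 2  # voxels of air around the sphere
    n = int(np.ceil(2 * spec.outer_radius / spec.spacing)) + 2 * pad
    origin = np.array([-n * spec.spacing / 2.0,
                       -n * spec.spacing / 2.0,
                       -pad * spec.spacing])
    return (n, n, n), origin


def _gyral_phase(seed: int) -> float:
    return float(np.random.default_rng(seed).uniform(0.0, 2.0 * np.pi))


def _modulation(spec: PhantomSpec, ux, uy, uz, phase: float):
    """Radial interface shift a*sin(2*pi*s/lambda + phase) per direction."""
    r_gw = spec.interface_radii()["grey"]
    b = GYRAL_AXIS
    cos_t = np.clip(ux * b[0] + uy * b[1] + uz * b[2], -1.0, 1.0)
    s = r_gw * np.arccos(cos_t)  # arc length from the gyral axis
    return spec.gyral_amplitude * np.sin(2.0 * np.pi * s / spec.gyral_wavelength + phase)


def make_layered_sphere(spec: PhantomSpec) -> VoxelModel:
    """Voxelize the concentric-shell phantom (with gyrification if a > 0)."""
    shape, origin = _grid(spec)
    s = spec.spacing
    coords = [origin[a] + (np.arange(shape[a]) + 0.5) * s for a in range(3)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    c = spec.center
    dx, dy, dz = X - c[0], Y - c[1], Z - c[2]
    r = np.sqrt(dx * dx + dy * dy + dz * dz)

    radii = spec.interface_radii()
    labels = np.zeros(shape, dtype=np.uint8)
    labels[r <= spec.outer_radius] = 1                      # skin
    labels[r <= radii["skin"]] = 2                          # bone
    labels[r <= radii["bone"]] = 3                          # CSF

    if spec.gyral_amplitude > 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            inv_r = np.where(r > 0, 1.0 / r, 0.0)
        delta = _modulation(spec, dx * inv_r, dy * inv_r, dz * inv_r,
                            _gyral_phase(spec.seed))
    else:
        delta = 0.0
    labels[r <= radii["csf"] + delta] = 4                   # grey (pial)
    labels[r <= radii["grey"] + delta] = 5                  # white

    return VoxelModel(labels=labels, spacing=s, origin=origin,
                      label_names=dict(PHANTOM_LABELS))


def _c4_direction() -> np.ndarray:
    t = np.deg2rad(C4_LATERAL_DEG)
    return np.array([np.sin(t), 0.0, np.cos(t)])


def _crown_direction(spec: PhantomSpec) -> np.ndarray:
    """Unit direction of the gyral crown nearest the C4-like point."""
    phase = _gyral_phase(spec.seed)
    r_gw = spec.interface_radii()["grey"]
    b = GYRAL_AXIS
    d = _c4_direction()
    theta_d = float(np.arccos(np.clip(d @ b, -1.0, 1.0)))
    # crowns: sin(2*pi*r_gw*theta/lambda + phase) = 1
    lam = spec.gyral_wavelength
    k = np.arange(0, int(np.ceil(2 * np.pi * r_gw / lam)) + 2)
    theta_c = (np.pi / 2.0 - phase + 2.0 * np.pi * k) * lam / (2.0 * np.pi * r_gw)
    theta_c = theta_c[(theta_c > 0.05) & (theta_c < np.pi - 0.05)]
    if theta_c.size == 0:
        raise ValueError("no gyral crown on the phantom surface")
    theta = theta_c[np.argmin(np.abs(theta_c - theta_d))]
    # nearest point to d on the crown ring at angle theta around the axis
    perp = d - (d @ b) * b
    perp /= np.linalg.norm(perp)
    return np.sin(theta) * perp + np.cos(theta) * b


def _outermost_grey(model: VoxelModel, spec: PhantomSpec,
                    direction: np.ndarray) -> np.ndarray:
    """2x2 patch of outermost grey voxels around a surface direction."""
    c = spec.center
    radii = spec.interface_radii()
    p_surf = c + direction * (radii["csf"])  # nominal pial point
    idx0 = np.floor(model.world_to_index(p_surf) + 0.5).astype(int)
    normal_axis = int(np.argmax(np.abs(direction)))
    tang = [a for a in range(3) if a != normal_axis]
    sgn = 1 if direction[normal_axis] > 0 else -1

    nvox = model.labels.shape[normal_axis]
    voxels = []
    for da in (0, 1):
        for db in (0, 1):
            col = idx0.copy()
            col[tang[0]] += da
            col[tang[1]] += db
            # scan the column from outside inward for the first grey voxel
            found = None
            order = range(nvox - 1, -1, -1) if sgn > 0 else range(nvox)
            for i in order:
                col[normal_axis] = i
                if model.labels[tuple(col)] == GREY_LABEL:
                    found = col.copy()
                    break
            if found is None:
                raise ValueError("no gyral crown grey matter under the patch")
            voxels.append(found)
    return np.array(voxels, dtype=int)


def make_gyrified_phantom(
    spec: PhantomSpec,
) -> tuple[VoxelModel, ROISpec, InitialPose]:
    """Gyrified phantom plus its ROI and conventional initial coil pose."""
    if not spec.gyral_amplitude > 0:
        raise ValueError("gyral amplitude must be positive; "
                         "use make_layered_sphere for the smooth case")
    model = make_layered_sphere(spec)
    direction = _crown_direction(spec)
    voxels = _outermost_grey(model, spec, direction)
    centers = model.index_to_world(voxels)
    roi = ROISpec(voxels=voxels, center=centers.mean(axis=0),
                  extent_mm=2 * spec.spacing)

    # project the ROI center radially out to the offset surface
    surf = offset_surface(model, STANDOFF_MM)
    u = roi.center - spec.center
    u = u / np.linalg.norm(u)
    target = spec.center + u * (spec.outer_radius + STANDOFF_MM)
    pts, normals, _ = SurfaceQuery(surf).closest(target)
    return model, roi, InitialPose(center=pts[0], normal=normals[0], phi_deg=0.0)


def make_uniform_B_case(
    radius_mm: float = 40.0,
    sigma_S_per_m: float = 0.1,
    B0_T: float = 1.0,
    frequency_Hz: float = 2240.0,
    spacing_mm: float = 2.0,
):
    """Homogeneous conducting sphere in a uniform axial B field.

    The vector potential of a uniform field ``B0 * zhat`` is the closed form
    ``A = 0.5 * B x r`` about the sphere axis.  The induced field then has
    the analytic magnitude ``|E| = omega * B0 * rho / 2`` with ``rho`` the
    distance from the axis — the standard eddy-current oracle for
    quasi-static solvers.

    Returns ``(model, sigma_volume, A_func)`` where ``A_func`` maps world
    points (n, 3) to vector-potential samples (n, 3) in T*m.
    """
    if min(radius_mm, sigma_S_per_m, B0_T, frequency_Hz, spacing_mm) <= 0:
        raise ValueError("all parameters must be positive")
    pad = 2
    n = int(np.ceil(2 * radius_mm / spacing_mm)) + 2 * pad
    origin = np.array([-n * spacing_mm / 2.0, -n * spacing_mm / 2.0,
                       -pad * spacing_mm])
    center = np.array([0.0, 0.0, radius_mm])
    coords = [origin[a] + (np.arange(n) + 0.5) * spacing_mm for a in range(3)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    r = np.sqrt(X ** 2 + Y ** 2 + (Z - center[2]) ** 2)
    labels = (r <= radius_mm).astype(np.uint8)
    model = VoxelModel(labels=labels, spacing=spacing_mm, origin=origin,
                       label_names={1: "Uniform medium"})
    sigma = SigmaVolume(sigma=labels * sigma_S_per_m, spacing=spacing_mm,
                        origin=origin)

    B = np.array([0.0, 0.0, B0_T])

    def A_func(points: np.ndarray) -> np.ndarray:
        rel = (np.atleast_2d(points) - center) * 1e-3  # mm -> m
        return 0.5 * np.cross(B, rel)

    return model, sigma, A_func
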
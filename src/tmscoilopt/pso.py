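"""Particle swarm optimization of the coil pose on the offset surface.

A particle is a coil pose ``(x, y, z, phi)``: the figure-of-eight
intersection point on the 10 mm offset surface plus the rotation angle
about the local normal.  Velocities and positions follow the canonical
update

    v <- w*v + c1*rand()*(pbest - pos) + c2*rand()*(gbest - pos)
    pos <- pos + v

with independent uniform(0, 1) draws per dimension and term, learning
factors ``c1 = c2 = 2.05`` and a linearly annealed inertia weight
``w = w_max - (t/t_max) * (w_max - w_min)`` from 1.2 down to 0.9.

The search region is a 4 x 4 cm^2 patch of the offset surface centered
above the target ROI.  Constraints are handled by project-and-continue:
after each update the position is clipped in the patch's tangent
coordinates and snapped back to the nearest surface point, leaving the
velocity untouched.  The rotation angle is continuous during updates and
wrapped modulo 360; because the figure-of-eight field magnitude has a
180-degree period, angular differences in the velocity terms use the
shortest distance modulo 180 and results report phi modulo 180.

The objective is the mean induced |E| over the ROI voxels, evaluated by
the SPFD solver; repeated evaluations of (near-)identical poses are served
from a cache keyed at 0.5 mm / 1 degree resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import coil as coil_mod
from . import spfd
from .model_io import SurfaceQuery, VoxelModel, map_conductivity, offset_surface
from .phantom import InitialPose, ROISpec, STANDOFF_MM

logger = logging.getLogger("tmscoilopt")

PHI_PERIOD_DEG = 180.0  # field-magnitude symmetry of the figure-of-eight


@dataclass
class PSOConfig:
    """Swarm hyperparameters and termination rule."""

    n_particles: int = 8
    c1: float = 2.05
    c2: float = 2.05
    omega_max: float = 1.2
    omega_min: float = 0.9
    t_max: int = 30
    improvement_tol: float = 0.01   # relative gbest improvement ...
    patience: int = 3               # ... over this many iterations
    velocity_clamp_mm: float = 20.0   # half the patch extent per axis
    velocity_clamp_deg: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.omega_max < self.omega_min:
            raise ValueError("omega_max must be >= omega_min")


def inertia_weight(t: int, t_max: int, omega_max: float = 1.2,
                   omega_min: float = 0.9) -> float:
    """Self-adaptive linear schedule w_max - t/t_max * (w_max - w_min)."""
    if not 0 <= t <= t_max:
        raise ValueError("t must lie in [0, t_max]")
    return omega_max - (t / t_max) * (omega_max - omega_min)


def wrap_angle_deg(phi: float, period: float = 360.0) -> float:
    return float(phi) % period


def angular_difference_deg(a: float, b: float,
                           period: float = PHI_PERIOD_DEG) -> float:
    """Shortest signed distance a - b on a circle of the given period."""
    d = (a - b) % period
    if d > period / 2:
        d -= period
    return d


# ---------------------------------------------------------------------------
# Search patch on the offset surface
# ---------------------------------------------------------------------------

class SurfacePatch:
    """Square patch of the offset surface centered above the ROI.

    Points are parameterized by tangent-plane coordinates (u, v) at the
    patch center; mapping back to the surface goes through a nearest-point
    query, so the patch follows the curvature of the offset surface.
    """

    def __init__(self, surface_query: SurfaceQuery, center: np.ndarray,
                 normal: np.ndarray, half_extent_mm: float = 20.0):
        self.query = surface_query
        self.center = np.asarray(center, dtype=float)
        self.normal = np.asarray(normal, dtype=float)
        self.normal /= np.linalg.norm(self.normal)
        self.e1 = coil_mod.tangent_reference(self.normal)
        self.e2 = np.cross(self.normal, self.e1)
        self.half_extent = float(half_extent_mm)

    def to_surface(self, u: float, v: float) -> np.ndarray:
        """Map clipped tangent coordinates to the nearest surface point."""
        u = float(np.clip(u, -self.half_extent, self.half_extent))
        v = float(np.clip(v, -self.half_extent, self.half_extent))
        p = self.center + u * self.e1 + v * self.e2
        pts, _, _ = self.query.closest(p)
        return pts[0]

    def project(self, point: np.ndarray) -> np.ndarray:
        """Project an arbitrary 3-D point into the patch (clip, then snap)."""
        rel = np.asarray(point, dtype=float) - self.center
        return self.to_surface(float(rel @ self.e1), float(rel @ self.e2))

    def lattice(self, spacing_mm: float = 10.0) -> np.ndarray:
        """Regular lattice of surface points covering the patch."""
        n = int(round(2 * self.half_extent / spacing_mm))
        offs = -self.half_extent + (np.arange(n) + 0.5) * spacing_mm
        return np.array([self.to_surface(u, v) for u in offs for v in offs])


def search_patch_for(model: VoxelModel, initial_pose: InitialPose,
                     half_extent_mm: float = 20.0,
                     standoff_mm: float = STANDOFF_MM) -> SurfacePatch:
    """Build the search patch of the offset surface around the initial pose."""
    surf = offset_surface(model, standoff_mm)
    return SurfacePatch(SurfaceQuery(surf), initial_pose.center,
                        initial_pose.normal, half_extent_mm)


# ---------------------------------------------------------------------------
# Objective: SPFD solve -> mean ROI |E|
# ---------------------------------------------------------------------------

class EFieldObjective:
    """Mean ROI |E| (V/m) as a function of coil pose, with caching.

    The conductivity map, sparse operator and conducting-edge masks are
    precomputed once; each pose evaluation only recomputes the coil's
    vector potential on conducting edges, the right-hand side, and the CG
    solve.
    """

    def __init__(self, model: VoxelModel, geom: coil_mod.CoilGeometry,
                 roi: ROISpec, patch: SurfacePatch,
                 rtol: float = spfd.DEFAULT_RTOL, cache: bool = True,
                 snap_resolution: tuple[float, float] = (0.5, 1.0)):
        self.model = model
        self.geom = geom
        self.roi = roi
        self.patch = patch
        self.rtol = rtol
        self.sigma = map_conductivity(model)
        self.operator = spfd.sigma_operator(self.sigma)
        self.cache_enabled = cache
        self.snap_resolution = snap_resolution
        self._cache: dict[tuple, float] = {}
        self.n_solves = 0
        self.n_cache_hits = 0

    def _key(self, pos: np.ndarray) -> tuple:
        dx, dphi = self.snap_resolution
        return (round(pos[0] / dx), round(pos[1] / dx), round(pos[2] / dx),
                round((pos[3] % PHI_PERIOD_DEG) / dphi))

    def __call__(self, pos: np.ndarray) -> float:
        pos = np.asarray(pos, dtype=float)
        key = self._key(pos)
        if self.cache_enabled and key in self._cache:
            self.n_cache_hits += 1
            return self._cache[key]
        placement = coil_mod.place_coil(self.geom, self.patch.query,
                                        pos[:3], pos[3])
        A = coil_mod.vector_potential(
            self.geom, placement, self.sigma,
            edge_masks=tuple(self.operator.edge_masks))
        system = spfd.SPFDSystem(self.operator, self.operator.assemble_rhs(A),
                                 self.geom.frequency)
        psi = spfd.solve(system, rtol=self.rtol)
        e = spfd.efield(psi, A, self.sigma, self.geom.frequency)
        val = spfd.roi_statistic(e, self.roi.voxels)
        self.n_solves += 1
        if self.cache_enabled:
            self._cache[key] = val
        logger.info("objective: pos=(%.1f, %.1f, %.1f) phi=%.1f -> %.4g V/m "
                    "(%d CG iters)", *pos[:3], pos[3] % PHI_PERIOD_DEG, val,
                    psi.iterations)
        return val

    def efield_volume(self, pos: np.ndarray) -> spfd.EFieldVolume:
        """Full |E| volume for one pose (for reporting/export)."""
        pos = np.asarray(pos, dtype=float)
        placement = coil_mod.place_coil(self.geom, self.patch.query,
                                        pos[:3], pos[3])
        A = coil_mod.vector_potential(
            self.geom, placement, self.sigma,
            edge_masks=tuple(self.operator.edge_masks))
        system = spfd.SPFDSystem(self.operator, self.operator.assemble_rhs(A),
                                 self.geom.frequency)
        psi = spfd.solve(system, rtol=self.rtol)
        return spfd.efield(psi, A, self.sigma, self.geom.frequency)


def evaluate_pose(pos: np.ndarray, objective: EFieldObjective) -> float:
    """Objective value (mean ROI |E|, V/m) of one coil pose."""
    return objective(pos)


# ---------------------------------------------------------------------------
# Swarm state and updates
# ---------------------------------------------------------------------------

@dataclass
class ParticleState:
    pos: np.ndarray                  # (x, y, z, phi)
    vel: np.ndarray
    pbest_pos: np.ndarray
    pbest_val: float

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.vel = np.asarray(self.vel, dtype=float)
        self.pbest_pos = np.asarray(self.pbest_pos, dtype=float)


@dataclass
class SwarmState:
    particles: list[ParticleState]
    gbest_pos: np.ndarray
    gbest_val: float
    t: int = 0
    history: list[float] = field(default_factory=list)


INIT_PHI_STEP_DEG = 15.0


def initialize_swarm(patch: SurfacePatch, config: PSOConfig,
                     objective=None) -> SwarmState:
    """Particles on the 10 mm patch lattice with 15-degree initial angles.

    Positions are drawn without replacement from the lattice (16 points on
    the default 4 x 4 cm^2 patch); initial rotation angles are random
    multiples of 15 degrees and initial velocities are zero.  When an
    objective is given, all particles are evaluated so personal/global
    bests start defined.
    """
    rng = np.random.default_rng(config.seed)
    lattice = patch.lattice(10.0)
    if config.n_particles > len(lattice):
        raise ValueError(
            f"{config.n_particles} particles but only {len(lattice)} "
            "lattice points on the patch")
    chosen = rng.choice(len(lattice), size=config.n_particles, replace=False)
    phis = rng.choice(np.arange(0.0, PHI_PERIOD_DEG, INIT_PHI_STEP_DEG),
                      size=config.n_particles)
    particles = []
    for i, (li, phi) in enumerate(zip(chosen, phis)):
        pos = np.append(lattice[li], phi)
        val = float(objective(pos)) if objective is not None else -np.inf
        particles.append(ParticleState(pos=pos, vel=np.zeros(4),
                                       pbest_pos=pos.copy(), pbest_val=val))
    best = max(particles, key=lambda p: p.pbest_val)
    return SwarmState(particles=particles, gbest_pos=best.pbest_pos.copy(),
                      gbest_val=best.pbest_val, t=0,
                      history=[best.pbest_val])


def update_particle(p: ParticleState, gbest_pos: np.ndarray, omega: float,
                    c1: float, c2: float, rng, patch: SurfacePatch | None,
                    clamp: np.ndarray, objective=None) -> ParticleState:
    """One velocity/position update (in place), then projection to the patch.

    ``rng`` must provide ``random(size)``; two independent 4-vectors of
    uniform draws are used per update.  If ``objective`` is given the new
    position is evaluated and the personal best updated.
    """
    r1 = rng.random(4)
    r2 = rng.random(4)
    dp = p.pbest_pos - p.pos
    dg = np.asarray(gbest_pos, dtype=float) - p.pos
    # the objective has a 180-degree period in phi: steer along the
    # shortest angular difference
    dp[3] = angular_difference_deg(p.pbest_pos[3], p.pos[3])
    dg[3] = angular_difference_deg(gbest_pos[3], p.pos[3])
    p.vel = omega * p.vel + c1 * r1 * dp + c2 * r2 * dg
    p.vel = np.clip(p.vel, -clamp, clamp)
    p.pos = p.pos + p.vel
    if patch is not None:
        p.pos[:3] = patch.project(p.pos[:3])
    p.pos[3] = wrap_angle_deg(p.pos[3])
    if objective is not None:
        val = float(objective(p.pos))
        if val > p.pbest_val:
            p.pbest_val = val
            p.pbest_pos = p.pos.copy()
    return p


@dataclass
class OptimizationResult:
    """Outcome of one PSO run, mirroring the per-run reporting columns."""

    best_pos: np.ndarray
    best_val: float
    initial_val: float
    enhancement_pct: float
    displacement_mm: float
    phi_deg: float                   # reported modulo 180
    iterations: int
    n_evaluations: int               # iterations x particles (budget metric)
    n_solver_calls: int              # actual distinct objective evaluations
    history: list[float]
    seed: int
    converged: bool


def run_pso(objective, patch: SurfacePatch, initial_pose: InitialPose,
            config: PSOConfig) -> OptimizationResult:
    """Run the swarm until the termination rule or ``t_max`` iterations.

    Termination: the run is converged at the first iteration ``t`` (with
    ``t >= patience``) at which the relative gbest improvement over the
    last ``patience`` iterations falls below ``improvement_tol``.
    """
    initial_pos = np.append(np.asarray(initial_pose.center, float),
                            initial_pose.phi_deg)
    initial_val = float(objective(initial_pos))

    rng = np.random.default_rng(config.seed + 1)  # decoupled from init draws
    swarm = initialize_swarm(patch, config, objective=objective)
    n_calls_before = getattr(objective, "n_solves", None)
    clamp = np.array([config.velocity_clamp_mm] * 3
                     + [config.velocity_clamp_deg])

    converged = False
    for t in range(1, config.t_max + 1):
        omega = inertia_weight(t - 1, config.t_max,
                               config.omega_max, config.omega_min)
        for p in swarm.particles:
            update_particle(p, swarm.gbest_pos, omega, config.c1, config.c2,
                            rng, patch, clamp, objective=objective)
            if p.pbest_val > swarm.gbest_val:
                swarm.gbest_val = p.pbest_val
                swarm.gbest_pos = p.pbest_pos.copy()
        swarm.t = t
        swarm.history.append(swarm.gbest_val)
        assert swarm.history[-1] >= swarm.history[-2] - 1e-12, \
            "global best must be non-decreasing"
        if t >= config.patience:
            ref = swarm.history[t - config.patience]
            if ref > 0 and (swarm.history[t] - ref) / ref < config.improvement_tol:
                converged = True
                break
        logger.info("iteration %d: gbest %.4g V/m (omega %.3f)",
                    t, swarm.gbest_val, omega)

    best_pos = swarm.gbest_pos.copy()
    enhancement = (100.0 * (swarm.gbest_val - initial_val) / initial_val
                   if initial_val > 0 else float("nan"))
    displacement = float(np.linalg.norm(best_pos[:3] - initial_pos[:3]))
    return OptimizationResult(
        best_pos=best_pos,
        best_val=float(swarm.gbest_val),
        initial_val=initial_val,
        enhancement_pct=float(enhancement),
        displacement_mm=displacement,
        phi_deg=float(best_pos[3] % PHI_PERIOD_DEG),
        iterations=swarm.t,
        n_evaluations=swarm.t * config.n_particles,
        n_solver_calls=(getattr(objective, "n_solves", 0) or 0)
        - (n_calls_before or 0) if n_calls_before is not None
        else swarm.t * config.n_particles,
        history=list(swarm.history),
        seed=config.seed,
        converged=converged,
    )


def optimize_coil_position(model: VoxelModel, geom: coil_mod.CoilGeometry,
                           roi: ROISpec, initial_pose: InitialPose,
                           config: PSOConfig,
                           cache: bool = True) -> OptimizationResult:
    """End-to-end optimization of the coil pose on a head model."""
    patch = search_patch_for(model, initial_pose)
    objective = EFieldObjective(model, geom, roi, patch, cache=cache)
    return run_pso(objective, patch, initial_pose, config)
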
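"""PSO mechanics: schedules, updates, initialization, and convergence."""

import numpy as np
import pytest

from tmscoilopt import model_io as mio
from tmscoilopt import pso

from conftest import voxel_sphere


@pytest.fixture(scope="module")
def sphere_patch():
    """4 x 4 cm^2 patch on the offset surface of a 40 mm sphere apex."""
    model = voxel_sphere(40.0, 2.0)
    surf = mio.offset_surface(model, 10.0)
    apex = np.array([0.0, 0.0, 90.0])
    query = mio.SurfaceQuery(surf)
    pts, normals, _ = query.closest(apex)
    return pso.SurfacePatch(query, pts[0], normals[0], half_extent_mm=20.0)


# ---------------------------------------------------------------------------
# inertia schedule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("t,expected", [(0, 1.2), (30, 0.9), (15, 1.05)])
def test_inertia_weight_linear_schedule(t, expected):
    assert pso.inertia_weight(t, 30) == pytest.approx(expected)


def test_inertia_weight_bounds():
    ws = [pso.inertia_weight(t, 30) for t in range(31)]
    assert all(0.9 <= w <= 1.2 for w in ws)
    assert ws == sorted(ws, reverse=True)
    with pytest.raises(ValueError):
        pso.inertia_weight(31, 30)


# ---------------------------------------------------------------------------
# particle update (Eq.-level oracle with stubbed rand)
# ---------------------------------------------------------------------------

class StubRng:
    """rand() stub returning a fixed value for every draw."""

    def __init__(self, value):
        self.value = value

    def random(self, size=None):
        return np.full(size, self.value) if size else self.value


def test_update_is_stationary_at_consensus():
    pos = np.array([1.0, 2.0, 3.0, 40.0])
    p = pso.ParticleState(pos=pos.copy(), vel=np.zeros(4),
                          pbest_pos=pos.copy(), pbest_val=1.0)
    pso.update_particle(p, pos.copy(), omega=1.0, c1=2.05, c2=2.05,
                        rng=StubRng(0.5), patch=None,
                        clamp=np.full(4, 1e9))
    np.testing.assert_allclose(p.pos, pos)
    np.testing.assert_allclose(p.vel, 0.0)


def test_pure_inertia_when_learning_factors_zero():
    p = pso.ParticleState(pos=np.array([0.0, 0.0, 0.0, 0.0]),
                          vel=np.array([1.0, -2.0, 0.5, 10.0]),
                          pbest_pos=np.array([9.0, 9.0, 9.0, 90.0]),
                          pbest_val=1.0)
    pso.update_particle(p, np.array([5.0, 5.0, 5.0, 50.0]), omega=1.0,
                        c1=0.0, c2=0.0, rng=StubRng(0.5), patch=None,
                        clamp=np.full(4, 1e9))
    np.testing.assert_allclose(p.pos, [1.0, -2.0, 0.5, 10.0])


def test_hand_computed_single_update():
    """One update with rand() = 0.5 on a 1-D instance, worked by hand:

    v = 1.0*0.4 + 2.05*0.5*(2 - 1) + 2.05*0.5*(4 - 1) = 4.5
    x = 1 + 4.5 = 5.5
    """
    p = pso.ParticleState(pos=np.array([1.0, 0.0, 0.0, 0.0]),
                          vel=np.array([0.4, 0.0, 0.0, 0.0]),
                          pbest_pos=np.array([2.0, 0.0, 0.0, 0.0]),
                          pbest_val=1.0)
    gbest = np.array([4.0, 0.0, 0.0, 0.0])
    pso.update_particle(p, gbest, omega=1.0, c1=2.05, c2=2.05,
                        rng=StubRng(0.5), patch=None, clamp=np.full(4, 1e9))
    assert p.vel[0] == pytest.approx(4.5)
    assert p.pos[0] == pytest.approx(5.5)


def test_phi_update_uses_shortest_arc():
    # pbest at 170, pos at 10: shortest 180-periodic distance is -20, not +160
    assert pso.angular_difference_deg(170.0, 10.0) == pytest.approx(-20.0)
    assert pso.angular_difference_deg(10.0, 170.0) == pytest.approx(20.0)
    assert pso.angular_difference_deg(95.0, 5.0) == pytest.approx(90.0)


def test_velocity_clamp_applied():
    p = pso.ParticleState(pos=np.zeros(4), vel=np.zeros(4),
                          pbest_pos=np.array([100.0, 0.0, 0.0, 0.0]),
                          pbest_val=1.0)
    pso.update_particle(p, np.array([100.0, 0.0, 0.0, 0.0]), omega=1.0,
                        c1=2.05, c2=2.05, rng=StubRng(1.0), patch=None,
                        clamp=np.array([20.0, 20.0, 20.0, 45.0]))
    assert p.vel[0] == pytest.approx(20.0)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def test_initial_swarm_on_lattice_with_15deg_angles(sphere_patch):
    cfg = pso.PSOConfig(seed=3)
    swarm = pso.initialize_swarm(sphere_patch, cfg)
    assert len(swarm.particles) == 8
    positions = np.array([p.pos[:3] for p in swarm.particles])
    # all distinct (drawn without replacement from the 16-point lattice)
    assert len(np.unique(positions.round(3), axis=0)) == 8
    for p in swarm.particles:
        assert p.pos[3] % 15.0 == pytest.approx(0.0, abs=1e-9)
        assert 0 <= p.pos[3] < 180
        np.testing.assert_allclose(p.vel, 0.0)

    again = pso.initialize_swarm(sphere_patch, cfg)
    np.testing.assert_allclose(
        [p.pos for p in swarm.particles], [p.pos for p in again.particles])


def test_too_many_particles_rejected(sphere_patch):
    with pytest.raises(ValueError, match="lattice"):
        pso.initialize_swarm(sphere_patch, pso.PSOConfig(n_particles=17))


def test_patch_lattice_has_16_points_and_projection_stays_on_patch(sphere_patch):
    lattice = sphere_patch.lattice(10.0)
    assert lattice.shape == (16, 3)
    # projection clips a far-away point back into the patch
    far = sphere_patch.center + 100.0 * sphere_patch.e1
    proj = sphere_patch.project(far)
    rel = proj - sphere_patch.center
    assert abs(rel @ sphere_patch.e1) <= sphere_patch.half_extent + 1.0


# ---------------------------------------------------------------------------
# full runs against a stub objective
# ---------------------------------------------------------------------------

class StubObjective:
    """Smooth unimodal surrogate: peaks at a target point on the patch."""

    def __init__(self, target, target_phi=60.0):
        self.target = np.asarray(target, dtype=float)
        self.target_phi = target_phi
        self.n_calls = 0

    def __call__(self, pos):
        self.n_calls += 1
        d2 = np.sum((np.asarray(pos[:3]) - self.target) ** 2)
        dphi = pso.angular_difference_deg(pos[3], self.target_phi)
        return float(np.exp(-d2 / 400.0) * np.exp(-(dphi / 90.0) ** 2))


def _initial_pose(patch):
    from tmscoilopt.phantom import InitialPose
    return InitialPose(center=patch.center, normal=patch.normal, phi_deg=0.0)


def test_pso_finds_stub_optimum_on_patch(sphere_patch):
    """Distance-to-target stub: 10/10 seeds within 2 mm in <= 15 iterations."""
    target = sphere_patch.to_surface(8.0, -6.0)
    for seed in range(10):
        objective = lambda pos: -float(
            np.linalg.norm(np.asarray(pos[:3]) - target))
        cfg = pso.PSOConfig(seed=seed, t_max=15, improvement_tol=0.0)
        res = pso.run_pso(objective, sphere_patch,
                          _initial_pose(sphere_patch), cfg)
        assert res.iterations <= 15
        assert np.linalg.norm(res.best_pos[:3] - target) < 2.0


def test_gbest_monotone_and_matches_history(sphere_patch):
    obj = StubObjective(sphere_patch.to_surface(-5.0, 5.0))
    res = pso.run_pso(obj, sphere_patch, _initial_pose(sphere_patch),
                      pso.PSOConfig(seed=1, t_max=10))
    assert res.history == sorted(res.history)
    assert res.best_val == res.history[-1]


def test_t_max_zero_returns_best_of_initial_swarm(sphere_patch):
    obj = StubObjective(sphere_patch.to_surface(0.0, 0.0))
    cfg = pso.PSOConfig(seed=4, t_max=0)
    res = pso.run_pso(obj, sphere_patch, _initial_pose(sphere_patch), cfg)
    swarm = pso.initialize_swarm(sphere_patch, cfg, objective=StubObjective(
        sphere_patch.to_surface(0.0, 0.0)))
    assert res.iterations == 0
    assert res.best_val == pytest.approx(swarm.gbest_val)


def test_evaluation_budget_is_particles_times_iterations(sphere_patch):
    obj = StubObjective(sphere_patch.to_surface(3.0, 3.0))
    cfg = pso.PSOConfig(seed=0, t_max=8, improvement_tol=0.0)
    res = pso.run_pso(obj, sphere_patch, _initial_pose(sphere_patch), cfg)
    assert res.iterations == 8
    assert res.n_evaluations == 64
    # actual calls: 1 initial pose + 8 initialization + 64 iteration updates
    assert obj.n_calls == 1 + 8 + 64


def test_enhancement_bookkeeping(sphere_patch):
    obj = StubObjective(sphere_patch.to_surface(6.0, 0.0))
    res = pso.run_pso(obj, sphere_patch, _initial_pose(sphere_patch),
                      pso.PSOConfig(seed=2, t_max=12))
    expected = 100.0 * (res.best_val - res.initial_val) / res.initial_val
    assert res.enhancement_pct == pytest.approx(expected)
    assert 0.0 <= res.phi_deg < 180.0
    assert res.displacement_mm >= 0.0


# ---------------------------------------------------------------------------
# the real E-field objective (cache behavior)
# ---------------------------------------------------------------------------

def test_efield_objective_cache_and_positivity(gyrified_scenario):
    from tmscoilopt import coil as cl
    _, model, roi, ip = gyrified_scenario
    patch = pso.search_patch_for(model, ip)
    obj = pso.EFieldObjective(model, cl.build_foe_coil(), roi, patch)
    pos = np.append(ip.center, 30.0)
    v1 = obj(pos)
    assert v1 > 0.0                       # any valid pose induces some field
    assert obj.n_solves == 1
    # a pose snapping to the same key is served from the cache
    v2 = obj(pos + np.array([1e-6, -1e-6, 1e-6, 1e-5]))
    assert v2 == v1
    assert obj.n_solves == 1 and obj.n_cache_hits == 1
    # the 180-degree field symmetry is folded into the cache key
    assert obj(np.append(ip.center, 210.0)) == v1
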
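# Methods

## Physical model and solver

The induced field is computed in the quasi-static regime, which is
accurate at the 2.24 kHz drive frequency used throughout: displacement
currents and wave propagation are negligible, tissue is treated as a
purely conductive medium, and magnetic permeability is uniform (tissue is
non-magnetic), so the coil's field is unperturbed by the head. With a
single-phase sinusoidal drive the complex phasor problem collapses to one
real solve for the scaled potential ψ (units V·s):

∇·σ(∇ψ + A) = 0,  |E| = ω|A + ∇ψ|,

with A the amplitude of the coil's vector potential. The scalar-potential
finite-difference (SPFD) discretization places ψ at voxel corners. The
conductance of the edge joining two adjacent nodes is the arithmetic mean
of the conductivities of the four voxels sharing that edge, times edge
cross-section over length (= h for cubic voxels of side h); harmonic
averaging was deliberately not used. The source term integrates the
along-edge component of A, sampled directly at edge midpoints (no
interpolation from voxel centers, which removes one discretization error
from the right-hand side). The result is a symmetric septa-diagonal
system whose rows sum to zero — a pure-Neumann problem whose nullspace
(one additive constant per connected conducting component) is fixed by a
mean-zero projection rather than by grounding a node, preserving symmetry
and making solutions reproducible bit-for-bit.

The solve uses conjugate gradients with a Jacobi (diagonal)
preconditioner. An incomplete-LU preconditioner was evaluated and
rejected: ILU factors of a symmetric matrix are not themselves a
symmetric positive-definite operator, which conjugate gradients requires,
and the diagonally preconditioned iteration already converges in roughly
70–150 iterations on the benchmark geometries. The default relative
residual tolerance is 1e-8 (tightening to 1e-10 changes |E| by well under
0.1%); non-convergence within the iteration cap raises an error carrying
the final residual.

|E| is reported at voxel centers by averaging each component's four
like-oriented edge values; air voxels are NaN. On the standard analytic
oracle — a homogeneous conducting sphere in a uniform axial B field,
where |E| = ωB₀ρ/2 — the solver's interior relative L2 error is 0.25% at
2 mm spacing and 0.07% at 1 mm.

Tissue conductivities ship as a packaged CSV (31 tissues at 2.24 kHz,
including grey matter 0.104 S/m, CSF 2.0 S/m, skin 2.0e-4 S/m); label 0
and "Internal air" are non-conducting.

## Coil and placement

The coil is a single-turn figure-of-eight: two 20 mm-radius loops
tangent at the coil origin along the local X axis, opposite circulation,
64 straight segments per loop (on-axis field accurate to ~1%), driven at
1 kA, 2.24 kHz. The 20 mm loop radius is a documented choice — about
half the diameter of a conventional clinical figure-of-eight — and
absolute V/m outputs scale with it, which is why no absolute field values
are benchmarked. The vector potential is the Biot–Savart midpoint sum
over segments.

Placement constrains the coil to a surface at a constant 10 mm from the
scalp (the protective-shell gap). That offset surface is extracted as the
10 mm iso-level of the Euclidean distance transform of the head mask
(shifted half a voxel to account for the EDT measuring to voxel centers),
which stays well defined over concavities where displacing mesh vertices
along normals would self-intersect. The scalp itself is the marching-cubes
boundary of the largest 6-connected nonzero-label component, extracted
from a lightly smoothed (σ = 1 voxel) indicator so that surface areas
track the underlying smooth anatomy instead of the voxel staircase.
Rotation zero aligns the coil's long axis with the projection of world +X
onto the tangent plane (falling back to +Y, with a warning, where the
normal is parallel to X); a 180° rotation maps the figure-of-eight onto
itself with reversed current, so field magnitudes have a 180° period in φ
and results report φ modulo 180°.

## Optimizer

Poses (x, y, z, φ) live on a 4 × 4 cm² patch of the offset surface
centered above the target. Defaults: 8 particles, c₁ = c₂ = 2.05,
inertia annealed linearly 1.2 → 0.9 over t_max = 30, velocity clamped to
20 mm per spatial axis (half the patch extent) and 45° in φ.
Initialization draws particle positions without replacement from the
16-point, 10 mm lattice on the patch and rotation angles from multiples
of 15°, with zero initial velocities. During updates φ is continuous;
angular differences in the velocity terms take the shortest arc modulo
180°. Constraints are handled by project-and-continue: after each update
the position is clipped in the patch's tangent coordinates and snapped to
the nearest surface point; the velocity is left unchanged.

Termination — a rule left open by the problem statement — is defined as
the first iteration at which the relative global-best improvement over
the last 3 iterations falls below 1%; "iterations to converge" is that
iteration index. The reported evaluation budget is iterations ×
particles, matching the bookkeeping convention of the benchmark this
mirrors (initialization evaluations are tracked separately). Repeated
pose evaluations are served from a cache keyed at 0.5 mm / 1° resolution;
the φ-period symmetry is folded into the key.

The objective is the arithmetic mean of |E| over the 4 ROI voxels — not
the ROI maximum — and both the optimized and initial-pose values entering
the enhancement percentage use the same statistic.

The exhaustive oracle enumerates an extent/spacing-per-side lattice of
cell centers crossed with an angle list; 18 × 18 mm at 1 mm with 12
angles gives exactly 3,888 poses (the 19-points-per-side reading would
give 4,332 and is rejected by that count). The 12 angles span [0°, 180°)
in 15° steps, consistent with the field's φ-period. Histograms of
enumerated objectives use 30 equal-width bins over the observed range.

## Synthetic phantom

The phantom stands in for segmented anatomical head models: a 50 mm
sphere with skin (4 mm), skull (6 mm), CSF (4 mm), grey matter (6 mm)
shells and a white-matter core, voxelized at 2 mm by default (1 mm is
supported; 2 mm keeps a full optimization study within minutes on one
CPU). Shell thicknesses are roughly anatomical proportions scaled to the
50 mm radius. Gyrification modulates the pial and grey–white interfaces
together by a·sin(2πs/λ + phase), with s the great-circle arc length
around a fixed gyral axis, so the cortical ribbon keeps constant
thickness while its area grows with amplitude a (defaults a = 3 mm,
λ = 12 mm; the phase derives from the seed). The gyral axis is tilted 30°
from world Y toward X: with the axis at Y the scenario is mirror-symmetric
about the coil's rotation-zero reference and the conventional initial
pose is exactly optimal, leaving the optimizer nothing to find; the
oblique axis reproduces the gyral-orientation dependence that makes
orientation optimization worthwhile on real anatomy.

The scenario anchor ("C4-like", in lieu of a 10–20 EEG system on a
sphere) is 45° lateral from the apex in the +X hemisphere. The ROI is
the 2 × 2 column patch of outermost grey-matter voxels on the gyral crown
nearest that anchor (4 voxels; at 1 mm spacing this is the 2 × 2 mm²
four-voxel target, at the default 2 mm spacing the patch is nominally
4 × 4 mm²). The initial pose projects the ROI center radially onto the
offset surface with φ = 0.

What the phantom does *not* emulate: anatomically realistic gyral graphs,
sulcal CSF geometry, tissue heterogeneity beyond five shells, or
inter-subject variability. Passing tests on it demonstrate the solver's
physics, the optimizer's mechanics and the metrics' monotone response to
folding — not clinical field magnitudes, which additionally depend on
unavailable real head models and exact coil dimensions.

## Cortical complexity metrics

The local gyrification index is the pial surface area divided by the
smoothed-hull area, both restricted to the column under the 4 × 4 cm²
search surface. The hull is the marching-cubes surface of the brain mask
morphologically closed with a 15 mm spherical element (implemented by two
Euclidean distance transforms) — a deterministic stand-in for interactive
smoothed-surface tracing. An unfolded cortex scores 1.00 within mesh
tolerance; the index rises strictly with gyral amplitude.

The fractal dimension uses aligned-grid box counting at sizes 1, 2, 4,
8, 16 with the negated ordinary-least-squares slope of log₂count against
log₂size (the two-size form is the special case). Sizes exceeding the
mask extent are dropped with a warning. The counted structure is the
extracted pial surface under the patch, rasterized at a fixed 1 mm pitch:
the marching-cubes surface is sub-voxel accurate, so this keeps the FD
estimate from degrading on coarser label grids. Anchors: a filled block
scores 3.0, a one-voxel sheet 2.0, a line 1.0, each within ±0.1. On the
2 mm phantom the patch FD runs ≈ 1.84 (smooth) to ≈ 1.89 (4 mm
amplitude), strictly increasing with folding with fit R² ≈ 1.0; the
box-placement rule (aligned, not sliding) and the rasterization pitch are
fixed conventions of this implementation.

Spearman rank correlations between {lGI, FD} and {mean enhancement, mean
iterations} are reported per model with two-sided p-values; a constant
column yields an undefined correlation, reported as NaN.

## Problem sizes and numerical choices

Benchmarks and tests run the 50 mm / 2 mm phantom (≈ 66,000 conducting
voxels, ≈ 75,000 solver unknowns; one pose evaluation ≈ 0.7 s: vector
potential on conducting edges plus a preconditioned CG solve). The
acceptance benchmark performs five seeded swarm runs plus a 216-pose
exhaustive search (18 × 18 mm at 3 mm, 6 angles). Degenerate inputs are
rejected with specific errors: anisotropic voxels, unknown tissue labels,
non-conducting grids, ROIs touching air, swarms larger than the
initialization lattice, and candidate poses beyond the snap radius.

Reproducibility: phantom generation, swarm initialization and updates are
driven by explicit integer seeds through separate generators; reruns with
the same configuration produce byte-identical result tables.
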
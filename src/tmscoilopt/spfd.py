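"""Quasi-static scalar-potential finite-difference (SPFD) solver.

At stimulation frequencies of a few kHz the induced field in tissue is
quasi-static: displacement currents are negligible and the electric field
splits into an impressed part from the coil and a charge-redistribution
part,

    E = -dA/dt - grad(psi_t).

For a single-phase sinusoidal drive the complex problem reduces to one real
solve for the scaled potential ``psi`` (units V*s):

    div( sigma * (grad(psi) + A) ) = 0,      |E| = omega * |A + grad(psi)|,

with ``A`` the amplitude of the coil's vector potential.  Discretized on
the voxel grid with potentials at voxel corners (nodes), this yields a
symmetric septa-diagonal system: the conductance of the edge between two
adjacent nodes is the mean conductivity of the 4 voxels sharing that edge
times the edge cross-section over length.  The system is pure-Neumann
(rows sum to zero); the additive-constant nullspace is fixed by a
mean-zero constraint per connected conducting component rather than by
grounding a node, which preserves symmetry.

The solve uses preconditioned conjugate gradients with an incomplete-LU
preconditioner (diagonal fallback), converging the relative residual below
``rtol`` (default 1e-8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse import linalg as sla

from .coil import AVolume
from .model_io import SigmaVolume

logger = logging.getLogger("tmscoilopt")

DEFAULT_RTOL = 1e-8
DEFAULT_MAX_ITER = 4000


class SolverError(RuntimeError):
    """Raised when the iterative solve fails to converge."""


# ---------------------------------------------------------------------------
# Operator: everything that depends on sigma only (reused across coil poses)
# ---------------------------------------------------------------------------

class SPFDOperator:
    """Grid-and-conductivity part of the SPFD system.

    Built once per head model; the per-pose right-hand side from the coil's
    vector potential is assembled against it.  Holds the edge conductances,
    the node Laplacian over conducting nodes, the connected-component
    structure used for gauge fixing, and a reusable preconditioner.
    """

    def __init__(self, sigma: SigmaVolume):
        sig = np.asarray(sigma.sigma, dtype=float)
        if not np.any(sig > 0):
            raise ValueError("grid has no conducting voxels")
        self.sigma = sigma
        self.spacing = float(sigma.spacing)
        self.origin = np.asarray(sigma.origin, dtype=float)
        self.shape_vox = sig.shape
        self.shape_nodes = tuple(n + 1 for n in sig.shape)
        h = self.spacing * 1e-3  # mm -> m

        # edge conductance per family: mean sigma of the 4 voxels sharing
        # the edge, times cross-section over length (= h for cubic voxels)
        self.edge_s: list[np.ndarray] = []
        self.edge_masks: list[np.ndarray] = []
        for axis in range(3):
            t1, t2 = [a for a in range(3) if a != axis]
            pad = [(0, 0)] * 3
            pad[t1] = (1, 1)
            pad[t2] = (1, 1)
            sp = np.pad(sig, pad)
            sl0 = [slice(None)] * 3
            sbar = np.zeros(_edge_shape(self.shape_vox, axis))
            for d1 in (0, 1):
                for d2 in (0, 1):
                    sl = list(sl0)
                    n1 = self.shape_vox[t1] + 1
                    n2 = self.shape_vox[t2] + 1
                    sl[t1] = slice(d1, d1 + n1)
                    sl[t2] = slice(d2, d2 + n2)
                    sbar += sp[tuple(sl)]
            sbar *= 0.25
            self.edge_s.append(sbar * h)
            self.edge_masks.append(sbar > 0)

        # node bookkeeping
        n_nodes = int(np.prod(self.shape_nodes))
        lowers, uppers, weights = [], [], []
        for axis in range(3):
            mask = self.edge_masks[axis]
            idx = np.argwhere(mask)
            lo = np.ravel_multi_index(idx.T, self.shape_nodes)
            up_idx = idx.copy()
            up_idx[:, axis] += 1
            up = np.ravel_multi_index(up_idx.T, self.shape_nodes)
            lowers.append(lo)
            uppers.append(up)
            weights.append(self.edge_s[axis][mask])
        lo = np.concatenate(lowers)
        up = np.concatenate(uppers)
        w = np.concatenate(weights)

        conducting = np.zeros(n_nodes, dtype=bool)
        conducting[lo] = True
        conducting[up] = True
        self.node_flat = np.flatnonzero(conducting)          # grid -> list
        self.n_dof = len(self.node_flat)
        node_map = np.full(n_nodes, -1, dtype=np.int64)      # flat -> dof
        node_map[self.node_flat] = np.arange(self.n_dof)
        self.node_map = node_map
        self._edge_lo = [node_map[l] for l in lowers]
        self._edge_up = [node_map[u] for u in uppers]

        li, ui = node_map[lo], node_map[up]
        rows = np.concatenate([li, ui, li, ui])
        cols = np.concatenate([li, ui, ui, li])
        vals = np.concatenate([w, w, -w, -w])
        self.matrix = sparse.coo_matrix(
            (vals, (rows, cols)), shape=(self.n_dof, self.n_dof)).tocsr()

        n_comp, labels = csgraph.connected_components(self.matrix, directed=False)
        self.component_labels = labels
        self.components = [np.flatnonzero(labels == c) for c in range(n_comp)]

        self._precond: sla.LinearOperator | None = None

    # -- gauge -------------------------------------------------------------
    def project_nullspace(self, x: np.ndarray) -> np.ndarray:
        """Subtract the per-component mean (the pure-Neumann nullspace)."""
        out = x.copy()
        for comp in self.components:
            out[comp] -= out[comp].mean()
        return out

    # -- preconditioner ----------------------------------------------------
    def preconditioner(self) -> sla.LinearOperator:
        """Jacobi (diagonal) preconditioner.

        CG requires a symmetric positive-definite preconditioner, which
        rules out incomplete-LU solves of the (singular, symmetric) Neumann
        matrix; the diagonal scaling keeps the strong conductivity
        contrasts between tissues from degrading convergence.
        """
        if self._precond is None:
            d = self.matrix.diagonal()
            dinv = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 0.0)
            self._precond = sla.LinearOperator(
                (self.n_dof, self.n_dof), matvec=lambda x: dinv * x)
        return self._precond

    # -- per-pose right-hand side -------------------------------------------
    def assemble_rhs(self, A: AVolume) -> np.ndarray:
        """sigma-weighted edge integrals of the vector potential.

        For the edge from node n to node m, the source flux is
        ``s_e * h * A_e`` with ``A_e`` the along-edge component of A at the
        edge midpoint; it enters +ve at n and -ve at m.
        """
        h = self.spacing * 1e-3
        b = np.zeros(self.n_dof)
        for axis in range(3):
            mask = self.edge_masks[axis]
            flux = self.edge_s[axis][mask] * h * A.edge[axis][mask]
            np.add.at(b, self._edge_lo[axis], flux)
            np.add.at(b, self._edge_up[axis], -flux)
        return b


def _edge_shape(shape_vox: tuple[int, int, int], axis: int) -> tuple[int, int, int]:
    out = [n + 1 for n in shape_vox]
    out[axis] = shape_vox[axis]
    return tuple(out)


# ---------------------------------------------------------------------------
# Spec-level system / results containers
# ---------------------------------------------------------------------------

@dataclass
class SPFDSystem:
    """Assembled sparse system for one coil pose."""

    operator: SPFDOperator
    rhs: np.ndarray
    frequency: float

    @property
    def matrix(self) -> sparse.csr_matrix:
        return self.operator.matrix


@dataclass
class PotentialVolume:
    """Scaled scalar potential psi (V*s) on the node grid; NaN off-tissue."""

    psi: np.ndarray
    spacing: float
    origin: np.ndarray
    iterations: int = 0
    residual: float = 0.0
    converged: bool = True


@dataclass
class EFieldVolume:
    """Per-voxel |E| (V/m); NaN on non-conducting voxels."""

    e: np.ndarray
    spacing: float
    origin: np.ndarray
    frequency: float
    metadata: dict = field(default_factory=dict)


def assemble(sigma: SigmaVolume, A: AVolume, frequency: float) -> SPFDSystem:
    """Build the septa-diagonal SPFD system for one conductivity map and coil pose."""
    op = sigma_operator(sigma)
    return SPFDSystem(operator=op, rhs=op.assemble_rhs(A), frequency=frequency)


def sigma_operator(sigma: SigmaVolume) -> SPFDOperator:
    """Operator for a conductivity map (cache this across poses)."""
    return SPFDOperator(sigma)


def solve(system: SPFDSystem, rtol: float = DEFAULT_RTOL,
          max_iter: int = DEFAULT_MAX_ITER) -> PotentialVolume:
    """Solve for psi by preconditioned CG with mean-zero gauge."""
    op = system.operator
    b = op.project_nullspace(system.rhs)
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        x = np.zeros(op.n_dof)
        it = 0
    else:
        counter = _IterCounter()
        x, info = sla.cg(op.matrix, b, rtol=rtol, atol=0.0,
                         maxiter=max_iter, M=op.preconditioner(),
                         callback=counter)
        it = counter.n
        if info > 0:
            res = np.linalg.norm(op.matrix @ x - b) / bnorm
            raise SolverError(
                f"CG did not converge in {max_iter} iterations "
                f"(relative residual {res:.3e})")
    x = op.project_nullspace(x)
    res = np.linalg.norm(op.matrix @ x - b) / bnorm if bnorm else 0.0
    logger.debug("SPFD solve: %d CG iterations, relative residual %.2e",
                 it, res)

    psi = np.full(int(np.prod(op.shape_nodes)), np.nan)
    psi[op.node_flat] = x
    return PotentialVolume(psi=psi.reshape(op.shape_nodes), spacing=op.spacing,
                           origin=op.origin.copy(), iterations=it,
                           residual=float(res), converged=True)


class _IterCounter:
    def __init__(self):
        self.n = 0

    def __call__(self, _xk):
        self.n += 1


def efield(psi: PotentialVolume, A: AVolume, sigma: SigmaVolume,
           frequency: float) -> EFieldVolume:
    """|E| = omega * |A + grad(psi)| at voxel centers; NaN in air.

    Edge-sampled quantities (the along-edge A component and the finite
    difference of psi) are averaged over the 4 like-oriented edges of each
    voxel to obtain the center value per component.
    """
    h = psi.spacing * 1e-3
    p = psi.psi
    omega = 2.0 * np.pi * frequency
    comp2 = np.zeros(sigma.sigma.shape)
    for axis in range(3):
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[axis] = slice(1, None)
        sl_lo[axis] = slice(None, -1)
        grad = (p[tuple(sl_hi)] - p[tuple(sl_lo)]) / h  # on axis-edge grid
        total = grad + A.edge[axis]
        # average the 4 like-oriented edges of each voxel
        t1, t2 = [a for a in range(3) if a != axis]
        c = np.zeros(sigma.sigma.shape)
        for d1 in (0, 1):
            for d2 in (0, 1):
                sl = [slice(None)] * 3
                sl[t1] = slice(d1, sigma.sigma.shape[t1] + d1)
                sl[t2] = slice(d2, sigma.sigma.shape[t2] + d2)
                c += total[tuple(sl)]
        comp2 += (0.25 * c) ** 2
    e = omega * np.sqrt(comp2)
    e[sigma.sigma == 0] = np.nan
    return EFieldVolume(e=e, spacing=psi.spacing, origin=psi.origin.copy(),
                        frequency=frequency)


def roi_statistic(e: EFieldVolume, roi_voxels: np.ndarray) -> float:
    """Arithmetic mean of |E| over the ROI voxels (V/m)."""
    roi_voxels = np.asarray(roi_voxels, dtype=int)
    vals = e.e[roi_voxels[:, 0], roi_voxels[:, 1], roi_voxels[:, 2]]
    if np.any(np.isnan(vals)):
        raise ValueError("ROI contains non-conducting voxels; ROI misplaced")
    return float(vals.mean())
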
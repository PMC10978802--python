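"""Quasi-static large-deformation finite-element engine.

Total Lagrangian formulation on 8-node trilinear hexahedra with 2x2x2
Gauss quadrature.  Near-incompressibility is handled by the mean-dilatation
(B-bar) treatment: the deviatoric neo-Hookean term is integrated pointwise
while the volumetric energy ``(1/D1)(J-1)^2`` is evaluated at the
element-average dilatation ``Jbar`` (one volumetric constraint per element),
the standard remedy for volumetric locking of displacement elements.

The global problem is solved by Newton-Raphson with load stepping and
automatic step cutback; every linear solve uses a sparse LU factorization.
The solver contains no randomness: repeated runs are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import reverse_cuthill_mckee

from .contact import contact_contribution, face_contact_contribution
from .materials import ElementInversionError, NeoHookeanParams
from .mesh import GAUSS_POINTS, HexMesh, shape_gradients_natural

logger = logging.getLogger(__name__)

__all__ = [
    "SolverConfig",
    "SolutionState",
    "DirichletBC",
    "ContactPair",
    "FEProblem",
    "element_forces",
    "newton_solve",
]


@dataclass
class SolverConfig:
    """Newton/continuation controls."""

    n_load_steps: int = 25
    newton_tol: float = 1e-8  # relative residual norm
    max_newton_iters: int = 30
    step_cutback: float = 0.5
    max_cutbacks: int = 10
    abs_tol_floor: float = 1e-9  # nN, guards the unloaded first step
    #: reuse the LU factorization across iterations (modified Newton) and
    #: refactor only on stalls; set False for textbook full Newton (used by
    #: the quadratic-convergence diagnostics)
    reuse_factorization: bool = True
    refactor_stall_ratio: float = 0.2  # refactor unless residual drops 5x
    refactor_every: int = 8

    def __post_init__(self) -> None:
        if self.n_load_steps < 1:
            raise ValueError("n_load_steps must be >= 1")
        if not self.newton_tol > 0:
            raise ValueError("newton_tol must be > 0")
        if not (0.0 < self.step_cutback < 1.0):
            raise ValueError("step_cutback must lie in (0, 1)")


@dataclass
class SolutionState:
    """Converged (or last attempted) state at one load level."""

    load_factor: float
    displacements: np.ndarray  # (N, 3) µm
    reaction: float  # total indenter force, full model (nN)
    converged: bool
    residual_history: list[float]
    contact_states: list = field(default_factory=list)
    strain_energy: float = 0.0  # full model (nN µm)


@dataclass
class DirichletBC:
    """Prescribed displacement component on a node set.

    The imposed value is ``value * load_factor`` (µm); ``value`` may be a
    scalar or a per-node array aligned with ``nodes``.
    """

    nodes: np.ndarray
    component: int  # 0=x, 1=y, 2=z
    value: float | np.ndarray = 0.0


@dataclass
class ContactPair:
    """A rigid surface acting on a candidate node set.

    ``motion`` (µm) displaces the surface reference position by
    ``motion * load_factor`` (used for the descending indenter sphere).
    """

    surface: object
    nodes: np.ndarray
    penalty: np.ndarray  # per candidate node (nN/µm)
    motion: np.ndarray = field(default_factory=lambda: np.zeros(3))
    is_indenter: bool = False
    #: optional gap band (µm) in which separated nodes keep their stiffness
    #: block in the tangent (see ``contact_contribution``); zero keeps the
    #: tangent exactly consistent
    stiffness_band: float = 0.0
    #: optional (F, 4) outward-wound surface quads; when given the penalty
    #: is integrated at face Gauss points (mesh-convergent contact) with
    #: ``penalty_pressure`` (kPa/µm) per face instead of nodal springs
    faces: np.ndarray | None = None
    penalty_pressure: np.ndarray | None = None


class Discretization:
    """Precomputed element data for one mesh + material assignment."""

    def __init__(self, mesh: HexMesh, materials: dict[str, NeoHookeanParams]):
        self.mesh = mesh
        X = mesh.nodes[mesh.elements]  # (E,8,3)
        dN_nat = shape_gradients_natural(GAUSS_POINTS)  # (Q,8,3)
        # J_map[e,q,k,d] = dX_k/dxi_d
        Jmap = np.einsum("eak,qad->eqkd", X, dN_nat)
        detJ = np.linalg.det(Jmap)
        if detJ.min() <= 0:
            bad = np.unique(np.nonzero(detJ.min(axis=1) <= 0)[0])
            raise ElementInversionError(f"non-positive reference Jacobian in elements {bad}")
        Jinv = np.linalg.inv(Jmap)  # [e,q,d,k] = dxi_d/dX_k
        self.dNdX = np.einsum("qad,eqdk->eqak", dN_nat, Jinv)  # (E,Q,8,3)
        self.wdet = detJ  # unit Gauss weights
        self.V0 = detJ.sum(axis=1)

        C10 = np.empty(mesh.n_elements)
        D1 = np.empty(mesh.n_elements)
        for name in np.unique(mesh.element_compartment):
            if name not in materials:
                raise KeyError(f"no material assigned to compartment {name!r}")
            m = mesh.element_compartment == name
            C10[m] = materials[name].C10
            D1[m] = materials[name].D1
        self.C10, self.D1 = C10, D1

        edof = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(-1, 24)
        self.rows = np.repeat(edof, 24, axis=1).ravel()
        self.cols = np.tile(edof, (1, 24)).ravel()
        self.edof = edof
        self.ndof = 3 * mesh.n_nodes

    # -- kinematics + constitutive response, vectorized over all elements
    def assemble(self, U: np.ndarray, tangent: bool = True):
        """Internal force vector, energy and (optionally) tangent matrix."""
        mesh = self.mesh
        dN, w = self.dNdX, self.wdet
        u_e = U.reshape(-1, 3)[mesh.elements]  # (E,8,3)

        F = np.einsum("eai,eqaK->eqiK", u_e, dN)
        F[..., 0, 0] += 1.0
        F[..., 1, 1] += 1.0
        F[..., 2, 2] += 1.0
        J = np.linalg.det(F)
        if J.min() <= 0:
            bad = np.unique(np.nonzero(J.min(axis=1) <= 0)[0])
            raise ElementInversionError(f"element inversion (det F <= 0) in elements {bad}")
        Finv = np.linalg.inv(F)
        trC = np.einsum("eqiK,eqiK->eq", F, F)
        A = J ** (-2.0 / 3.0)
        c10 = self.C10[:, None]

        # deviatoric 2nd PK stress S = 2 C10 A (I - trC/3 Cinv), Cinv = Finv Finv^T
        Cinv = np.einsum("eqKi,eqLi->eqKL", Finv, Finv)
        S = np.zeros_like(F)
        S[..., 0, 0] = S[..., 1, 1] = S[..., 2, 2] = 1.0
        S = 2.0 * (c10 * A)[..., None, None] * (S - (trC / 3.0)[..., None, None] * Cinv)
        P = np.einsum("eqiK,eqKL->eqiL", F, S)
        f_dev = np.einsum("eq,eqiL,eqaL->eai", w, P, dN)

        # mean dilatation volumetric term
        Jbar = (w * J).sum(axis=1) / self.V0
        p = (2.0 / self.D1) * (Jbar - 1.0)  # (E,)
        FinvT = np.swapaxes(Finv, -1, -2)
        gvec = np.einsum("eq,eqiK,eqaK->eai", w * J, FinvT, dN)  # (E,8,3)
        f_el = f_dev + p[:, None, None] * gvec

        energy = float(
            (w * (c10 * (A * trC - 3.0))).sum()
            + ((1.0 / self.D1) * (Jbar - 1.0) ** 2 * self.V0).sum()
        )

        f_int = np.zeros(self.ndof)
        np.add.at(f_int, self.edof.reshape(-1, 8, 3), f_el)

        if not tangent:
            return f_int, energy, None

        # --- consistent tangent
        P1 = np.einsum("eqaK,eqiK->eqai", dN, F)
        P2 = np.einsum("eqaK,eqKi->eqai", dN, Finv)  # dN_a . F^{-1} -> F^{-T} row
        sab = np.einsum("eqai,eqbi->eqab", P2, P2)
        gS = np.einsum("eqaK,eqKL,eqbL->eqab", dN, S, dN)

        coef = 4.0 * c10 * A  # (E,Q)
        w_ = w
        # geometric (deviatoric) part: delta_ij gS_ab
        Kg = np.einsum("eq,eqab->eab", w_, gS)
        K_dev = np.zeros((mesh.n_elements, 8, 3, 8, 3))
        idx = np.arange(3)
        K_dev[:, :, idx, :, idx] += Kg[None, :, :, :]
        # material (deviatoric) parts
        K_dev -= np.einsum("eq,eqai,eqbj->eaibj", w_ * coef / 3.0, P1, P2)
        K_dev -= np.einsum("eq,eqai,eqbj->eaibj", w_ * coef / 3.0, P2, P1)
        K_dev += np.einsum("eq,eqai,eqbj->eaibj", w_ * coef * trC / 9.0, P2, P2)
        Ks = np.einsum("eq,eqab->eab", w_ * coef * trC / 6.0, sab)
        K_dev[:, :, idx, :, idx] += Ks[None, :, :, :]
        K_dev += np.einsum("eq,eqaj,eqbi->eaibj", w_ * coef * trC / 6.0, P2, P2)

        # volumetric: (2/D1)/V0 g g^T + p * H
        K_vol = (2.0 / self.D1 / self.V0)[:, None, None, None, None] * np.einsum(
            "eai,ebj->eaibj", gvec, gvec
        )
        K_vol += p[:, None, None, None, None] * (
            np.einsum("eq,eqai,eqbj->eaibj", w_ * J, P2, P2)
            - np.einsum("eq,eqaj,eqbi->eaibj", w_ * J, P2, P2)
        )

        Kdata = (K_dev + K_vol).reshape(-1, 576).ravel()
        Kmat = sp.coo_matrix(
            (Kdata, (self.rows, self.cols)), shape=(self.ndof, self.ndof)
        ).tocsr()
        return f_int, energy, Kmat


def element_forces(
    node_coords: np.ndarray,
    nodal_displacements: np.ndarray,
    params: NeoHookeanParams,
):
    """Internal force vector (8,3) and consistent tangent (24,24) of one hex.

    Convenience wrapper over the vectorized kernels for verification tests.
    """
    mesh = HexMesh(
        nodes=np.asarray(node_coords, float),
        elements=np.arange(8, dtype=int)[None, :],
        element_compartment=np.array(["pseudocoelom"], dtype=object),
        node_sets={},
        min_edge_contact=np.nan,
        outer_node_area=np.zeros(8),
        level=0,
        geometry=None,
    )
    disc = Discretization(mesh, {"pseudocoelom": params})
    f, _, K = disc.assemble(np.asarray(nodal_displacements, float).ravel())
    return f.reshape(8, 3), K.toarray()


@dataclass
class FEProblem:
    """A meshed body with boundary conditions and rigid contact pairs."""

    mesh: HexMesh
    materials: dict[str, NeoHookeanParams]
    dirichlet: list[DirichletBC] = field(default_factory=list)
    contacts: list[ContactPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.disc = Discretization(self.mesh, self.materials)
        fixed = []
        for bc in self.dirichlet:
            fixed.append(3 * np.asarray(bc.nodes, int) + bc.component)
        self.fixed_dofs = (
            np.unique(np.concatenate(fixed)) if fixed else np.empty(0, dtype=int)
        )
        mask = np.ones(self.disc.ndof, dtype=bool)
        mask[self.fixed_dofs] = False
        self.free_dofs = np.nonzero(mask)[0]
        self._full2free = np.full(self.disc.ndof, -1, dtype=int)
        self._full2free[self.free_dofs] = np.arange(self.free_dofs.size)

    def prescribed_U(self, load_factor: float) -> np.ndarray:
        U = np.zeros(self.disc.ndof)
        for bc in self.dirichlet:
            U[3 * np.asarray(bc.nodes, int) + bc.component] = (
                np.asarray(bc.value) * load_factor
            )
        return U

    def _contact_terms(self, U: np.ndarray, load_factor: float):
        """External contact forces, tangent blocks and states.

        Returns ``(f_ext, Kc, blocks, states, reaction)`` where ``blocks``
        maps node id -> (free-dof indices, restricted tangent block), the
        representation consumed by the Woodbury-corrected linear solver.
        """
        mesh = self.mesh
        f_ext = np.zeros(self.disc.ndof)
        rows, cols, data = [], [], []
        states = []
        blocks: dict[tuple, tuple] = {}  # sortable keys -> (free dofs, block)
        reaction = 0.0
        import copy

        for pi, pair in enumerate(self.contacts):
            surf = copy.copy(pair.surface)
            if hasattr(surf, "center"):
                surf.center = surf.center + pair.motion * load_factor
            else:
                surf.origin = surf.origin + pair.motion * load_factor
            if pair.faces is not None:
                xcur = mesh.nodes + U.reshape(-1, 3)
                nf, Kf, st = face_contact_contribution(
                    xcur, pair.faces, surf, pair.penalty_pressure
                )
                fdofs = (3 * pair.faces[:, :, None] + np.arange(3)).reshape(-1, 12)
                np.add.at(f_ext, fdofs.ravel(), nf.reshape(-1, 12).ravel())
                rows.append(np.repeat(fdofs, 12, axis=1).ravel())
                cols.append(np.tile(fdofs, (1, 12)).ravel())
                data.append(Kf.ravel())
                states.append(st)
                ffree = self._full2free[fdofs]  # (F,12)
                nonzero = np.abs(Kf).max(axis=(1, 2)) > 0
                for fi in np.nonzero(nonzero)[0]:
                    keep = ffree[fi] >= 0
                    if keep.any():
                        blocks[("f", pi, int(fi))] = (
                            ffree[fi][keep],
                            Kf[fi][np.ix_(keep, keep)],
                        )
            else:
                ids = np.asarray(pair.nodes, int)
                x = mesh.nodes[ids] + U.reshape(-1, 3)[ids]
                forces, Kb, st = contact_contribution(
                    x, ids, surf, pair.penalty, stiffness_band=pair.stiffness_band
                )
                dof = (3 * ids[:, None] + np.arange(3)).astype(int)
                np.add.at(f_ext, dof.ravel(), forces.ravel())
                rows.append(np.repeat(dof, 3, axis=1).ravel())
                cols.append(np.tile(dof, (1, 3)).ravel())
                data.append(Kb.ravel())
                states.append(st)
                fdof = self._full2free[dof]  # (n,3), -1 where fixed
                for i, node in enumerate(ids):
                    keep = fdof[i] >= 0
                    if keep.any():
                        key = ("n", 0, int(node))
                        prev = blocks.get(key)
                        B = Kb[i][np.ix_(keep, keep)]
                        if prev is not None:
                            B = prev[1] + B
                        blocks[key] = (fdof[i][keep], B)
            if pair.is_indenter:
                reaction += st.total_force * mesh.symmetry_factor
        if rows:
            Kc = sp.coo_matrix(
                (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
                shape=(self.disc.ndof, self.disc.ndof),
            ).tocsr()
        else:
            Kc = None
        return f_ext, Kc, blocks, states, reaction


class _LULinearSolver:
    """Sparse LU with a fixed fill-reducing (RCM) permutation, reusable
    across Newton iterations while the stiffness pattern is unchanged.

    Contact-stiffness changes between refactorizations (active-set growth,
    normal reorientation) are applied as low-rank Woodbury corrections, so
    a contact activation does not force an expensive refactorization; the
    correction makes the applied tangent exact for the current contact
    state while only the bulk-elasticity drift remains approximated (and
    triggers refactorization through the stall test).
    """

    _BLOCK_TOL = 1e-6  # relative change below which a block is "unchanged"

    def __init__(self) -> None:
        self.perm: np.ndarray | None = None
        self.lu = None
        self.base_blocks: dict[int, np.ndarray] = {}
        self.updates: list[tuple[np.ndarray, np.ndarray]] = []
        self._zcols: dict[int, np.ndarray] = {}

    def refactor(self, Kff: sp.spmatrix, contact_blocks: dict[int, tuple]) -> None:
        """Factor ``Kff``; remember the contact blocks it contains.

        ``contact_blocks`` maps node id -> (free-dof indices (k,), block
        (k,k)) already restricted to free dofs and included in ``Kff``.
        """
        Kff = Kff.tocsr()
        if self.perm is None:
            self.perm = reverse_cuthill_mckee(Kff, symmetric_mode=True)
        Kp = Kff[self.perm][:, self.perm].tocsc()
        self.lu = spla.splu(Kp, permc_spec="NATURAL")
        self.base_blocks = {n: (d.copy(), B.copy()) for n, (d, B) in contact_blocks.items()}
        self.updates = []
        self._zcols = {}

    def set_current_blocks(self, contact_blocks: dict[int, tuple]) -> None:
        """Register the contact blocks of the current iterate; differences
        from the factored state become Woodbury corrections."""
        updates = []
        for key in sorted(contact_blocks.keys() | self.base_blocks.keys()):
            cur = contact_blocks.get(key)
            base = self.base_blocks.get(key)
            dofs = cur[0] if cur is not None else base[0]
            B = cur[1] if cur is not None else np.zeros_like(base[1])
            B0 = base[1] if base is not None else np.zeros_like(B)
            if B.shape != B0.shape:  # pragma: no cover - differing fixities
                continue
            dB = B - B0
            scale = max(np.abs(B).max(), np.abs(B0).max(), 1.0)
            if np.abs(dB).max() > self._BLOCK_TOL * scale:
                updates.append((dofs, dB))
        self.updates = updates

    @property
    def n_update_dofs(self) -> int:
        return sum(len(d) for d, _ in self.updates)

    def _base_solve(self, b: np.ndarray) -> np.ndarray:
        x = np.empty_like(b)
        x[self.perm] = self.lu.solve(b[self.perm])
        return x

    def solve(self, b: np.ndarray) -> np.ndarray:
        y = self._base_solve(b)
        if not self.updates:
            return y
        # unique dof list of the correction space
        dofs = np.unique(np.concatenate([d for d, _ in self.updates]))
        pos = {d: i for i, d in enumerate(dofs)}
        m = len(dofs)
        D = np.zeros((m, m))
        for d, dB in self.updates:
            ii = np.array([pos[k] for k in d])
            D[np.ix_(ii, ii)] += dB
        for d in dofs:
            if d not in self._zcols:
                e = np.zeros_like(b)
                e[d] = 1.0
                self._zcols[d] = self._base_solve(e)
        Z = np.stack([self._zcols[d] for d in dofs], axis=1)  # (nfree, m)
        M = np.eye(m) + D @ Z[dofs, :]
        corr = np.linalg.solve(M, D @ y[dofs])
        return y - Z @ corr


def _solve_step(
    problem: FEProblem,
    U: np.ndarray,
    load_factor: float,
    config: SolverConfig,
) -> SolutionState:
    disc = problem.disc
    free = problem.free_dofs
    Upre = problem.prescribed_U(load_factor)
    U = U.copy()
    U[problem.fixed_dofs] = Upre[problem.fixed_dofs]
    linsolver: _LULinearSolver = getattr(problem, "_linsolver", None) or _LULinearSolver()
    problem._linsolver = linsolver

    def residual(Ux):
        f_int, energy, _ = disc.assemble(Ux, tangent=False)
        f_ext, Kc, blocks, states, reaction = problem._contact_terms(Ux, load_factor)
        R = f_int - f_ext
        rnorm = float(np.linalg.norm(R[free]))
        fscale = max(
            float(np.linalg.norm(f_ext)),
            float(np.linalg.norm(f_int[problem.fixed_dofs])),
            config.abs_tol_floor / config.newton_tol,
        )
        return dict(
            R=R, rnorm=rnorm, fscale=fscale, Kc=Kc, blocks=blocks,
            states=states, reaction=reaction, energy=energy,
        )

    history: list[float] = []
    converged = False
    res = residual(U)
    since_factor = 0
    no_progress = 0
    best_rnorm = np.inf
    for it in range(config.max_newton_iters):
        history.append(res["rnorm"])
        if logger.isEnabledFor(logging.DEBUG):  # pragma: no cover - diagnostics
            logger.debug(
                "load %.6g iter %d |R| = %.3e (scale %.3e)",
                load_factor, it, res["rnorm"], res["fscale"],
            )
        if res["rnorm"] <= config.newton_tol * res["fscale"]:
            converged = True
            break
        # bail out early on stagnation instead of burning the full budget
        if res["rnorm"] < 0.7 * best_rnorm:
            best_rnorm, no_progress = res["rnorm"], 0
        else:
            no_progress += 1
            if no_progress >= 6:
                break
        # two consecutive slow iterations indicate a genuinely stale tangent
        # (a single residual spike is just a contact activation, which the
        # low-rank contact correction already accounts for)
        stalled = (
            len(history) > 2
            and res["rnorm"] > config.refactor_stall_ratio * history[-2]
            and history[-2] > config.refactor_stall_ratio * history[-3]
        )
        if linsolver.lu is not None:
            linsolver.set_current_blocks(res["blocks"])
        refactor = (
            not config.reuse_factorization
            or linsolver.lu is None
            or stalled
            or linsolver.n_update_dofs > 240
            or since_factor >= config.refactor_every
        )
        if refactor:
            _, _, K = disc.assemble(U, tangent=True)
            if res["Kc"] is not None:
                K = K + res["Kc"]
            linsolver.refactor(K[free][:, free], res["blocks"])
            since_factor = 0
        else:
            since_factor += 1
        dU = linsolver.solve(-res["R"][free])
        # backtracking line search: breaks active-set limit cycles and
        # rejects trial states that would invert elements
        alpha = 1.0
        best = None
        for _ in range(6):
            Ut = U.copy()
            Ut[free] += alpha * dU
            try:
                res_t = residual(Ut)
            except ElementInversionError:
                alpha *= 0.5
                continue
            if best is None or res_t["rnorm"] < best[1]["rnorm"]:
                best = (Ut, res_t)
            if res_t["rnorm"] <= res["rnorm"]:
                break
            alpha *= 0.5
        hopeless = best is None or best[1]["rnorm"] > 10.0 * res["rnorm"]
        if hopeless and since_factor > 0:
            # the direction came from a stale tangent: force a fresh
            # factorization at the current point and retry the iteration
            since_factor = config.refactor_every
            continue
        if best is None:
            break  # persistent inversion under a fresh tangent: give up
        U, res = best

    states = res["states"]
    reaction = res["reaction"]
    energy = res["energy"]
    return SolutionState(
        load_factor=load_factor,
        displacements=U.reshape(-1, 3).copy(),
        reaction=reaction,
        converged=converged,
        residual_history=history,
        contact_states=states,
        strain_energy=energy * problem.mesh.symmetry_factor,
    )


def newton_solve(
    problem: FEProblem,
    config: SolverConfig | None = None,
    load_factors: np.ndarray | None = None,
    stop_at_reaction: float | None = None,
) -> list[SolutionState]:
    """Run the load-stepped Newton continuation.

    ``load_factors`` defaults to ``linspace(0, 1, n_load_steps+1)[1:]``.
    On non-convergence the step is retried with the increment multiplied by
    ``step_cutback``; after ``max_cutbacks`` failures the partial history is
    returned with the last state flagged unconverged.  If
    ``stop_at_reaction`` is given, stepping stops once the indenter reaction
    exceeds it.
    """
    config = config or SolverConfig()
    if load_factors is None:
        load_factors = np.linspace(0.0, 1.0, config.n_load_steps + 1)[1:]
    states: list[SolutionState] = []
    U = problem.prescribed_U(0.0)
    U_prev = None
    lam_prev = None
    lam_done = 0.0
    i = 0
    pending = list(np.atleast_1d(load_factors).astype(float))
    cutbacks = 0
    while pending:
        lam = pending[0]
        U_try = U
        if U_prev is not None and lam_done > lam_prev and len(states) >= 3:
            # linear extrapolation of the converged path as initial guess;
            # skipped during the first steps while the contact patch is
            # still forming and the response is far from path-linear
            fac = (lam - lam_done) / (lam_done - lam_prev)
            U_try = U + np.clip(fac, 0.0, 1.0) * (U - U_prev)
            U_try[problem.fixed_dofs] = U[problem.fixed_dofs]
        try:
            st = _solve_step(problem, U_try, lam, config)
            if not st.converged and U_try is not U:
                # extrapolated guess led astray: retry plainly before cutback
                st = _solve_step(problem, U, lam, config)
        except ElementInversionError:
            if U_try is not U:
                st = _solve_step(problem, U, lam, config)
            else:
                st = SolutionState(
                    load_factor=lam,
                    displacements=U.reshape(-1, 3).copy(),
                    reaction=0.0,
                    converged=False,
                    residual_history=[np.inf],
                )
        if st.converged:
            U_prev, lam_prev = U.copy(), lam_done
            U = st.displacements.ravel().copy()
            lam_done = lam
            states.append(st)
            pending.pop(0)
            cutbacks = 0
            if stop_at_reaction is not None and st.reaction >= stop_at_reaction:
                break
        else:
            cutbacks += 1
            if cutbacks > config.max_cutbacks:
                states.append(st)
                break
            # retry with a smaller increment towards the same target
            lam_mid = lam_done + config.step_cutback * (lam - lam_done)
            pending.insert(0, lam_mid)
        i += 1
        if i > 10 * (len(np.atleast_1d(load_factors)) + config.max_cutbacks) + 100:
            break  # pragma: no cover - safety valve
    return states
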
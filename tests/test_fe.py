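import numpy as np
import pytest

from nemaindent.fe import (
    ContactPair,
    DirichletBC,
    FEProblem,
    SolverConfig,
    element_forces,
    newton_solve,
)
from nemaindent.materials import (
    ElasticInput,
    NeoHookeanParams,
    from_engineering,
    stress_and_tangent,
)
from nemaindent.mesh import HexMesh, structured_box

UNIT_CUBE = np.array(
    [
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
    ],
    dtype=float,
)


class TestElementKernels:
    def test_zero_displacement_zero_force(self, soft_params):
        f, _ = element_forces(UNIT_CUBE, np.zeros((8, 3)), soft_params)
        assert np.abs(f).max() == 0.0

    def test_rigid_translation_zero_force(self, soft_params):
        f, _ = element_forces(UNIT_CUBE, 0.37 * np.ones((8, 3)), soft_params)
        assert np.abs(f).max() < 1e-12

    def test_rigid_rotation_zero_force(self, soft_params):
        th = 0.5
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        u = UNIT_CUBE @ R.T - UNIT_CUBE
        f, _ = element_forces(UNIT_CUBE, u, soft_params)
        assert np.abs(f).max() < 1e-10

    def test_tangent_is_exact_force_derivative(self, soft_params):
        rng = np.random.default_rng(42)
        X = UNIT_CUBE + 0.05 * rng.standard_normal((8, 3))
        u = 0.08 * rng.standard_normal((8, 3))
        f, K = element_forces(X, u, soft_params)
        h = 1e-6
        K_fd = np.zeros((24, 24))
        for d in range(24):
            up, um = u.ravel().copy(), u.ravel().copy()
            up[d] += h
            um[d] -= h
            fp, _ = element_forces(X, up.reshape(8, 3), soft_params)
            fm, _ = element_forces(X, um.reshape(8, 3), soft_params)
            K_fd[:, d] = (fp - fm).ravel() / (2 * h)
        assert np.abs(K - K_fd).max() / np.abs(K_fd).max() < 1e-5
        assert np.abs(K - K.T).max() / np.abs(K).max() < 1e-12

    def test_single_hex_uniaxial_matches_closed_form(self, soft_params):
        """Stretch with free lateral faces vs the pointwise constitutive law."""
        import scipy.optimize as so

        m = structured_box((1, 1, 1))
        lam = 1.2
        bcs = [
            DirichletBC(m.node_sets["z0"], 2, 0.0),
            DirichletBC(m.node_sets["z1"], 2, lam - 1.0),
            DirichletBC(m.node_sets["x0"], 0, 0.0),
            DirichletBC(m.node_sets["y0"], 1, 0.0),
        ]
        prob = FEProblem(m, {"pseudocoelom": soft_params}, dirichlet=bcs)
        st = newton_solve(prob, SolverConfig(n_load_steps=5))[-1]
        assert st.converged
        f_int, _, _ = prob.disc.assemble(st.displacements.ravel(), tangent=False)
        Fz = f_int.reshape(-1, 3)[m.node_sets["z1"], 2].sum()

        def lateral(q):
            s, _ = stress_and_tangent(np.diag([q, q, lam]), soft_params)
            return s[0, 0]

        q = so.brentq(lateral, 0.7, 1.05, xtol=1e-14)
        sigma, _ = stress_and_tangent(np.diag([q, q, lam]), soft_params)
        P_nominal = q * q * lam * sigma[2, 2] / lam  # unit reference area
        assert Fz == pytest.approx(P_nominal, rel=5e-3)


class TestNewtonSolve:
    def test_patch_consistency(self, soft_params):
        """Homogeneous boundary displacement reproduces the exact linear field."""
        m = structured_box((2, 2, 2))
        G = np.array([[0.03, 0.01, 0.0], [0.0, -0.02, 0.015], [0.005, 0.0, 0.04]])
        vals = m.nodes @ G.T
        bnd = np.unique(np.concatenate(list(m.node_sets.values())))
        bcs = [DirichletBC(bnd, c, vals[bnd, c]) for c in range(3)]
        prob = FEProblem(m, {"pseudocoelom": soft_params}, dirichlet=bcs)
        st = newton_solve(prob, SolverConfig(n_load_steps=1))[-1]
        assert st.converged
        assert np.abs(st.displacements - vals).max() < 1e-8

    def test_quadratic_convergence_with_full_newton(self, soft_params):
        """Residual ratio test on the last iterations under exact tangents."""
        m = structured_box((2, 2, 2))
        bcs = [
            DirichletBC(m.node_sets["z0"], 2, 0.0),
            DirichletBC(m.node_sets["z1"], 2, -0.25),
            DirichletBC(m.node_sets["x0"], 0, 0.0),
            DirichletBC(m.node_sets["y0"], 1, 0.0),
        ]
        prob = FEProblem(m, {"pseudocoelom": soft_params}, dirichlet=bcs)
        cfg = SolverConfig(n_load_steps=2, reuse_factorization=False, newton_tol=1e-12)
        states = newton_solve(prob, cfg)
        for st in states:
            assert st.converged
            r = st.residual_history
            # superlinear tail: successive reduction factors sharpen
            assert r[-1] < 1e-8 * r[0]
            assert r[-1] / r[-2] < (r[-2] / r[-3]) * 1.1

    def test_lame_annulus_near_incompressible(self):
        """Quarter plane-strain annulus, prescribed inner radial displacement,
        vs the linear-elastic Lame solution at nu = 0.499 (locking check)."""
        a, b, u_a = 10.0, 15.0, 0.01
        nr, nt = 6, 12
        r = np.linspace(a, b, nr + 1)
        th = np.linspace(0, np.pi / 2, nt + 1)
        R, T = np.meshgrid(r, th, indexing="ij")
        pts = np.stack([R * np.cos(T), R * np.sin(T)], axis=-1)
        nodes, elems = [], []
        nid = {}
        for k, y in enumerate((0.0, 1.0)):
            for i in range(nr + 1):
                for j in range(nt + 1):
                    nid[(i, j, k)] = len(nodes)
                    nodes.append([pts[i, j, 0], y, pts[i, j, 1]])
        for i in range(nr):
            for j in range(nt):
                quad = [(i, j), (i, j + 1), (i + 1, j + 1), (i + 1, j)]
                elems.append([nid[(p, q, 0)] for p, q in quad] + [nid[(p, q, 1)] for p, q in quad])
        nodes = np.array(nodes)
        elems = np.array(elems)
        mesh = HexMesh(
            nodes=nodes, elements=elems,
            element_compartment=np.full(len(elems), "pseudocoelom", dtype=object),
            node_sets={}, min_edge_contact=np.nan,
            outer_node_area=np.zeros(len(nodes)), level=0, geometry=None,
            symmetry_factor=1.0,
        )
        if mesh.jacobians().min() <= 0:
            elems[:, :4], elems[:, 4:] = elems[:, 4:].copy(), elems[:, :4].copy()
        assert mesh.jacobians().min() > 0

        E, nu = 100.0, 0.499
        params = from_engineering(ElasticInput(E=E, nu=nu))
        rad = np.hypot(nodes[:, 0], nodes[:, 2])
        inner = np.nonzero(np.abs(rad - a) < 1e-9)[0]
        x0 = np.nonzero(np.abs(nodes[:, 0]) < 1e-9)[0]
        z0 = np.nonzero(np.abs(nodes[:, 2]) < 1e-9)[0]
        nhat = nodes[inner][:, [0, 2]] / rad[inner, None]
        bcs = [
            DirichletBC(np.arange(len(nodes)), 1, 0.0),  # plane strain
            DirichletBC(x0, 0, 0.0),
            DirichletBC(z0, 2, 0.0),
            DirichletBC(inner, 0, u_a * nhat[:, 0]),
            DirichletBC(inner, 2, u_a * nhat[:, 1]),
        ]
        prob = FEProblem(mesh, {"pseudocoelom": params}, dirichlet=bcs)
        st = newton_solve(prob, SolverConfig(n_load_steps=1))[-1]
        assert st.converged

        # Lame: u(r) = A r + B / r with u(a) = u_a, sigma_rr(b) = 0
        lam_ = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu_ = E / (2 * (1 + nu))
        M = np.array([[a, 1 / a], [2 * (lam_ + mu_), -2 * mu_ / b**2]])
        A, B = np.linalg.solve(M, [u_a, 0.0])
        outer = np.nonzero(np.abs(rad - b) < 1e-9)[0]
        u_num = np.hypot(st.displacements[outer, 0], st.displacements[outer, 2]).mean()
        u_exact = A * b + B / b
        assert u_num == pytest.approx(u_exact, rel=0.02)

    def test_path_independence_in_load_steps(self, soft_params):
        """Hyperelastic statics: halving the step count leaves the final
        reaction unchanged."""
        m = structured_box((2, 2, 2))

        def run(nsteps):
            bcs = [
                DirichletBC(m.node_sets["z0"], 2, 0.0),
                DirichletBC(m.node_sets["z1"], 2, -0.3),
                DirichletBC(m.node_sets["x0"], 0, 0.0),
                DirichletBC(m.node_sets["y0"], 1, 0.0),
            ]
            prob = FEProblem(m, {"pseudocoelom": soft_params}, dirichlet=bcs)
            st = newton_solve(prob, SolverConfig(n_load_steps=nsteps))[-1]
            assert st.converged
            f_int, _, _ = prob.disc.assemble(st.displacements.ravel(), tangent=False)
            return f_int.reshape(-1, 3)[m.node_sets["z1"], 2].sum()

        assert run(4) == pytest.approx(run(8), rel=1e-3)

    def test_no_volumetric_locking_between_049_and_0499(self):
        """Mean-dilatation treatment: the confined compression response
        changes little between nu = 0.49 and nu = 0.499."""
        m = structured_box((3, 3, 3))

        def run(nu):
            params = from_engineering(ElasticInput(E=150.0, nu=nu))
            bcs = [
                DirichletBC(m.node_sets["z0"], 2, 0.0),
                DirichletBC(m.node_sets["z1"], 2, -0.2),
                DirichletBC(m.node_sets["x0"], 0, 0.0),
                DirichletBC(m.node_sets["y0"], 1, 0.0),
            ]
            prob = FEProblem(m, {"pseudocoelom": params}, dirichlet=bcs)
            st = newton_solve(prob, SolverConfig(n_load_steps=4))[-1]
            assert st.converged
            f_int, _, _ = prob.disc.assemble(st.displacements.ravel(), tangent=False)
            return f_int.reshape(-1, 3)[m.node_sets["z1"], 2].sum()

        assert run(0.49) == pytest.approx(run(0.499), rel=0.05)

    def test_failure_returns_partial_history(self, soft_params):
        """An impossible load with a tiny iteration budget flags failure."""
        m = structured_box((1, 1, 1))
        bcs = [
            DirichletBC(m.node_sets["z0"], 2, 0.0),
            DirichletBC(m.node_sets["z1"], 2, -0.99),  # crush to zero volume
            DirichletBC(m.node_sets["x0"], 0, 0.0),
            DirichletBC(m.node_sets["y0"], 1, 0.0),
        ]
        prob = FEProblem(m, {"pseudocoelom": soft_params}, dirichlet=bcs)
        cfg = SolverConfig(n_load_steps=1, max_newton_iters=3, max_cutbacks=1)
        states = newton_solve(prob, cfg)
        assert not states[-1].converged

    def test_solver_config_validation(self):
        with pytest.raises(ValueError):
            SolverConfig(n_load_steps=0)
        with pytest.raises(ValueError):
            SolverConfig(step_cutback=1.5)
        with pytest.raises(ValueError):
            SolverConfig(newton_tol=-1.0)
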
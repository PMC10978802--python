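import numpy as np
import pytest
import scipy.optimize as so
from hypothesis import given, settings, strategies as st

from nemaindent.materials import (
    ElasticInput,
    ElementInversionError,
    NeoHookeanParams,
    energy,
    from_engineering,
    pk2_stress,
    stress_and_tangent,
)


def random_admissible_F(seed: int, scale: float = 0.15) -> np.ndarray:
    rng = np.random.default_rng(seed)
    F = np.eye(3) + scale * rng.standard_normal((3, 3))
    if np.linalg.det(F) <= 0.05:
        return random_admissible_F(seed + 1000, scale * 0.5)
    return F


class TestEngineeringConversion:
    def test_reference_values(self):
        p = from_engineering(ElasticInput(E=150.0, nu=0.49))
        assert p.mu == pytest.approx(50.3356, abs=1e-4)
        assert p.kappa == pytest.approx(2500.0, rel=1e-10)
        assert p.C10 == pytest.approx(p.mu / 2)
        assert p.D1 == pytest.approx(2 / p.kappa)

    def test_round_trip_identity(self):
        p = from_engineering(ElasticInput(E=840.0, nu=0.495))
        e = p.to_engineering()
        assert e.E == pytest.approx(840.0, rel=1e-12)
        assert e.nu == pytest.approx(0.495, rel=1e-12)
        p2 = from_engineering(e)
        assert p2.C10 == pytest.approx(p.C10, rel=1e-12)
        assert p2.D1 == pytest.approx(p.D1, rel=1e-12)

    @pytest.mark.parametrize("E, nu", [(0.0, 0.3), (-5.0, 0.3), (100.0, 0.5), (100.0, -0.1)])
    def test_invalid_inputs_rejected(self, E, nu):
        with pytest.raises(ValueError):
            from_engineering(ElasticInput(E=E, nu=nu))

    def test_recovered_E_consistency_invariant(self):
        # E = 9 kappa mu / (3 kappa + mu) must hold to near machine precision
        p = from_engineering(ElasticInput(E=1200.0, nu=0.49))
        E_rec = 9 * p.kappa * p.mu / (3 * p.kappa + p.mu)
        assert E_rec == pytest.approx(1200.0, rel=1e-10)


class TestStressAndTangent:
    def test_stress_free_reference(self, soft_params):
        sigma, _ = stress_and_tangent(np.eye(3), soft_params)
        assert np.abs(sigma).max() == 0.0

    def test_incompressible_uniaxial_closed_form(self):
        # sigma_axial = mu (lam^2 - 1/lam) in the incompressible limit
        p = NeoHookeanParams(C10=25.0, D1=2 / 1e5)  # mu = 50 kPa, nearly incompressible
        lam = 1.2

        def lateral_stress(q):
            s, _ = stress_and_tangent(np.diag([q, q, lam]), p)
            return s[0, 0]

        q = so.brentq(lateral_stress, 0.7, 1.05, xtol=1e-14)
        sigma, _ = stress_and_tangent(np.diag([q, q, lam]), p)
        assert sigma[2, 2] == pytest.approx(50.0 * (lam**2 - 1 / lam), rel=1e-3)

    def test_small_strain_uniaxial_modulus(self, soft_params):
        eps = 1e-4
        lam = 1 + eps

        def lateral_stress(q):
            s, _ = stress_and_tangent(np.diag([q, q, lam]), soft_params)
            return s[0, 0]

        q = so.brentq(lateral_stress, 1 - 1e-3, 1 + 1e-6, xtol=1e-16)
        sigma, _ = stress_and_tangent(np.diag([q, q, lam]), soft_params)
        E_apparent = sigma[2, 2] / eps
        assert E_apparent == pytest.approx(150.0, rel=1e-3)

    def test_inverted_deformation_rejected(self, soft_params):
        with pytest.raises(ElementInversionError):
            pk2_stress(np.diag([1.0, 1.0, -1.0]), soft_params)

    def test_stress_symmetry_and_tangent_minor_symmetry(self, soft_params):
        F = random_admissible_F(3)
        sigma, c = stress_and_tangent(F, soft_params)
        assert np.allclose(sigma, sigma.T, atol=1e-10)
        assert np.allclose(c, np.swapaxes(c, 0, 1), atol=1e-8)
        assert np.allclose(c, np.swapaxes(c, 2, 3), atol=1e-8)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_stress_is_energy_gradient(self, seed, soft_params):
        """P = dW/dF by central finite differences at random admissible F."""
        F = random_admissible_F(seed)
        S = pk2_stress(F, soft_params)
        P = F @ S
        h = 1e-6
        for i in range(3):
            for K in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[i, K] += h
                Fm[i, K] -= h
                fd = (energy(Fp, soft_params) - energy(Fm, soft_params)) / (2 * h)
                assert P[i, K] == pytest.approx(fd, rel=2e-5, abs=1e-6)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_objectivity_under_rotations(self, seed, soft_params):
        """W(QF) = W(F) for random rotations Q."""
        F = random_admissible_F(seed)
        rng = np.random.default_rng(seed + 1)
        A = rng.standard_normal((3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        assert energy(Q @ F, soft_params) == pytest.approx(
            energy(F, soft_params), rel=1e-12, abs=1e-12
        )

    def test_tangent_positive_definite_at_identity(self, soft_params):
        _, c = stress_and_tangent(np.eye(3), soft_params)
        # Voigt-project the minor-symmetric tangent and check eigenvalues
        idx = [(0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (0, 2)]
        M = np.array([[c[a, b, x, y] for (x, y) in idx] for (a, b) in idx])
        assert np.linalg.eigvalsh(0.5 * (M + M.T)).min() > 0
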
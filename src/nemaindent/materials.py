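"""Nearly incompressible neo-Hookean constitutive law.

Each tissue compartment is a Green-elastic, neo-Hookean solid in the
decoupled (deviatoric/volumetric) form common to commercial FE codes::

    W(F) = C10 (Ibar1 - 3) + (1/D1) (J - 1)^2

with ``Ibar1 = J^(-2/3) tr(C)``, ``C = F^T F``, ``J = det F``,
``C10 = mu/2`` and ``D1 = 2/kappa``.  The engineering constants map as
``mu = E / (2 (1+nu))`` and ``kappa = E / (3 (1-2 nu))``.

Tissue incompressibility is imposed approximately through a near-0.5
Poisson ratio (default 0.49); exact ``nu = 0.5`` is rejected because a
displacement-based discretization locks there.

Units are the package-internal µm–nN–kPa system (1 nN/µm² = 1 kPa), so
moduli in kPa combine directly with lengths in µm and forces in nN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElasticInput",
    "NeoHookeanParams",
    "from_engineering",
    "energy",
    "stress_and_tangent",
    "pk2_stress",
    "ElementInversionError",
]


class ElementInversionError(RuntimeError):
    """det(F) <= 0: the deformation gradient is not admissible."""


@dataclass(frozen=True)
class ElasticInput:
    """Engineering constants: Young's modulus ``E`` (kPa), Poisson ratio ``nu``."""

    E: float
    nu: float

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"Young's modulus must be > 0, got E={self.E}")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError(
                f"Poisson ratio must satisfy 0 <= nu < 0.5, got nu={self.nu}; "
                "exact incompressibility is imposed via nu close to (not equal "
                "to) 0.5"
            )


@dataclass(frozen=True)
class NeoHookeanParams:
    """Hyperelastic constants ``C10`` (kPa) and ``D1`` (1/kPa)."""

    C10: float
    D1: float

    def __post_init__(self) -> None:
        if not (self.C10 > 0 and self.D1 > 0):
            raise ValueError(f"C10 and D1 must be > 0, got {self.C10}, {self.D1}")

    @property
    def mu(self) -> float:
        """Shear modulus (kPa)."""
        return 2.0 * self.C10

    @property
    def kappa(self) -> float:
        """Bulk modulus (kPa)."""
        return 2.0 / self.D1

    def to_engineering(self) -> ElasticInput:
        """Invert the map back to (E, nu)."""
        mu, kappa = self.mu, self.kappa
        E = 9.0 * kappa * mu / (3.0 * kappa + mu)
        nu = (3.0 * kappa - 2.0 * mu) / (2.0 * (3.0 * kappa + mu))
        return ElasticInput(E=E, nu=nu)


def from_engineering(inp: ElasticInput) -> NeoHookeanParams:
    """Map engineering constants to neo-Hookean parameters."""
    mu = inp.E / (2.0 * (1.0 + inp.nu))
    kappa = inp.E / (3.0 * (1.0 - 2.0 * inp.nu))
    return NeoHookeanParams(C10=0.5 * mu, D1=2.0 / kappa)


def _check_F(F: np.ndarray) -> float:
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise ElementInversionError(f"det(F) = {J} <= 0")
    return J


def energy(F: np.ndarray, params: NeoHookeanParams) -> float:
    """Strain-energy density W(F) in kPa."""
    F = np.asarray(F, dtype=float)
    J = _check_F(F)
    I1 = float(np.einsum("iK,iK->", F, F))
    Ibar1 = J ** (-2.0 / 3.0) * I1
    return params.C10 * (Ibar1 - 3.0) + (1.0 / params.D1) * (J - 1.0) ** 2


def pk2_stress(F: np.ndarray, params: NeoHookeanParams) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = 2 dW/dC (kPa)."""
    F = np.asarray(F, dtype=float)
    J = _check_F(F)
    C = F.T @ F
    Cinv = np.linalg.inv(C)
    trC = np.trace(C)
    A = J ** (-2.0 / 3.0)
    S_dev = 2.0 * params.C10 * A * (np.eye(3) - (trC / 3.0) * Cinv)
    p = (2.0 / params.D1) * (J - 1.0)
    S_vol = p * J * Cinv
    return S_dev + S_vol


def _material_tangent(F: np.ndarray, params: NeoHookeanParams) -> np.ndarray:
    """Material tangent CC_IJKL = 2 dS_IJ/dC_KL (kPa)."""
    J = _check_F(F)
    C = F.T @ F
    Cinv = np.linalg.inv(C)
    trC = np.trace(C)
    A = J ** (-2.0 / 3.0)
    I3 = np.eye(3)

    CiCi = np.einsum("ij,kl->ijkl", Cinv, Cinv)
    # d C^-1 / dC (symmetrized)
    dCinv = -0.5 * (
        np.einsum("ik,jl->ijkl", Cinv, Cinv) + np.einsum("il,jk->ijkl", Cinv, Cinv)
    )

    c10 = params.C10
    CC_dev = 4.0 * c10 * A * (
        -(1.0 / 3.0) * np.einsum("kl,ij->ijkl", Cinv, I3)
        - (1.0 / 3.0) * np.einsum("kl,ij->ijkl", I3, Cinv)
        + (trC / 9.0) * CiCi
        - (trC / 3.0) * dCinv
    )

    # volumetric part: S_vol = p J C^-1 with p = (2/D1)(J-1)
    # dJ/dC = (J/2) C^-1
    k2 = 2.0 / params.D1
    p = k2 * (J - 1.0)
    CC_vol = (
        (k2 * J * J + p * J) * CiCi + 2.0 * p * J * dCinv
    )
    return CC_dev + CC_vol


def stress_and_tangent(
    F: np.ndarray, params: NeoHookeanParams
) -> tuple[np.ndarray, np.ndarray]:
    """Cauchy stress (kPa) and spatial tangent moduli at one material point.

    The spatial tangent is the push-forward
    ``c_ijkl = J^-1 F_iI F_jJ F_kK F_lL CC_IJKL`` of the material tangent;
    it carries the minor symmetries ``c_ijkl = c_jikl = c_ijlk``.
    """
    F = np.asarray(F, dtype=float)
    J = _check_F(F)
    S = pk2_stress(F, params)
    sigma = (F @ S @ F.T) / J
    CC = _material_tangent(F, params)
    c_spatial = np.einsum("iI,jJ,kK,lL,IJKL->ijkl", F, F, F, F, CC) / J
    return sigma, c_spatial
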
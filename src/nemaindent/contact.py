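"""Frictionless penalty contact against analytic rigid surfaces.

Two rigid bodies appear in the AFM set-up: the spherical glass bead glued
to the cantilever (default radius 5 µm, i.e. the 10 µm bead) and the flat
support the worm rests on.  Both are treated by node-to-analytic-surface
penalty contact: a candidate surface node with signed gap ``g < 0``
(penetration) receives a purely normal force ``kappa * (-g)`` pushing it
back out.  Nodes exactly on the surface (``g = 0``) are kept in the active
set so that the penalty stiffness regularizes the otherwise unconstrained
rigid-body translation before the indenter engages.

The per-node penalty ``kappa`` (nN/µm) is scaled by the stiffest
compartment modulus and the local surface-element edge so the induced
penetrations stay far below the mesh resolution at any refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidSphere",
    "RigidPlane",
    "ContactState",
    "gap",
    "contact_contribution",
    "face_contact_contribution",
]


@dataclass
class RigidSphere:
    """Analytic spherical indenter (radius µm, centre µm)."""

    radius: float = 5.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"sphere radius must be > 0, got {self.radius}")
        self.center = np.asarray(self.center, dtype=float)

    def gap_and_normal(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = np.atleast_2d(x) - self.center
        r = np.linalg.norm(d, axis=1)
        n = d / r[:, None]
        return r - self.radius, n

    def curvature_radius(self, x: np.ndarray) -> np.ndarray:
        return np.linalg.norm(np.atleast_2d(x) - self.center, axis=1)


@dataclass
class RigidPlane:
    """Rigid half-space boundary; admissible side is ``(x - origin)·n >= 0``."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        self.normal = n / np.linalg.norm(n)

    def gap_and_normal(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.atleast_2d(x)
        g = (x - self.origin) @ self.normal
        return g, np.broadcast_to(self.normal, x.shape).copy()

    def curvature_radius(self, x: np.ndarray) -> np.ndarray:
        return np.full(np.atleast_2d(x).shape[0], np.inf)


def gap(x: np.ndarray, surface) -> np.ndarray:
    """Signed distance (µm): positive outside, negative when penetrating."""
    g, _ = surface.gap_and_normal(x)
    return g if np.ndim(x) > 1 else float(g[0])


@dataclass
class ContactState:
    """Converged contact diagnostics for one rigid surface."""

    node_ids: np.ndarray  # candidate nodes
    gaps: np.ndarray  # signed distance per candidate (µm)
    active: np.ndarray  # bool mask over candidates
    contact_forces: np.ndarray  # (n_candidates, 3) nodal forces (nN)
    total_force: float  # force on the rigid surface along `axis` (nN)
    penetration_warning: bool = False

    @property
    def active_nodes(self) -> np.ndarray:
        return self.node_ids[self.active]


def contact_contribution(
    positions: np.ndarray,
    node_ids: np.ndarray,
    surface,
    penalty: np.ndarray,
    axis: np.ndarray = (0.0, 0.0, 1.0),
    stiffness_band: float = 0.0,
):
    """Penalty forces and consistent tangent blocks for one rigid surface.

    Parameters
    ----------
    positions : current coordinates of the candidate nodes, (n, 3) µm.
    node_ids : global node indices of the candidates.
    surface : ``RigidSphere`` or ``RigidPlane``.
    penalty : per-node penalty stiffness (nN/µm), shape (n,).
    axis : direction along which ``total_force`` on the surface is reported
        (the indentation axis, +z by default).
    stiffness_band : gap distance (µm) within which *separated* nodes still
        contribute their penalty stiffness block (not force) to the tangent.
        A nonzero band pre-stiffens nodes about to touch so that contact
        activations do not destabilize quasi-Newton iterations; it never
        changes the converged solution.  Zero gives the exact consistent
        tangent.

    Returns
    -------
    (forces, K_blocks, state): nodal external forces (n, 3), consistent
    3x3 tangent blocks (n, 3, 3) to be *added* to the global stiffness for
    each candidate node, and a ``ContactState``.
    """
    positions = np.atleast_2d(positions)
    penalty = np.broadcast_to(np.asarray(penalty, float), positions.shape[:1])
    if np.any(penalty <= 0):
        raise ValueError("contact penalty must be > 0")
    g, n = surface.gap_and_normal(positions)
    active = g <= 0.0
    pen = np.where(active, -g, 0.0)

    forces = (penalty * pen)[:, None] * n
    # tangent: d(residual)/du = kappa [n x n - pen * (I - n x n)/r]
    nn = np.einsum("ai,aj->aij", n, n)
    eye = np.eye(3)
    r = surface.curvature_radius(positions)
    curv = np.where(np.isfinite(r), pen / np.where(r > 0, r, 1.0), 0.0)
    stiff = active | (g <= stiffness_band)
    K_blocks = (
        penalty[:, None, None] * stiff[:, None, None] * nn
        - (penalty * curv)[:, None, None] * (eye - nn)
    )

    axis = np.asarray(axis, float)
    total = float(-(forces @ axis).sum())  # reaction on the rigid surface
    max_pen = pen.max(initial=0.0)
    warn = bool(
        np.isfinite(getattr(surface, "radius", np.inf))
        and max_pen > 0.1 * getattr(surface, "radius", np.inf)
    )
    state = ContactState(
        node_ids=np.asarray(node_ids),
        gaps=g,
        active=active,
        contact_forces=forces,
        total_force=total,
        penetration_warning=warn,
    )
    return forces, K_blocks, state


# 2x2 Gauss rule on the bilinear quad face
_QP = np.array([-1.0, 1.0]) / np.sqrt(3.0)
_FACE_GP = np.array([[a, b] for a in _QP for b in _QP])  # (4, 2)
_FACE_N = np.stack(
    [
        0.25
        * np.array(
            [
                (1 - xi) * (1 - eta),
                (1 + xi) * (1 - eta),
                (1 + xi) * (1 + eta),
                (1 - xi) * (1 + eta),
            ]
        )
        for xi, eta in _FACE_GP
    ]
)  # (4 gp, 4 nodes)
_FACE_dN = np.stack(
    [
        0.25
        * np.array(
            [
                [-(1 - eta), -(1 - xi)],
                [(1 - eta), -(1 + xi)],
                [(1 + eta), (1 + xi)],
                [-(1 + eta), (1 - xi)],
            ]
        )
        for xi, eta in _FACE_GP
    ]
)  # (4 gp, 4 nodes, 2)


def face_contact_contribution(
    positions: np.ndarray,
    faces: np.ndarray,
    surface,
    penalty_pressure: np.ndarray,
    axis: np.ndarray = (0.0, 0.0, 1.0),
):
    """Gauss-point-integrated penalty contact over bilinear surface faces.

    The contact pressure ``p = kappa_p <-g>`` (kPa per µm of penetration)
    is evaluated at 2x2 Gauss points of each candidate face and integrated
    consistently to the face nodes, which makes the total contact force a
    smooth function of the contact-patch boundary and restores proper mesh
    convergence that node-lumped penalties lack.

    Parameters
    ----------
    positions : (n_face_nodes_total...) current coordinates indexed by the
        ids inside ``faces``; i.e. a full (N, 3) nodal array.
    faces : (F, 4) node ids, outward-wound (normal pointing away from the
        body).
    penalty_pressure : per-face penalty stiffness (kPa/µm), shape (F,).

    Returns
    -------
    (node_forces, face_blocks, state): assembled nodal forces as a dict-free
    (F, 4, 3) array aligned with ``faces``, consistent 12x12 stiffness
    blocks (F, 12, 12), and a ``ContactState`` whose gaps/active refer to
    the Gauss points (complementarity holds pointwise at the quadrature
    level).
    """
    x = positions[faces]  # (F, 4, 3)
    xg = np.einsum("ga,fak->fgk", _FACE_N, x)  # (F, 4gp, 3)
    tang = np.einsum("gad,fak->fgdk", _FACE_dN, x)  # (F, 4gp, 2, 3)
    nvec = np.cross(tang[:, :, 0, :], tang[:, :, 1, :])  # area-weighted normal
    dA = np.linalg.norm(nvec, axis=2)  # (F, 4gp)

    F, G = xg.shape[0], xg.shape[1]
    g, n = surface.gap_and_normal(xg.reshape(-1, 3))
    g = g.reshape(F, G)
    n = n.reshape(F, G, 3)
    pen = np.where(g <= 0.0, -g, 0.0)
    p = penalty_pressure[:, None] * pen  # (F, 4gp) contact pressure, kPa

    node_forces = np.einsum("ga,fg,fg,fgk->fak", _FACE_N, p, dA, n)
    # dominant tangent: kappa_p N_a N_b (n x n) dA on active gauss points
    act = (g <= 0.0).astype(float)
    nn = np.einsum("fgi,fgj->fgij", n, n)
    blocks = np.einsum(
        "ga,gb,fg,fgij->faibj",
        _FACE_N,
        _FACE_N,
        penalty_pressure[:, None] * act * dA,
        nn,
    ).reshape(F, 12, 12)

    axis = np.asarray(axis, float)
    total = float(-(node_forces.reshape(-1, 3) @ axis).sum())
    state = ContactState(
        node_ids=faces,
        gaps=g.ravel(),
        active=(g <= 0.0).ravel(),
        contact_forces=node_forces.reshape(-1, 3),
        total_force=total,
        penetration_warning=bool(
            pen.max(initial=0.0)
            > 0.1 * getattr(surface, "radius", np.inf)
        ),
    )
    return node_forces, blocks, state
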
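"""Idealized layered-cylinder geometry of the *C. elegans* body.

The nematode trunk is approximated as a straight circular cylinder made of
three concentric tissue compartments (inside-out):

* ``pseudocoelom`` — the fluid-filled body cavity, modelled as a solid,
  nearly incompressible core (default diameter 26.3 µm);
* ``muscle`` — the body-wall muscle layer (default width 1.0 µm);
* ``cuticle_hypodermis`` — the collagenous cuticle (0.6 µm) merged with the
  thin hypodermal cell layer (0.1 µm) into a single 0.7 µm outer shell.

Lengths are micrometres throughout.  The coordinate convention used by the
whole package: cylinder axis along *y*, indentation along *-z*, so the
contact point with the spherical probe sits at ``(0, 0, R_outer)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["CompartmentSpec", "WormGeometry", "build_geometry", "GeometryError"]

#: canonical inside-out compartment order
COMPARTMENT_ORDER = ("pseudocoelom", "muscle", "cuticle_hypodermis")


class GeometryError(ValueError):
    """Raised for invalid geometric input (names the offending field)."""


@dataclass(frozen=True)
class CompartmentSpec:
    """One concentric compartment, an annulus ``r_inner <= r <= r_outer`` (µm)."""

    name: str
    r_inner: float
    r_outer: float

    def __post_init__(self) -> None:
        if self.name not in COMPARTMENT_ORDER:
            raise GeometryError(f"unknown compartment name {self.name!r}")
        if not self.r_outer > self.r_inner:
            raise GeometryError(
                f"compartment {self.name!r}: r_inner ({self.r_inner}) must be "
                f"< r_outer ({self.r_outer})"
            )

    @property
    def width(self) -> float:
        return self.r_outer - self.r_inner


@dataclass(frozen=True)
class WormGeometry:
    """Layered cylinder: compartments tile ``[0, outer_radius]`` without gaps.

    ``symmetry`` records the two mirror planes the discretization exploits
    (x = 0, the vertical plane through the axis; y = 0, the transverse plane
    through the contact point), giving a quarter model.
    """

    compartments: tuple[CompartmentSpec, ...]
    length: float
    symmetry: tuple[str, ...] = field(default=("x", "y"))

    def __post_init__(self) -> None:
        if not self.compartments:
            raise GeometryError("compartments: at least one compartment required")
        r = 0.0
        for comp in self.compartments:
            if abs(comp.r_inner - r) > 1e-12 * max(1.0, r):
                raise GeometryError(
                    f"compartment {comp.name!r} does not tile: starts at "
                    f"{comp.r_inner}, expected {r}"
                )
            r = comp.r_outer
        names = [c.name for c in self.compartments]
        order = [n for n in COMPARTMENT_ORDER if n in names]
        if names != order:
            raise GeometryError(f"compartments out of inside-out order: {names}")
        if self.length < 3.0 * 2.0 * self.outer_radius:
            raise GeometryError(
                f"length ({self.length} um) must be >= 3 x outer diameter "
                f"({6.0 * self.outer_radius} um)"
            )

    @property
    def outer_radius(self) -> float:
        return self.compartments[-1].r_outer

    @property
    def interface_radii(self) -> tuple[float, ...]:
        """Outer radius of each compartment, inside-out."""
        return tuple(c.r_outer for c in self.compartments)

    def compartment(self, name: str) -> CompartmentSpec:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)


def build_geometry(
    pseudocoelom_diameter_um: float = 26.3,
    muscle_width_um: float = 1.0,
    hypodermis_width_um: float = 0.1,
    cuticle_width_um: float = 0.6,
    length_um: float | None = None,
) -> WormGeometry:
    """Build the layered-cylinder geometry from compartment dimensions.

    Defaults reproduce the published anatomy: pseudocoelom diameter 26.3 µm,
    muscle width 1.0 µm, hypodermis 0.1 µm and cuticle 0.6 µm (the last two
    merged into one shell), giving interface radii 13.15 / 14.15 / 14.85 µm.

    Zero widths are allowed and drop the corresponding compartment (the
    all-zero-width limit is a homogeneous cylinder of the pseudocoelom
    radius).  ``length_um`` defaults to 90 µm, ≈3 outer diameters, so end
    effects at the central contact are negligible.
    """
    if pseudocoelom_diameter_um <= 0:
        raise GeometryError(
            f"pseudocoelom_diameter_um must be > 0, got {pseudocoelom_diameter_um}"
        )
    for fname, w in (
        ("muscle_width_um", muscle_width_um),
        ("hypodermis_width_um", hypodermis_width_um),
        ("cuticle_width_um", cuticle_width_um),
    ):
        if w < 0:
            raise GeometryError(f"{fname} must be >= 0, got {w}")

    r1 = 0.5 * pseudocoelom_diameter_um
    r2 = r1 + muscle_width_um
    r3 = r2 + hypodermis_width_um + cuticle_width_um

    comps = [CompartmentSpec("pseudocoelom", 0.0, r1)]
    if muscle_width_um > 0:
        comps.append(CompartmentSpec("muscle", r1, r2))
    if hypodermis_width_um + cuticle_width_um > 0:
        comps.append(CompartmentSpec("cuticle_hypodermis", r2, r3))

    if length_um is None:
        length_um = max(90.0, 6.0 * r3)
    if length_um <= 0:
        raise GeometryError(f"length_um must be > 0, got {length_um}")

    return WormGeometry(compartments=tuple(comps), length=float(length_um))
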
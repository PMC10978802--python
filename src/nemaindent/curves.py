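"""Force-displacement curve containers.

``FDCurve`` is an analysis-ready force vs tip-sample indentation record
(displacement in nm, force in nN); ``RawFDCurve`` is an as-acquired AFM
record against piezo position, before baseline zeroing, contact-point
detection and cantilever-bending correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FDCurve", "RawFDCurve", "depth_at_force"]


@dataclass
class FDCurve:
    """Force (nN) versus tip-sample displacement (nm).

    ``meta`` carries acquisition/simulation metadata (``treatment``,
    ``set_force_nN``, ``source`` in {simulated, measured, synthetic}, ...).
    """

    displacement: np.ndarray  # nm
    force: np.ndarray  # nN
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.displacement.shape != self.force.shape or self.displacement.ndim != 1:
            raise ValueError("displacement and force must be equal-length 1-D arrays")
        if self.displacement.size < 2:
            raise ValueError("a curve needs at least 2 samples")
        if np.any(np.diff(self.displacement) <= 0):
            raise ValueError("displacement must be strictly increasing")
        if self.displacement[0] < 0:
            raise ValueError("displacement must be non-negative")
        if self.meta.get("source") == "simulated":
            if np.any(self.force < 0) or np.any(np.diff(self.force) < 0):
                raise ValueError("simulated force must be non-negative, non-decreasing")

    @property
    def delta_max(self) -> float:
        """Maximum indentation depth (nm)."""
        return float(self.displacement[-1])

    def force_at(self, depth_nm):
        """Piecewise-linear force interpolation (nN)."""
        d = np.asarray(depth_nm, dtype=float)
        if np.any(d < self.displacement[0]) or np.any(d > self.displacement[-1]):
            raise ValueError("depth outside the curve's range")
        return np.interp(d, self.displacement, self.force)

    def plot(self, ax=None, **kwargs):  # pragma: no cover - convenience
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.displacement, self.force, **kwargs)
        ax.set_xlabel("indentation depth (nm)")
        ax.set_ylabel("force (nN)")
        return ax


def depth_at_force(curve: FDCurve, force_nN: float) -> float:
    """Depth (nm) at which the curve reaches ``force_nN``.

    Monotone piecewise-linear interpolation of the inverse curve; raises if
    the requested force lies outside the recorded range.
    """
    f = curve.force
    if not (f[0] <= force_nN <= f[-1]):
        raise ValueError(
            f"force {force_nN} nN outside curve range [{f[0]}, {f[-1]}] nN"
        )
    return float(np.interp(force_nN, f, curve.displacement))


@dataclass
class RawFDCurve:
    """Raw AFM record: force (nN) against piezo position (nm).

    ``cantilever_k`` is the cantilever spring constant in N/m (the study's
    cantilevers spanned 5.79-10.81 N/m); with force in nN the tip deflection
    in nm is numerically ``force / cantilever_k``.
    """

    piezo_position: np.ndarray  # nm
    force: np.ndarray  # nN
    cantilever_k: float  # N/m
    meta: dict = field(default_factory=dict)

    PLAUSIBLE_K = (0.5, 100.0)

    def __post_init__(self) -> None:
        self.piezo_position = np.asarray(self.piezo_position, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.piezo_position.shape != self.force.shape or self.force.ndim != 1:
            raise ValueError("piezo_position and force must be equal-length 1-D arrays")
        if np.isfinite(self.cantilever_k):
            lo, hi = self.PLAUSIBLE_K
            if not (lo <= self.cantilever_k <= hi):
                raise ValueError(
                    f"cantilever_k={self.cantilever_k} N/m outside plausible range "
                    f"[{lo}, {hi}]"
                )
        elif self.cantilever_k <= 0:
            raise ValueError("cantilever_k must be positive (may be inf)")

    def copy(self) -> "RawFDCurve":
        return RawFDCurve(
            self.piezo_position.copy(), self.force.copy(), self.cantilever_k,
            dict(self.meta),
        )
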
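"""Model/Results interface for worm-indentation biomechanics.

Two fittable models are exposed in the statsmodels idiom — a model object
built from data whose ``fit()`` returns a results object with estimates,
uncertainty diagnostics and a ``summary()`` table:

* :class:`WormIndentationModel` — the mechanistic three-compartment FE
  model.  ``simulate(moduli)`` produces forward F-D curves and
  ``fit(target)`` calibrates the compartment Young's moduli against a
  measured (or synthetic) curve.
* :class:`HertzModel` — the single-modulus Hertz/Sneddon contact model
  used by AFM vendor software, fitted to a processed F-D curve.

Both wrap the procedural layers in :mod:`nemaindent.simulate`,
:mod:`nemaindent.calibrate` and :mod:`nemaindent.afm`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import afm, calibrate
from .calibrate import COMPARTMENTS, CalibrationProblem
from .curves import FDCurve
from .geometry import WormGeometry, build_geometry
from .simulate import run_afm_indentation

__all__ = ["WormIndentationModel", "CalibrationResults", "HertzModel", "HertzResults"]


class WormIndentationModel:
    """Three-compartment nonlinear FE model of AFM indentation.

    Parameters
    ----------
    geometry : layered-cylinder geometry (defaults to the published
        anatomy: pseudocoelom diameter 26.3 µm, muscle 1.0 µm,
        cuticle+hypodermis 0.7 µm).
    level : mesh refinement (1 = production, 0 = coarse screening).
    nu : Poisson ratio of all compartments (near-incompressible).
    support : "plane" (resting on a rigid frictionless support) or "line".
    """

    def __init__(
        self,
        geometry: WormGeometry | None = None,
        level: int = 1,
        nu: float = 0.49,
        support: str = "plane",
        sphere_radius_um: float = 5.0,
    ):
        self.geometry = geometry or build_geometry()
        self.level = level
        self.nu = nu
        self.support = support
        self.sphere_radius_um = sphere_radius_um

    # -- forward
    def simulate(
        self,
        moduli_kPa=(150.0, 1200.0, 840.0),
        set_force_nN: float | None = 450.0,
        max_depth_nm: float | None = None,
        **kwargs,
    ) -> FDCurve:
        """Forward F-D curve for a (cuticle, muscle, pseudocoelom) triple."""
        return run_afm_indentation(
            geometry=self.geometry,
            moduli_kPa=moduli_kPa,
            set_force_nN=set_force_nN,
            max_depth_nm=max_depth_nm,
            level=self.level,
            nu=self.nu,
            support=self.support,
            sphere_radius_um=self.sphere_radius_um,
            **kwargs,
        )

    # -- inverse
    def fit(
        self,
        target: FDCurve,
        bounds=((10.0, 1e4),) * 3,
        search_level: int | None = None,
        max_evaluations: int = 150,
        seed: int = 0,
        refine_final: bool = True,
        **kwargs,
    ) -> "CalibrationResults":
        """Calibrate the compartment moduli against a target curve.

        The simplex search runs on a coarse ``search_level`` mesh
        (default: one level below the model's); the returned objective is
        re-evaluated at the model's own level when ``refine_final``.
        """
        if search_level is None:
            search_level = max(0, self.level - 1)
        problem = CalibrationProblem(
            target=target,
            geometry=self.geometry,
            bounds=bounds,
            level=search_level,
            nu=self.nu,
            support=self.support,
        )
        res = calibrate.fit_moduli(
            problem, max_evaluations=max_evaluations, seed=seed, **kwargs
        )
        final_obj = res.objective
        if refine_final and self.level != search_level:
            fine = CalibrationProblem(
                target=target, geometry=self.geometry, bounds=bounds,
                level=self.level, nu=self.nu, support=self.support,
            )
            final_obj = calibrate.objective(res.moduli_kPa, fine)
        return CalibrationResults(self, target, res, final_objective=final_obj)


class CalibrationResults:
    """Calibrated compartment moduli with diagnostics.

    ``params`` is a pandas Series of the moduli (kPa); ``sensitivities``
    carries the local identifiability diagnostic (misfit slope per decade
    of each modulus; larger = better constrained).
    """

    def __init__(self, model, target, result, final_objective=None):
        self.model = model
        self.target = target
        self.result = result
        self.params = pd.Series(result.moduli_kPa, index=list(COMPARTMENTS), name="E_kPa")
        self.objective = result.objective
        self.final_objective = final_objective if final_objective is not None else result.objective
        self.sensitivities = (
            pd.Series(result.sensitivities, index=list(COMPARTMENTS), name="dRMS_per_decade")
            if result.sensitivities is not None
            else None
        )
        self.converged = result.converged
        self.n_evaluations = result.n_evaluations

    def percent_change(self, other) -> calibrate.PercentChangeReport:
        """Percent change from ``other`` (the reference) to this fit."""
        return calibrate.percent_change(other, self.result)

    def simulate(self, **kwargs) -> FDCurve:
        """Forward curve at the fitted moduli."""
        return self.model.simulate(self.params.values, **kwargs)

    def summary(self) -> str:
        lines = [
            "Three-compartment indentation calibration",
            "=" * 45,
            f"target: {self.target.meta.get('treatment', '')} "
            f"(delta_max {self.target.delta_max:.0f} nm, "
            f"{self.target.displacement.size} samples)",
            f"converged: {self.converged}   evaluations: {self.n_evaluations}",
            f"RMS misfit: {self.objective:.3g} nN (search mesh), "
            f"{self.final_objective:.3g} nN (final mesh)",
            "",
            f"{'compartment':<18}{'E (kPa)':>10}{'sensitivity':>14}",
        ]
        for name in COMPARTMENTS:
            sens = (
                f"{self.sensitivities[name]:>14.3g}"
                if self.sensitivities is not None
                else f"{'-':>14}"
            )
            lines.append(f"{name:<18}{self.params[name]:>10.1f}{sens}")
        return "\n".join(lines)

    def plot(self, ax=None):  # pragma: no cover - convenience
        ax = self.target.plot(ax=ax, label="target", color="k")
        self.simulate(
            set_force_nN=None, max_depth_nm=self.target.delta_max
        ).plot(ax=ax, label="fit", ls="--")
        ax.legend()
        return ax


class HertzModel:
    """Hertz/Sneddon spherical contact model for one processed curve."""

    def __init__(self, curve: FDCurve, radius_um: float = 5.0, nu: float = 0.5):
        self.curve = curve
        self.radius_um = radius_um
        self.nu = nu

    def fit(self, fit_range_nm=None) -> "HertzResults":
        res = afm.hertz_sneddon_fit(
            self.curve, R_um=self.radius_um, nu=self.nu, fit_range_nm=fit_range_nm
        )
        return HertzResults(self, res)


class HertzResults:
    def __init__(self, model: HertzModel, result: afm.HertzFitResult):
        self.model = model
        self.result = result
        self.params = pd.Series({"E_overall_kPa": result.E_overall})
        self.rms_residual = result.rms_residual

    @property
    def E_overall(self) -> float:
        return self.result.E_overall

    def summary(self) -> str:
        r = self.result
        return "\n".join(
            [
                "Hertz/Sneddon spherical fit",
                "=" * 30,
                f"E_overall: {r.E_overall:.1f} kPa",
                f"R: {r.R} um   nu: {r.nu_assumed}",
                f"fit range: [{r.fit_range[0]:.0f}, {r.fit_range[1]:.0f}] nm "
                f"({r.n_points} samples)",
                f"RMS residual: {r.rms_residual:.3g} nN",
            ]
        )

    def predicted(self, depth_nm) -> np.ndarray:
        return afm.hertz_force(depth_nm, self.E_overall, self.result.R, self.result.nu_assumed)
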
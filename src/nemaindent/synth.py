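"""Synthetic raw AFM curves with machine-readable ground truth.

Emulates the acquisition chain of the force-spectroscopy experiment: a
flat pre-contact baseline (optionally offset and drifting), a contact
point, a post-contact rise generated by either the closed-form Hertz model
or the three-compartment FE forward model, expressed against *piezo*
position (which includes the cantilever deflection ``F/k``), with additive
Gaussian force noise.  Every fixture returns its ground truth so recovery
tests can assert exactly.

``SCENARIOS`` ships the study's calibrated compartment-modulus presets:

========================  =======================================
BDM_mean                  (150, 1200, 840) kPa — BDM-immobilised mean
BDM_salt_control          (105, 390, 880) kPa — control for the salt assay
high_salt                 (90, 650, 76) kPa — hyperosmotic shock
aldicarb                  (140, 950, 94) kPa — aldicarb treatment
========================  =======================================

(ordered cuticle+hypodermis, muscle, pseudocoelom; all fitted at the
450 nN set force).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import FDCurve, RawFDCurve
from .simulate import run_afm_indentation
from .afm import hertz_force

__all__ = ["NoiseModel", "ScenarioPreset", "SCENARIOS", "make_raw_curve", "make_scenario_curve"]


@dataclass(frozen=True)
class ScenarioPreset:
    """A named treatment condition with its calibrated moduli (kPa)."""

    name: str
    moduli_kPa: tuple[float, float, float]  # (cuticle, muscle, pseudocoelom)
    set_force_nN: float = 450.0


SCENARIOS: dict[str, ScenarioPreset] = {
    p.name: p
    for p in (
        ScenarioPreset("BDM_mean", (150.0, 1200.0, 840.0)),
        ScenarioPreset("BDM_salt_control", (105.0, 390.0, 880.0)),
        ScenarioPreset("high_salt", (90.0, 650.0, 76.0)),
        ScenarioPreset("aldicarb", (140.0, 950.0, 94.0)),
    )
}


@dataclass
class NoiseModel:
    """Gaussian force noise plus baseline imperfections.

    ``sigma_force`` (nN) is the white force noise; ``baseline_offset``
    (nN) and ``baseline_drift`` (nN per nm of piezo travel) shift the whole
    record as an uncorrected acquisition baseline would.  The same seed
    always reproduces the identical curve.
    """

    sigma_force: float = 0.0
    baseline_offset: float = 0.0
    baseline_drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_force < 0:
            raise ValueError("sigma_force must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually used (for recovery assertions)."""

    contact_index: int
    contact_piezo_nm: float
    cantilever_k: float
    E_kPa: float | None = None  # Hertz source
    moduli_kPa: tuple | None = None  # FE source
    clean_curve: FDCurve | None = None  # noise-free F(delta)
    noise: NoiseModel = field(default_factory=NoiseModel)


def _piezo_from_indentation(curve: FDCurve, k: float) -> np.ndarray:
    """Piezo travel past contact: indentation plus cantilever deflection."""
    defl = curve.force / k if np.isfinite(k) else np.zeros_like(curve.force)
    return curve.displacement + defl


def make_raw_curve(
    hertz_E_kPa: float | None = None,
    fe_moduli_kPa=None,
    *,
    set_force_nN: float = 450.0,
    cantilever_k: float = 7.5,
    noise: NoiseModel | None = None,
    pre_contact_nm: float = 300.0,
    sample_spacing_nm: float = 1.0,
    R_um: float = 5.0,
    nu: float = 0.5,
    fe_level: int = 0,
    treatment: str = "synthetic",
) -> tuple[RawFDCurve, GroundTruth]:
    """Generate one raw AFM record plus its ground truth.

    The post-contact force comes from exactly one source: the closed-form
    Hertz model (``hertz_E_kPa``) or the FE forward model
    (``fe_moduli_kPa``).  Defaults mirror the study's acquisition: 450 nN
    set force, 7.5 N/m cantilever, 1 nm piezo sampling.
    """
    if (hertz_E_kPa is None) == (fe_moduli_kPa is None):
        raise ValueError("specify exactly one of hertz_E_kPa or fe_moduli_kPa")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)

    # noise-free F(delta) source on a dense indentation grid
    if hertz_E_kPa is not None:
        if hertz_E_kPa <= 0:
            raise ValueError("hertz_E_kPa must be positive")
        # depth reaching the set force: invert the 3/2 power law
        d_max = 1000.0 * (
            set_force_nN / ((4.0 / 3.0) * (hertz_E_kPa / (1 - nu**2)) * np.sqrt(R_um))
        ) ** (2.0 / 3.0)
        d = np.linspace(0.0, d_max, max(200, int(d_max)))
        clean = FDCurve(d, hertz_force(d, hertz_E_kPa, R_um, nu),
                        {"source": "synthetic"})
    else:
        sim = run_afm_indentation(
            moduli_kPa=fe_moduli_kPa, set_force_nN=set_force_nN, level=fe_level,
            sphere_radius_um=R_um, nu=min(nu, 0.499),
        )
        dense = np.linspace(0.0, sim.delta_max, max(200, int(sim.delta_max)))
        clean = FDCurve(dense, np.interp(dense, sim.displacement, sim.force),
                        {"source": "synthetic"})

    # map to piezo axis (monotone since dF/ddelta >= 0), then resample
    piezo_post = _piezo_from_indentation(clean, cantilever_k)
    total_travel = pre_contact_nm + piezo_post[-1]
    piezo = np.arange(0.0, total_travel, sample_spacing_nm)
    force = np.zeros_like(piezo)
    post = piezo >= pre_contact_nm
    force[post] = np.interp(piezo[post] - pre_contact_nm, piezo_post, clean.force)

    contact_index = int(np.searchsorted(piezo, pre_contact_nm))
    force = force + noise.baseline_offset + noise.baseline_drift * piezo
    if noise.sigma_force > 0:
        force = force + rng.normal(0.0, noise.sigma_force, size=force.size)

    raw = RawFDCurve(
        piezo_position=piezo,
        force=force,
        cantilever_k=cantilever_k,
        meta={
            "treatment": treatment,
            "set_force_nN": set_force_nN,
            "source": "synthetic",
            "seed": noise.seed,
        },
    )
    truth = GroundTruth(
        contact_index=contact_index,
        contact_piezo_nm=pre_contact_nm,
        cantilever_k=cantilever_k,
        E_kPa=hertz_E_kPa,
        moduli_kPa=None if fe_moduli_kPa is None else tuple(np.asarray(fe_moduli_kPa, float)),
        clean_curve=clean,
        noise=noise,
    )
    return raw, truth


def make_scenario_curve(
    preset: str | ScenarioPreset,
    noise: NoiseModel | None = None,
    *,
    cantilever_k: float = 7.5,
    fe_level: int = 0,
    **kwargs,
) -> tuple[RawFDCurve, GroundTruth]:
    """FE-generated raw curve for a named treatment scenario."""
    if isinstance(preset, str):
        try:
            preset = SCENARIOS[preset]
        except KeyError:
            raise KeyError(
                f"unknown scenario {preset!r}; available: {sorted(SCENARIOS)}"
            ) from None
    raw, truth = make_raw_curve(
        fe_moduli_kPa=preset.moduli_kPa,
        set_force_nN=preset.set_force_nN,
        cantilever_k=cantilever_k,
        noise=noise,
        fe_level=fe_level,
        treatment=preset.name,
        **kwargs,
    )
    return raw, truth
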
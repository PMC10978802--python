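"""AFM force-curve processing and summary statistics.

Implements the standard force-spectroscopy chain applied to each raw
record before analysis:

1. ``zero_baseline`` — remove offset (and linear drift) estimated from the
   flat pre-contact segment;
2. ``detect_contact_point`` — first sustained excursion of the force above
   the pre-contact noise floor;
3. ``correct_cantilever_bending`` — convert piezo travel to true tip-sample
   indentation by subtracting the cantilever deflection ``F/k``;

followed by the study's summary quantities: the overall Young's modulus
from a Hertz/Sneddon spherical fit ``F = (4/3) (E/(1-nu^2)) sqrt(R)
delta^(3/2)``, the bulk stiffness (OLS slope over the upper half of the
indentation range, ``[0.5 delta_max, delta_max]``) and treated/control
stiffness ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .curves import FDCurve, RawFDCurve

__all__ = [
    "zero_baseline",
    "detect_contact_point",
    "correct_cantilever_bending",
    "process_raw_curve",
    "hertz_sneddon_fit",
    "hertz_force",
    "bulk_stiffness",
    "normalize_stiffness",
    "HertzFitResult",
    "BulkStiffnessResult",
    "ProcessingError",
]


class ProcessingError(RuntimeError):
    pass


#: contact detection rule: force must exceed THRESHOLD_SIGMA x noise std
#: for at least PERSISTENCE consecutive samples
THRESHOLD_SIGMA = 5.0
PERSISTENCE = 10


def _precontact_region(raw: RawFDCurve, min_fraction: float = 0.2) -> np.ndarray:
    """Indices of a conservative pre-contact segment (first samples).

    The baseline segment is found iteratively: starting from the first 20%
    of samples, extend while the force stays within 4 robust standard
    deviations of the segment's linear trend.
    """
    n = raw.force.size
    n0 = max(int(min_fraction * n), 8)
    if n0 >= n:
        raise ProcessingError("record too short to contain a pre-contact baseline")
    idx = np.arange(n)
    seg = n0
    while True:
        x, y = idx[:seg], raw.force[:seg]
        coef = np.polyfit(x, y, 1)
        resid = y - np.polyval(coef, x)
        sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        sigma = max(sigma, 1e-12)
        future = raw.force[seg:] - np.polyval(coef, idx[seg:])
        beyond = np.nonzero(np.abs(future) > 4.0 * sigma)[0]
        new_seg = seg + (beyond[0] if beyond.size else future.size)
        if new_seg <= seg:
            break
        seg = new_seg
        if seg >= n:
            break
    # sanity: the segment must look flat relative to the full force range
    y = raw.force[:seg]
    frange = raw.force.max() - raw.force.min()
    if frange > 0 and (y.max() - y.min()) > 0.5 * frange:
        raise ProcessingError("no identifiable flat pre-contact region")
    return idx[:seg]


def zero_baseline(raw: RawFDCurve) -> RawFDCurve:
    """Remove the pre-contact baseline (offset and linear drift).

    A line is fitted to the detected pre-contact segment and subtracted
    from the whole record, so both a constant force offset and a slow
    linear drift vanish; the pre-contact mean becomes 0 up to noise.
    """
    seg = _precontact_region(raw)
    coef = np.polyfit(raw.piezo_position[seg], raw.force[seg], 1)
    out = raw.copy()
    out.force = raw.force - np.polyval(coef, raw.piezo_position)
    out.meta["baseline_removed"] = True
    out.meta["baseline_n"] = int(seg.size)
    return out


def detect_contact_point(
    raw: RawFDCurve,
    threshold_sigma: float = THRESHOLD_SIGMA,
    persistence: int = PERSISTENCE,
    refine: bool = True,
) -> int:
    """Index of the tip-sample contact point on a baseline-zeroed record.

    The contact sample is the first index at which the force exceeds
    ``threshold_sigma`` times the pre-contact noise standard deviation and
    stays above it for ``persistence`` consecutive samples.  With
    ``refine=True`` the threshold crossing is then sharpened by the
    spherical-contact power law: near contact ``F^(2/3)`` is linear in the
    piezo position, so a line through the shallow-indentation samples is
    extrapolated back to zero force, removing the systematic late-detection
    bias a pure threshold rule has in noise.
    """
    if not raw.meta.get("baseline_removed"):
        raise ProcessingError("zero the baseline before contact detection")
    seg = _precontact_region(raw)
    sigma = max(float(np.std(raw.force[seg])), 1e-12)
    above = raw.force > threshold_sigma * sigma
    # first run of `persistence` consecutive True values
    run = 0
    start = None
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= persistence:
            start = i - persistence + 1
            # walk back to where the force first left the noise floor
            while start > 0 and raw.force[start - 1] > sigma:
                start -= 1
            break
    if start is None:
        raise ProcessingError(
            f"force never exceeds {threshold_sigma} x noise ({sigma:.3g} nN): no contact"
        )
    if not refine:
        return start
    # refine with the F ~ (p - p0)^{3/2} law on shallow-indentation samples
    fmax = float(raw.force[start:].max())
    lo = max(3.0 * sigma, 1e-3 * fmax)
    hi = max(30.0 * sigma, 0.05 * fmax)
    m = np.zeros(raw.force.size, dtype=bool)
    m[start:] = (raw.force[start:] >= lo) & (raw.force[start:] <= hi)
    if m.sum() >= 4:
        x, y = raw.piezo_position[m], raw.force[m] ** (2.0 / 3.0)
        slope, icpt = np.polyfit(x, y, 1)
        if slope > 0:
            p0 = -icpt / slope
            cand = int(np.searchsorted(raw.piezo_position, p0))
            if 0 <= cand <= start + 5 and abs(cand - start) <= 100:
                return cand
    return start


def correct_cantilever_bending(
    raw: RawFDCurve, contact_index: int | None = None
) -> FDCurve:
    """Convert piezo travel to tip-sample displacement past contact.

    ``delta = (piezo - piezo_contact) - F/k``: the cantilever deflection
    (nm, numerically ``F`` in nN over ``k`` in N/m) is subtracted from the
    piezo displacement re-referenced to the contact point.
    """
    if contact_index is None:
        contact_index = detect_contact_point(raw)
    k = raw.cantilever_k
    piezo = raw.piezo_position[contact_index:] - raw.piezo_position[contact_index]
    force = raw.force[contact_index:]
    deflection = force / k if np.isfinite(k) else np.zeros_like(force)
    delta = piezo - deflection
    # clip the (noise-dominated) samples that fall behind the contact point
    keep = np.nonzero(delta > 0)[0]
    delta, force = delta[keep], force[keep]
    order_ok = np.diff(delta) > 0
    if order_ok.size and (~order_ok).mean() > 0.05:
        warnings.warn(
            "tip-sample displacement strongly non-monotonic after bending "
            "correction; check cantilever_k",
            stacklevel=2,
        )
    # enforce a strictly increasing grid for downstream interpolation
    mono = np.maximum.accumulate(delta)
    keep = np.nonzero(np.diff(np.concatenate(([-np.inf], mono))) > 0)[0]
    meta = dict(raw.meta)
    meta.setdefault("source", "measured")
    meta["k_N_per_m"] = k
    meta["contact_index"] = int(contact_index)
    d, f = delta[keep], force[keep]
    if d.size < 2:
        raise ProcessingError("fewer than 2 post-contact samples after correction")
    if d[0] > 0:
        d = np.concatenate(([0.0], d))
        f = np.concatenate(([0.0], f))
    return FDCurve(displacement=d, force=f, meta=meta)


def process_raw_curve(raw: RawFDCurve) -> FDCurve:
    """Full chain: zero baseline -> contact point -> bending correction."""
    z = zero_baseline(raw)
    return correct_cantilever_bending(z)


def hertz_force(delta_nm, E_kPa: float, R_um: float = 5.0, nu: float = 0.5):
    """Hertz/Sneddon force (nN) of a rigid sphere on an elastic half-space."""
    delta_um = np.asarray(delta_nm, dtype=float) / 1000.0
    return (4.0 / 3.0) * (E_kPa / (1.0 - nu**2)) * np.sqrt(R_um) * delta_um**1.5


@dataclass
class HertzFitResult:
    """Overall Young's modulus from the spherical Hertz/Sneddon fit."""

    E_overall: float  # kPa
    R: float  # µm
    nu_assumed: float
    fit_range: tuple[float, float]  # nm
    rms_residual: float  # nN
    n_points: int

    def __post_init__(self) -> None:
        if not self.E_overall > 0:
            raise ValueError(f"non-positive fitted modulus: {self.E_overall}")


def hertz_sneddon_fit(
    curve: FDCurve,
    R_um: float = 5.0,
    nu: float = 0.5,
    fit_range_nm: tuple[float, float] | None = None,
) -> HertzFitResult:
    """Least-squares Hertz/Sneddon modulus over the fit range.

    The model is linear in E, so the fit reduces to a single normal
    equation on the basis ``delta^{3/2}``.  Defaults follow the study's
    vendor-software analysis: 5 µm bead radius, incompressible tissue
    (nu = 0.5) and the entire post-contact curve.
    """
    lo, hi = fit_range_nm if fit_range_nm is not None else (0.0, curve.delta_max)
    m = (curve.displacement >= lo) & (curve.displacement <= hi)
    if m.sum() < 2:
        raise ValueError("fewer than 2 samples in the fit range")
    d, f = curve.displacement[m], curve.force[m]
    basis = hertz_force(d, 1.0, R_um, nu)  # force per unit modulus
    denom = float(basis @ basis)
    if denom == 0.0:
        raise ValueError("degenerate fit range (all depths zero)")
    E = float(basis @ f) / denom
    if E <= 0:
        raise ValueError(f"non-positive best-fit modulus ({E:.3g} kPa)")
    rms = float(np.sqrt(np.mean((f - E * basis) ** 2)))
    return HertzFitResult(
        E_overall=E, R=R_um, nu_assumed=nu, fit_range=(float(lo), float(hi)),
        rms_residual=rms, n_points=int(m.sum()),
    )


@dataclass
class BulkStiffnessResult:
    """OLS slope of F vs delta over the window [0.5 delta_max, delta_max]."""

    slope: float  # nN/nm
    intercept: float  # nN
    window: tuple[float, float]  # nm
    n_points: int


def bulk_stiffness(curve: FDCurve) -> BulkStiffnessResult:
    """Bulk stiffness: linear regression over the upper half of the depths."""
    dmax = curve.delta_max
    lo = 0.5 * dmax
    m = (curve.displacement >= lo) & (curve.displacement <= dmax)
    if m.sum() < 2:
        raise ValueError("fewer than 2 samples in the [0.5 dmax, dmax] window")
    slope, intercept = np.polyfit(curve.displacement[m], curve.force[m], 1)
    return BulkStiffnessResult(
        slope=float(slope),
        intercept=float(intercept),
        window=(float(lo), float(dmax)),
        n_points=int(m.sum()),
    )


def normalize_stiffness(
    treated: BulkStiffnessResult, control: BulkStiffnessResult
) -> float:
    """Treated-over-control bulk-stiffness ratio (dimensionless)."""
    if not control.slope > 0:
        raise ValueError("control stiffness must be positive")
    return treated.slope / control.slope
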
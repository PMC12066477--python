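"""Force-curve processing: contact-point detection and Young's-modulus fitting.

Each AFM force-volume pixel yields one approach curve: cantilever force versus
piezo displacement. Converting it to a Young's modulus requires (i) locating
the tip-sample contact point and the pre-contact force baseline, (ii) turning
piezo travel into indentation depth by subtracting cantilever deflection, and
(iii) regressing the post-contact force on the square of the depth, the form
shared by conical (Sneddon) and regular four-sided pyramidal (Bilodeau)
indenters:

    F = C(alpha, nu) * E * delta**2

with C = tan(alpha) / (sqrt(2) * (1 - nu**2)) for a four-sided pyramid and
C = 2 * tan(alpha) / (pi * (1 - nu**2)) for a cone; alpha is the tip
half-angle and nu the sample Poisson ratio (0.5 for incompressible soft
tissue). The regression is linear in E given the delta**2 regressor, so the
fit is closed form.

Units: piezo displacement in nm, force in nN, spring constant in N/m
(numerically equal to nN/nm), moduli in Pa.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "CantileverSpec",
    "ForceCurve",
    "FitResult",
    "FitOptions",
    "ForceCurveModel",
    "ModulusMap",
    "BundleUnusableError",
    "contact_model_constant",
    "detect_contact_point",
    "indentation_depth",
    "fit_modulus",
    "process_bundle",
]

# 1 Pa * nm**2 = 1e-9 nN: converts E [Pa] * delta[nm]**2 to force [nN]
_PA_NM2_TO_NN = 1e-9


class BundleUnusableError(RuntimeError):
    """Raised when more than half the pixels of a bundle fail to fit."""


@dataclass(frozen=True)
class CantileverSpec:
    """Probe and cantilever calibration constants.

    Defaults describe a soft silicon-nitride triangular cantilever carrying a
    four-sided pyramidal tip (MLCT-A class): spring constant 0.07 N/m, tip
    half-angle 17 degrees, nominal tip curvature radius 20 nm (informational
    only; no sphero-conical correction is applied), indentation speed
    29.6 um/s (informational), and an incompressible sample (nu = 0.5).
    """

    spring_constant_n_per_m: float = 0.07
    tip_half_angle_deg: float = 17.0
    tip_radius_nm: float = 20.0
    poisson_ratio: float = 0.5
    indentation_speed_um_per_s: float = 29.6

    def __post_init__(self) -> None:
        if not self.spring_constant_n_per_m > 0:
            raise ValueError("spring constant must be positive")
        if not 0.0 < self.tip_half_angle_deg < 90.0:
            raise ValueError("tip half-angle must lie in (0, 90) degrees")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")


def contact_model_constant(cantilever: CantileverSpec, model: str = "pyramid") -> float:
    """Dimensionless prefactor C in F = C * E * delta**2.

    ``model`` selects the indenter geometry: ``"pyramid"`` (Bilodeau,
    regular four-sided pyramid) or ``"cone"`` (Sneddon).
    """
    tan_a = math.tan(math.radians(cantilever.tip_half_angle_deg))
    one_minus_nu2 = 1.0 - cantilever.poisson_ratio**2
    if model == "pyramid":
        return tan_a / (math.sqrt(2.0) * one_minus_nu2)
    if model == "cone":
        return 2.0 * tan_a / (math.pi * one_minus_nu2)
    raise ValueError(f"unknown contact model {model!r} (expected 'pyramid' or 'cone')")


@dataclass
class ForceCurve:
    """One indentation record: piezo ramp (nm) and force (nN), plus fit."""

    piezo_nm: np.ndarray
    force_nN: np.ndarray
    fit: Optional["FitResult"] = None
    true_contact_index: Optional[int] = None  # set by the simulator
    true_modulus_pa: Optional[float] = None

    def __post_init__(self) -> None:
        self.piezo_nm = np.asarray(self.piezo_nm, dtype=float)
        self.force_nN = np.asarray(self.force_nN, dtype=float)
        if self.piezo_nm.shape != self.force_nN.shape or self.piezo_nm.ndim != 1:
            raise ValueError("piezo and force must be 1-D arrays of equal length")
        if self.piezo_nm.size < 16:
            raise ValueError("force curve needs at least 16 samples")
        if not np.all(np.diff(self.piezo_nm) > 0):
            raise ValueError("piezo displacement must be strictly increasing")

    def __len__(self) -> int:
        return int(self.piezo_nm.size)


@dataclass
class FitResult:
    """Outcome of fitting one force curve.

    ``contact_index`` is the first in-contact sample; ``baseline_nN`` the
    fitted pre-contact force offset. ``youngs_modulus_pa`` and ``r_squared``
    refer to the post-contact segment. Invalid fits carry a ``reject_reason``
    tag instead of a usable modulus.
    """

    contact_index: int = -1
    baseline_nN: float = float("nan")
    youngs_modulus_pa: float = float("nan")
    r_squared: float = float("nan")
    valid: bool = False
    reject_reason: Optional[str] = None
    contact_radius_nm: float = float("nan")  # delta_max * tan(alpha), diagnostic
    model: str = "pyramid"

    def summary(self) -> str:
        lines = [
            "Force-curve contact-model fit",
            f"  model:            {self.model}",
            f"  valid:            {self.valid}"
            + (f" (reject: {self.reject_reason})" if self.reject_reason else ""),
            f"  contact index:    {self.contact_index}",
            f"  baseline [nN]:    {self.baseline_nN:.4g}",
            f"  E [Pa]:           {self.youngs_modulus_pa:.6g}",
            f"  r^2:              {self.r_squared:.6f}",
            f"  contact radius:   {self.contact_radius_nm:.1f} nm",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class FitOptions:
    """Quality-control and model options for per-curve fits."""

    model: str = "pyramid"
    min_baseline_samples: int = 8
    min_contact_samples: int = 8
    min_r_squared: float = 0.80
    modulus_bounds_pa: tuple[float, float] = (50.0, 1.0e6)
    # force range below this multiple of the baseline noise = "never contacts"
    contact_snr: float = 6.0
    contact_force_floor_nN: float = 0.005


def _suffix(prefix_total: np.ndarray, total: float, c: np.ndarray) -> np.ndarray:
    # sum over i >= c given inclusive prefix cumsum
    return total - np.where(c > 0, prefix_total[c - 1], 0.0)


def detect_contact_point(
    curve: ForceCurve,
    cantilever: CantileverSpec,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Locate the contact point by exhaustive piecewise least squares.

    Every admissible sample index c is scored as the total squared residual of
    the piecewise model {constant baseline for i < c; F - b = beta * delta**2
    for i >= c}, where delta is the indentation depth implied by candidate c
    and beta >= 0 is profiled out in closed form. The minimizing index wins;
    ties go to the lowest index. The scan is exact (all candidates evaluated)
    and runs in O(n) via suffix sums, since for each candidate the residual is
    a polynomial in the candidate's baseline and contact offset.
    """
    F = curve.force_nN
    z = curve.piezo_nm
    n = F.size
    lo = options.min_baseline_samples
    hi = n - options.min_contact_samples  # candidates c in [lo, hi]
    if hi < lo:
        return FitResult(valid=False, reject_reason="no_baseline", model=options.model)

    k = cantilever.spring_constant_n_per_m  # nN/nm numerically
    u = z - F / k

    PF = np.cumsum(F)
    PF2 = np.cumsum(F * F)
    Pu = np.cumsum(u)
    u2 = u * u
    Pu2 = np.cumsum(u2)
    Pu3 = np.cumsum(u2 * u)
    Pu4 = np.cumsum(u2 * u2)
    PFu = np.cumsum(F * u)
    PFu2 = np.cumsum(F * u2)

    c = np.arange(lo, hi + 1)
    b = PF[c - 1] / c  # baseline mean over [0, c)
    sse_pre = PF2[c - 1] - c * b * b

    m = n - c
    SF = _suffix(PF, PF[-1], c)
    SF2 = _suffix(PF2, PF2[-1], c)
    Su = _suffix(Pu, Pu[-1], c)
    Su2 = _suffix(Pu2, Pu2[-1], c)
    Su3 = _suffix(Pu3, Pu3[-1], c)
    Su4 = _suffix(Pu4, Pu4[-1], c)
    SFu = _suffix(PFu, PFu[-1], c)
    SFu2 = _suffix(PFu2, PFu2[-1], c)

    v = z[c] - b / k  # contact offset in deflection-corrected coordinate
    s_fd2 = (SFu2 - 2.0 * v * SFu + v * v * SF) - b * (Su2 - 2.0 * v * Su + v * v * m)
    s_d4 = Su4 - 4.0 * v * Su3 + 6.0 * v**2 * Su2 - 4.0 * v**3 * Su + v**4 * m
    s_fc2 = SF2 - 2.0 * b * SF + m * b * b

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(s_d4 > 0, s_fd2 / np.where(s_d4 > 0, s_d4, 1.0), 0.0)
    beta = np.maximum(beta, 0.0)
    sse_post = s_fc2 - beta * s_fd2
    sse = sse_pre + np.maximum(sse_post, 0.0)

    best = int(np.argmin(sse))  # argmin returns first minimizer: lowest index
    contact = int(c[best])
    baseline = float(b[best])

    noise_sd = float(np.std(F[:contact])) if contact > 1 else 0.0
    span = float(np.max(F) - baseline)
    if span < max(options.contact_snr * noise_sd, options.contact_force_floor_nN):
        return FitResult(valid=False, reject_reason="no_contact", model=options.model)

    return FitResult(contact_index=contact, baseline_nN=baseline, model=options.model)


def indentation_depth(
    curve: ForceCurve,
    contact_index: int,
    baseline_nN: float,
    cantilever: CantileverSpec,
) -> np.ndarray:
    """Indentation depth series (nm) for samples at and past contact.

    delta_i = (z_i - z_contact) - (F_i - baseline) / k: piezo travel past
    contact minus cantilever deflection. Values that dip negative by no more
    than numerical jitter are clamped to zero; if more than 10% of the
    segment's increments are decreasing the curve is not a usable indentation
    and a ValueError tagged ``nonmonotone_indentation`` is raised.
    """
    if not 0 <= contact_index < len(curve):
        raise IndexError("contact_index out of range")
    k = cantilever.spring_constant_n_per_m
    z = curve.piezo_nm[contact_index:]
    f = curve.force_nN[contact_index:]
    delta = (z - z[0]) - (f - baseline_nN) / k
    dec = np.diff(delta) < 0
    if dec.size and np.count_nonzero(dec) > 0.10 * dec.size:
        raise ValueError("nonmonotone_indentation")
    return np.maximum(delta, 0.0)


def fit_modulus(
    curve: ForceCurve,
    cantilever: CantileverSpec,
    options: FitOptions = FitOptions(),
    contact: Optional[FitResult] = None,
) -> FitResult:
    """Fit Young's modulus to the post-contact segment of one curve.

    Detects the contact point (unless ``contact`` is supplied), computes the
    indentation depth and solves the linear least-squares problem
    F - baseline = C * E * delta**2 for E. Validity requires at least
    ``min_contact_samples`` post-contact points, r^2 above the configured
    minimum and E inside the configured physical bounds.
    """
    res = contact if contact is not None else detect_contact_point(curve, cantilever, options)
    if res.reject_reason is not None:
        curve.fit = res
        return res

    try:
        delta = indentation_depth(curve, res.contact_index, res.baseline_nN, cantilever)
    except ValueError as exc:
        res = replace(res, valid=False, reject_reason=str(exc))
        curve.fit = res
        return res

    fc = curve.force_nN[res.contact_index:] - res.baseline_nN
    if fc.size < options.min_contact_samples:
        res = replace(res, valid=False, reject_reason="short_contact")
        curve.fit = res
        return res

    d2 = delta * delta
    denom = float(np.dot(d2, d2))
    if denom <= 0.0:
        res = replace(res, valid=False, reject_reason="no_contact")
        curve.fit = res
        return res
    beta = float(np.dot(fc, d2)) / denom  # nN / nm^2
    C = contact_model_constant(cantilever, options.model)
    modulus_pa = beta / (C * _PA_NM2_TO_NN)

    resid = fc - beta * d2
    ss_tot = float(np.dot(fc - fc.mean(), fc - fc.mean()))
    r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 0.0

    tan_a = math.tan(math.radians(cantilever.tip_half_angle_deg))
    radius = float(delta[-1] * tan_a)

    lo_e, hi_e = options.modulus_bounds_pa
    reason = None
    if not lo_e <= modulus_pa <= hi_e:
        reason = "modulus_out_of_range"
    elif r2 < options.min_r_squared:
        reason = "poor_fit"

    res = replace(
        res,
        youngs_modulus_pa=modulus_pa,
        r_squared=r2,
        contact_radius_nm=radius,
        valid=reason is None,
        reject_reason=reason,
    )
    curve.fit = res
    return res


class ForceCurveModel:
    """Contact-mechanics model for a single force curve (fit via ``fit()``).

    Thin model object over :func:`detect_contact_point` and
    :func:`fit_modulus`; ``fit()`` returns a :class:`FitResult` carrying the
    modulus estimate, fit quality and diagnostics.
    """

    def __init__(
        self,
        curve: ForceCurve,
        cantilever: CantileverSpec = CantileverSpec(),
        options: FitOptions = FitOptions(),
    ) -> None:
        self.curve = curve
        self.cantilever = cantilever
        self.options = options

    def fit(self) -> FitResult:
        return fit_modulus(self.curve, self.cantilever, self.options)


@dataclass
class ModulusMap:
    """Per-pixel Young's moduli (Pa) on a square grid with a validity mask."""

    values_pa: np.ndarray
    valid_mask: np.ndarray
    pixel_pitch_nm: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values_pa = np.asarray(self.values_pa, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values_pa.shape != self.valid_mask.shape or self.values_pa.ndim != 2:
            raise ValueError("values and mask must be 2-D arrays of equal shape")
        if min(self.values_pa.shape) < 4:
            raise ValueError("modulus map must be at least 4x4")
        vals = self.values_pa[self.valid_mask]
        if vals.size and not np.all(np.isfinite(vals) & (vals > 0)):
            raise ValueError("valid pixels must be finite and positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values_pa.shape


# plausible contact-radius band for kPa-range tissue with a sharp pyramid
_CONTACT_RADIUS_BAND_NM = (20.0, 1000.0)


def process_bundle(bundle, cantilever: CantileverSpec, options: FitOptions = FitOptions()):
    """Fit every curve of a force-volume bundle into a :class:`ModulusMap`.

    Returns ``(map, qc)`` where ``qc`` is a tidy per-pixel table (row, col,
    modulus, r^2, validity, reject reason). Raises
    :class:`BundleUnusableError` if more than half the pixels are invalid.
    """
    import pandas as pd

    n = bundle.grid_n
    values = np.full((n, n), np.nan)
    valid = np.zeros((n, n), dtype=bool)
    rows = []
    radii = []
    for idx, curve in enumerate(bundle.curves):
        i, j = divmod(idx, n)
        if curve is None:
            rows.append((i, j, np.nan, np.nan, False, bundle.curve_errors.get(idx, "missing")))
            continue
        res = fit_modulus(curve, cantilever, options)
        if res.valid:
            values[i, j] = res.youngs_modulus_pa
            valid[i, j] = True
            radii.append(res.contact_radius_nm)
        rows.append((i, j, res.youngs_modulus_pa, res.r_squared, res.valid, res.reject_reason))

    n_invalid = int(n * n - valid.sum())
    if n_invalid > 0.5 * n * n:
        raise BundleUnusableError(
            f"bundle_unusable: {n_invalid}/{n * n} pixels failed to fit"
        )
    if radii:
        med = float(np.median(radii))
        lo, hi = _CONTACT_RADIUS_BAND_NM
        if not lo <= med <= hi:
            warnings.warn(
                f"median contact radius {med:.0f} nm outside the plausible "
                f"{lo:.0f}-{hi:.0f} nm band for soft tissue",
                stacklevel=2,
            )
    qc = pd.DataFrame(
        rows, columns=["row", "col", "modulus_pa", "r_squared", "valid", "reject_reason"]
    )
    mmap = ModulusMap(
        values_pa=values,
        valid_mask=valid,
        pixel_pitch_nm=bundle.pixel_pitch_nm,
        provenance=getattr(bundle, "bundle_id", ""),
    )
    return mmap, qc
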
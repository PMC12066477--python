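"""Synthetic force-volume data with known ground truth.

The generator emulates an AFM force-volume experiment on optic-nerve-head
tissue in which a stiff glial meshwork (astrocytic lamina cribrosa) is
interleaved with softer retinal-ganglion-cell axon bundles. A phantom is a
square modulus field on a 20x20 um region sampled at 128x128 pixels (both
configurable): axon bundles are drawn as randomly placed, randomly oriented
ellipses with cross-sectional diameters of 0.2-2 um, matching electron-
microscopy morphometry of axon bundles threading the glial plate; per-pixel
moduli get multiplicative lognormal jitter around each phase mean, since
moduli are positive and AFM modulus histograms are right-skewed.

Each pixel is then forward-simulated as a force-vs-piezo approach curve under
the pyramidal contact model with a 0.07 N/m cantilever, Gaussian force noise,
a randomized contact point and truncation at a 2.5 nN trigger force, giving
ground-truth data for the entire downstream pipeline (fitting, segmentation,
mode summarization, longitudinal statistics).

A longitudinal study design assigns each experimental group a pair of
relative moduli (its fraction of the baseline glial and axon stiffness) and
simulates the configured number of experimental and contralateral eyes per
group; contralateral eyes keep baseline stiffness at every time point.
Defaults reproduce a four-arm chronic ocular-hypertension design: weeks
0/4/8/12, group sizes 10/6/6/6 experimental plus 6/6/6 contralateral and a
six-eye drug-control arm, with glial stiffness falling to 64.5%, 25.8% and
19.4% of baseline at 4, 8 and 12 weeks and axon stiffness to 54.4%, 29.1%
and 24.1%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.draw import ellipse as _draw_ellipse

from .curve_processing import (
    CantileverSpec,
    ForceCurve,
    contact_model_constant,
    _PA_NM2_TO_NN,
)

__all__ = [
    "PhantomSpec",
    "GroundTruthPhantom",
    "AcquisitionSpec",
    "ForceVolumeBundle",
    "GroupSpec",
    "StudyDesign",
    "EyeInfo",
    "IOPSeries",
    "PhantomGenerationError",
    "TriggerUnreachableError",
    "make_phantom",
    "simulate_curve",
    "simulate_fv_bundle",
    "simulate_study",
    "simulate_iop",
    "default_study_design",
]


class PhantomGenerationError(RuntimeError):
    pass


class TriggerUnreachableError(RuntimeError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a two-phase tissue phantom.

    ``axon_area_fraction`` is the target areal coverage of axon bundles;
    ``modulus_cv`` the coefficient of variation of the within-phase lognormal
    modulus jitter (0 gives exactly two-valued fields).
    """

    roi_size_um: float = 20.0
    grid_n: int = 128
    glial_modulus_pa: float = 15_000.0
    axon_modulus_pa: float = 5_000.0
    axon_diameter_range_um: tuple[float, float] = (0.2, 2.0)
    axon_area_fraction: float = 0.4
    modulus_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_n < 8:
            raise ValueError("grid_n must be at least 8")
        if self.glial_modulus_pa <= 0 or self.axon_modulus_pa <= 0:
            raise ValueError("phase moduli must be positive")
        if not 0.0 <= self.axon_area_fraction < 1.0:
            raise ValueError("axon_area_fraction must lie in [0, 1)")
        lo, hi = self.axon_diameter_range_um
        if not 0.0 < lo <= hi < self.roi_size_um:
            raise ValueError("axon diameters must lie within (0, roi_size_um)")
        if self.modulus_cv < 0:
            raise ValueError("modulus_cv must be non-negative")


@dataclass
class GroundTruthPhantom:
    """A realized phantom: true modulus field plus the generating class mask."""

    modulus_field: np.ndarray  # Pa, grid_n x grid_n
    class_mask: np.ndarray  # 1 = glial, 0 = axon
    spec: PhantomSpec

    @property
    def axon_fraction(self) -> float:
        return float(1.0 - self.class_mask.mean())


def _lognormal_field(rng: np.random.Generator, mean: float, cv: float, shape) -> np.ndarray:
    """Lognormal draws with exact arithmetic mean ``mean`` and CV ``cv``."""
    if cv == 0:
        return np.full(shape, mean)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return np.exp(rng.normal(mu, math.sqrt(sigma2), shape))


def make_phantom(spec: PhantomSpec, max_resample: int = 20) -> GroundTruthPhantom:
    """Generate a two-phase phantom matching ``spec``.

    Elliptical axon bundles (major diameter uniform over the configured
    range, axis ratio uniform on [1, 2], orientation uniform) are placed at
    uniform random centers until the target area fraction is reached, then
    the whole field is resampled if the realized fraction misses the target
    by more than 20% relative. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.grid_n
    px_per_um = n / spec.roi_size_um
    lo_d, hi_d = spec.axon_diameter_range_um

    target = spec.axon_area_fraction
    mask_axon = np.zeros((n, n), dtype=bool)
    if target > 0:
        for _ in range(max_resample):
            mask_axon[:] = False
            attempts = 0
            max_attempts = 200_000
            while mask_axon.mean() < target:
                attempts += 1
                if attempts > max_attempts:
                    raise PhantomGenerationError(
                        "could not reach axon_area_fraction="
                        f"{target} with diameters in {spec.axon_diameter_range_um} um "
                        f"after {max_attempts} ellipse placements"
                    )
                major = rng.uniform(lo_d, hi_d)
                ratio = rng.uniform(1.0, 2.0)
                minor = major / ratio
                r0, c0 = rng.uniform(0, n, 2)
                theta = rng.uniform(0.0, math.pi)
                rr, cc = _draw_ellipse(
                    r0,
                    c0,
                    0.5 * major * px_per_um,
                    0.5 * minor * px_per_um,
                    shape=(n, n),
                    rotation=theta,
                )
                if rr.size == 0:  # degenerate at this resolution: skip
                    continue
                mask_axon[rr, cc] = True
            realized = mask_axon.mean()
            if abs(realized - target) <= 0.20 * target:
                break
        else:
            raise PhantomGenerationError(
                f"realized axon fraction missed {target} by >20% in {max_resample} resamples"
            )

    field_g = _lognormal_field(rng, spec.glial_modulus_pa, spec.modulus_cv, (n, n))
    field_a = _lognormal_field(rng, spec.axon_modulus_pa, spec.modulus_cv, (n, n))
    modulus = np.where(mask_axon, field_a, field_g)
    return GroundTruthPhantom(
        modulus_field=modulus,
        class_mask=(~mask_axon).astype(np.uint8),
        spec=spec,
    )


@dataclass(frozen=True)
class AcquisitionSpec:
    """Force-volume acquisition settings for the forward simulator.

    The piezo ramp for each pixel is built so the trigger force is reachable:
    the post-contact travel is the analytic travel to trigger times
    ``ramp_margin``. ``contact_window_nm`` bounds the randomized pre-contact
    baseline length; the realized contact point always coincides with a
    piezo sample so that noiseless curves are exactly representable by the
    piecewise contact model.
    """

    grid_n: int = 128
    roi_size_um: float = 20.0
    trigger_force_nN: float = 2.5
    samples_per_curve: int = 200
    noise_sd_nN: float = 0.05  # 2% of the 2.5 nN trigger
    contact_window_nm: tuple[float, float] = (300.0, 800.0)
    ramp_margin: float = 1.10
    model: str = "pyramid"

    def __post_init__(self) -> None:
        if self.trigger_force_nN <= 0:
            raise ValueError("trigger force must be positive")
        if self.samples_per_curve < 32:
            raise ValueError("need at least 32 samples per curve")
        if self.noise_sd_nN < 0:
            raise ValueError("noise SD must be non-negative")

    @property
    def pixel_pitch_nm(self) -> float:
        return self.roi_size_um * 1000.0 / self.grid_n


def _noiseless_force(s_nm: np.ndarray, cprime: float, k: float) -> np.ndarray:
    """Force (nN) at piezo travel past contact ``s`` for F = C' (s - F/k)^2.

    Solving the quadratic for the physical root (F < k*s) with the stable
    two-term form 2c / (b + sqrt(b^2 - 4ac)).
    """
    a = cprime / (k * k)
    b = 2.0 * cprime * s_nm / k + 1.0
    c = cprime * s_nm * s_nm
    disc = np.maximum(b * b - 4.0 * a * c, 0.0)
    return 2.0 * c / (b + np.sqrt(disc))


def simulate_curve(
    true_modulus_pa: float,
    cantilever: CantileverSpec = CantileverSpec(),
    acquisition: AcquisitionSpec = AcquisitionSpec(),
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> ForceCurve:
    """Forward-simulate one approach curve for a sample of known modulus.

    The curve has a pre-contact baseline (zero force plus Gaussian noise), a
    post-contact branch following the configured pyramidal/conical contact
    model with cantilever-deflection feedback, and ends at the first sample
    whose force reaches the trigger. Deterministic given ``rng``/``seed``.
    """
    if true_modulus_pa <= 0:
        raise ValueError("true modulus must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    k = cantilever.spring_constant_n_per_m
    C = contact_model_constant(cantilever, acquisition.model)
    cprime = C * true_modulus_pa * _PA_NM2_TO_NN  # nN / nm^2

    trig = acquisition.trigger_force_nN
    delta_trig = math.sqrt(trig / cprime)
    post_range = acquisition.ramp_margin * (delta_trig + trig / k)

    zc = rng.uniform(*acquisition.contact_window_nm)
    n = acquisition.samples_per_curve
    n_pre = int(round(n * zc / (zc + post_range)))
    n_pre = min(max(n_pre, 10), n - 16)
    z_pre = np.linspace(0.0, zc, n_pre, endpoint=False)
    z_post = zc + np.linspace(0.0, post_range, n - n_pre)
    z = np.concatenate([z_pre, z_post])

    force = np.zeros(n)
    force[n_pre:] = _noiseless_force(z_post - zc, cprime, k)
    if force[-1] < trig:
        raise TriggerUnreachableError(
            f"trigger {trig} nN unreachable within piezo range for E={true_modulus_pa} Pa"
        )
    if acquisition.noise_sd_nN > 0:
        force = force + rng.normal(0.0, acquisition.noise_sd_nN, n)

    crossing = np.nonzero(force >= trig)[0]
    if crossing.size == 0:
        raise TriggerUnreachableError("noise pushed the curve below trigger everywhere")
    end = max(int(crossing[0]), 15)  # keep the minimum curve length
    return ForceCurve(
        piezo_nm=z[: end + 1],
        force_nN=force[: end + 1],
        true_contact_index=n_pre,
        true_modulus_pa=float(true_modulus_pa),
    )


@dataclass
class ForceVolumeBundle:
    """All force curves of one raster scan, row-major, plus metadata."""

    curves: list  # ForceCurve or None per pixel
    grid_n: int
    pixel_pitch_nm: float
    cantilever: CantileverSpec
    acquisition: AcquisitionSpec
    seed: Optional[int] = None
    bundle_id: str = ""
    curve_errors: dict = field(default_factory=dict)  # pixel index -> reason

    def __post_init__(self) -> None:
        if len(self.curves) != self.grid_n**2:
            raise ValueError("bundle must hold grid_n**2 curves in row-major order")


def simulate_fv_bundle(
    phantom: GroundTruthPhantom,
    cantilever: CantileverSpec = CantileverSpec(),
    acquisition: Optional[AcquisitionSpec] = None,
    seed: int = 0,
    bundle_id: str = "",
) -> ForceVolumeBundle:
    """Simulate one force curve per phantom pixel (row-major scan order)."""
    spec = phantom.spec
    if acquisition is None:
        acquisition = AcquisitionSpec(grid_n=spec.grid_n, roi_size_um=spec.roi_size_um)
    if acquisition.grid_n != spec.grid_n:
        raise ValueError("phantom grid does not match acquisition grid")
    rng = np.random.default_rng(seed)
    flat = phantom.modulus_field.ravel()
    curves: list = []
    errors: dict = {}
    for idx, e_true in enumerate(flat):
        try:
            curves.append(simulate_curve(float(e_true), cantilever, acquisition, rng=rng))
        except TriggerUnreachableError as exc:  # recorded per pixel, not fatal
            curves.append(None)
            errors[idx] = str(exc)
    return ForceVolumeBundle(
        curves=curves,
        grid_n=spec.grid_n,
        pixel_pitch_nm=acquisition.pixel_pitch_nm,
        cantilever=cantilever,
        acquisition=acquisition,
        seed=seed,
        bundle_id=bundle_id,
        curve_errors=errors,
    )


@dataclass(frozen=True)
class GroupSpec:
    """One study arm: time point, relative stiffness and eye counts."""

    label: str
    week: int
    relative_glial_modulus: float
    relative_axon_modulus: float
    n_experimental_eyes: int
    n_contralateral_eyes: int = 0
    arm: str = "model"  # model | drug_control | blank


@dataclass(frozen=True)
class StudyDesign:
    """Longitudinal design: groups, baseline moduli and between-eye scatter."""

    groups: tuple[GroupSpec, ...]
    baseline_glial_modulus_pa: float = 15_000.0
    baseline_axon_modulus_pa: float = 5_000.0
    between_eye_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        weeks = [g.week for g in self.groups if g.arm != "drug_control"]
        if any(w < 0 for w in weeks):
            raise ValueError("weeks must be non-negative")
        if any(b >= a for a, b in zip(weeks[1:], weeks[:-1])):
            raise ValueError("weeks must be strictly increasing across model groups")
        for g in self.groups:
            if not (0.0 < g.relative_glial_modulus <= 1.0 and 0.0 < g.relative_axon_modulus <= 1.0):
                raise ValueError(f"relative moduli of {g.label} must lie in (0, 1]")
            if g.n_experimental_eyes < 1:
                raise ValueError(f"group {g.label} needs at least one experimental eye")


def default_study_design(
    baseline_glial_pa: float = 15_000.0,
    baseline_axon_pa: float = 5_000.0,
    between_eye_cv: float = 0.15,
    include_drug_control: bool = True,
    seed: int = 0,
) -> StudyDesign:
    """Four-arm chronic ocular-hypertension design with built-in declines.

    Glial stiffness drops by 35.5/74.2/80.6 % and axon stiffness by
    45.6/70.9/75.9 % at weeks 4/8/12 relative to week-0 controls; group sizes
    10/6/6/6 experimental eyes plus 6/6/6 contralateral controls and an
    optional six-eye drug-control arm with no simulated effect.
    """
    groups = [
        GroupSpec("Gw0", 0, 1.0, 1.0, 10, 0, "blank"),
        GroupSpec("Gw4", 4, 0.645, 0.544, 6, 6),
        GroupSpec("Gw8", 8, 0.258, 0.291, 6, 6),
        GroupSpec("Gw12", 12, 0.194, 0.241, 6, 6),
    ]
    if include_drug_control:
        groups.append(GroupSpec("Gw0-5Fu", 0, 1.0, 1.0, 6, 0, "drug_control"))
    return StudyDesign(
        groups=tuple(groups),
        baseline_glial_modulus_pa=baseline_glial_pa,
        baseline_axon_modulus_pa=baseline_axon_pa,
        between_eye_cv=between_eye_cv,
        seed=seed,
    )


@dataclass(frozen=True)
class EyeInfo:
    """Identity and ground truth of one simulated eye."""

    eye_id: str
    group_label: str
    week: int
    side: str  # experimental | contralateral
    arm: str
    true_glial_pa: float
    true_axon_pa: float


def simulate_study(
    design: StudyDesign,
    phantom_template: Optional[PhantomSpec] = None,
    cantilever: CantileverSpec = CantileverSpec(),
    acquisition: Optional[AcquisitionSpec] = None,
    simulate_bundles: bool = True,
) -> list:
    """Simulate every eye of a longitudinal study.

    Returns a list of ``(EyeInfo, GroundTruthPhantom, ForceVolumeBundle)``
    tuples (bundle ``None`` when ``simulate_bundles`` is off). Eye-level
    phase means are lognormal around the group-scaled baselines with CV
    ``design.between_eye_cv``; contralateral eyes keep baseline (week-0)
    relative stiffness at every time point.
    """
    if phantom_template is None:
        phantom_template = PhantomSpec()
    rng = np.random.default_rng(design.seed)
    out = []
    for group in design.groups:
        sides = [("experimental", group.n_experimental_eyes), ("contralateral", group.n_contralateral_eyes)]
        for side, n_eyes in sides:
            for i in range(n_eyes):
                rel_g = group.relative_glial_modulus if side == "experimental" else 1.0
                rel_a = group.relative_axon_modulus if side == "experimental" else 1.0
                mean_g = design.baseline_glial_modulus_pa * rel_g
                mean_a = design.baseline_axon_modulus_pa * rel_a
                eye_g = float(_lognormal_field(rng, mean_g, design.between_eye_cv, ()))
                eye_a = float(_lognormal_field(rng, mean_a, design.between_eye_cv, ()))
                eye_id = f"{group.label}-{side[:3]}-{i + 1:02d}"
                info = EyeInfo(
                    eye_id=eye_id,
                    group_label=group.label,
                    week=group.week,
                    side=side,
                    arm=group.arm,
                    true_glial_pa=eye_g,
                    true_axon_pa=eye_a,
                )
                from dataclasses import replace as _replace

                pspec = _replace(
                    phantom_template,
                    glial_modulus_pa=eye_g,
                    axon_modulus_pa=eye_a,
                    seed=int(rng.integers(2**31)),
                )
                try:
                    phantom = make_phantom(pspec)
                    bundle = None
                    if simulate_bundles:
                        acq = acquisition
                        if acq is None:
                            acq = AcquisitionSpec(
                                grid_n=pspec.grid_n, roi_size_um=pspec.roi_size_um
                            )
                        bundle = simulate_fv_bundle(
                            phantom,
                            cantilever,
                            acq,
                            seed=int(rng.integers(2**31)),
                            bundle_id=eye_id,
                        )
                except (PhantomGenerationError, TriggerUnreachableError) as exc:
                    raise RuntimeError(f"simulation failed for eye {eye_id}: {exc}") from exc
                out.append((info, phantom, bundle))
    return out


@dataclass
class IOPSeries:
    """Intraocular-pressure time series for one eye, sampled every 3 days."""

    eye_id: str
    times_days: np.ndarray
    iop_mmhg: np.ndarray
    arm: str

    def __post_init__(self) -> None:
        self.times_days = np.asarray(self.times_days, dtype=float)
        self.iop_mmhg = np.asarray(self.iop_mmhg, dtype=float)
        if self.times_days.shape != self.iop_mmhg.shape:
            raise ValueError("times and IOP series must have equal length")
        if np.any(self.iop_mmhg <= 0):
            raise ValueError("IOP values must be positive")


def simulate_iop(
    arm: str,
    n_weeks: int = 12,
    seed: int = 0,
    elevated_setpoint_mmhg: float = 35.0,
    normal_setpoint_mmhg: float = 12.0,
    maintenance_threshold_mmhg: float = 30.0,
    noise_sd_mmhg: float = 1.5,
    reversion: float = 0.5,
    eye_id: str = "eye",
) -> IOPSeries:
    """Simulate an IOP series measured every 3 days over ``n_weeks`` weeks.

    Experimental eyes follow a mean-reverting walk around the elevated
    setpoint; whenever a measurement falls below the maintenance threshold
    (30 mmHg) the vessel-cauterization is repeated and the next measurement
    restarts at the setpoint. Contralateral and drug-control eyes fluctuate
    around the normal setpoint.
    """
    if arm not in {"experimental", "contralateral", "drug_control"}:
        raise ValueError(f"unknown arm {arm!r}")
    rng = np.random.default_rng(seed)
    days = np.arange(0, 7 * n_weeks + 1, 3, dtype=float)
    n = days.size
    iop = np.empty(n)
    if arm == "experimental":
        setpoint = elevated_setpoint_mmhg
        iop[0] = setpoint
        for t in range(1, n):
            prev = iop[t - 1]
            if prev < maintenance_threshold_mmhg:  # repeat cauterization
                iop[t] = setpoint + rng.normal(0.0, noise_sd_mmhg)
            else:
                iop[t] = prev + reversion * (setpoint - prev) + rng.normal(0.0, noise_sd_mmhg)
        iop = np.maximum(iop, 1.0)
    else:
        iop = normal_setpoint_mmhg + rng.normal(0.0, noise_sd_mmhg, n) if noise_sd_mmhg > 0 else np.full(
            n, normal_setpoint_mmhg
        )
        iop = np.maximum(iop, 1.0)
    return IOPSeries(eye_id=eye_id, times_days=days, iop_mmhg=iop, arm=arm)
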
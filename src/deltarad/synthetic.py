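"""Synthetic longitudinal CBCT-like cohorts for pipeline testing.

Each phantom patient is an ellipsoidal prostate-like ROI inside a small 3D
grid.  Every fraction's image is a fresh realization of a stationary
Gaussian random field (white noise smoothed with an isotropic kernel)
whose correlation length drifts linearly with fraction index, with
per-patient slope drawn conditional on the latent outcome (responders
drift, controls on average do not).  The drift deliberately lives in the
smoothing length and not in the mean intensity, so texture-class delta
features carry the signal while the first-order mean does not; redrawing
the field each fraction provides the day-to-day feature sampling noise
that both contour arms share.  Bright fiducial-marker voxels are placed
inside the ROI, and automated contours are boundary perturbations of the
manual contour tuned by bisection to a target Dice coefficient.

All randomness flows from ``CohortConfig.seed`` through independent
per-patient child streams, so cohorts are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .contours import dice
from .longitudinal import FractionationSchedule
from .preprocessing import _dilation_structure
from .types import ROIMask, VolumeImage


class GenerationError(RuntimeError):
    """The requested cohort cannot be generated (e.g. unreachable DSC target)."""


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults emulate a conventionally fractionated prostate cohort:
    ~50 patients treated with 80 Gy / 40 fractions or 70.2 Gy / 26
    fractions (2:1), 0.9 x 0.9 x 2 mm voxels, automated contours at
    DSC ~ 0.89, and fiducial artifacts excluding roughly 18% of the ROI.
    Axis order is (z, y, x) throughout.
    """

    n_patients: int = 50
    schedules: tuple[tuple[float, int], ...] = ((80.0, 40), (70.2, 26))
    schedule_weights: tuple[float, ...] = (2.0, 1.0)
    image_shape: tuple[int, int, int] = (20, 48, 48)
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 0.9, 0.9)
    roi_radius_mm: tuple[float, float, float] = (12.0, 14.0, 14.0)
    roi_radius_jitter: float = 0.15  # per-patient relative radius variation
    auto_error_refresh: float = 0.3  # fraction-to-fraction variance share of DIR error
    texture_correlation_length_mm: float = 2.0
    drift_effect_size: float = 0.06  # mm of correlation length per fraction
    drift_slope_sd: float | None = None  # default: 0.25 * |drift_effect_size|
    noise_sd: float = 0.1
    fiducial_count: int = 3
    fiducial_intensity: float = 8.0
    fiducial_mask_dilation_mm: float = 4.3
    target_auto_dsc: float = 0.89
    outcome_prevalence: float = 0.4
    subacute_flip_prob: float = 0.15
    ipss_shift: float = 5.0
    ipss_noise_sd: float = 2.0
    alpha_beta_gy: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if any(n < 2 for _, n in self.schedules):
            raise ValueError("every schedule needs >= 2 fractions")
        if not 0 < self.target_auto_dsc <= 1:
            raise ValueError("target_auto_dsc must be in (0, 1]")
        if not 0 < self.outcome_prevalence < 1:
            raise ValueError("outcome_prevalence must be in (0, 1)")
        if self.texture_correlation_length_mm <= 0 or self.noise_sd < 0:
            raise ValueError("correlation length must be > 0 and noise_sd >= 0")


@dataclass
class Fraction:
    image: VolumeImage
    manual: ROIMask
    automated: ROIMask
    fiducial: ROIMask


@dataclass
class PatientCourse:
    patient_id: str
    schedule: FractionationSchedule
    fractions: list[Fraction]
    outcome_acute: int
    outcome_subacute: int
    ipss_baseline: int
    ipss_post: int
    latent_slope: float = 0.0  # generating drift, for diagnostics/tests

    @property
    def delta_ipss(self) -> int:
        return self.ipss_post - self.ipss_baseline


def _ellipsoid_mask(shape, spacing, radii_mm) -> np.ndarray:
    center = [(n - 1) / 2.0 for n in shape]
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, s, r in zip(grids, center, spacing, radii_mm):
        acc = acc + ((g - c) * s / r) ** 2
    return acc <= 1.0


def _smooth_field(base: np.ndarray, sigma_mm: float, spacing) -> np.ndarray:
    sig = [max(sigma_mm, 1e-3) / s for s in spacing]
    f = ndimage.gaussian_filter(base, sigma=sig, mode="nearest")
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else f


def _signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    return outside - inside  # negative inside


def perturb_mask_to_dsc(
    manual: ROIMask,
    target_dsc: float,
    rng: np.random.Generator,
    field_sigma_mm: float = 3.0,
    tol: float = 0.005,
    max_amplitude_mm: float | None = None,
    field: np.ndarray | None = None,
) -> ROIMask:
    """Boundary perturbation of ``manual`` with Dice tuned by bisection.

    The perturbed mask is ``{v : signed_distance(v) <= a * g(v)}`` for a
    smooth zero-mean random field ``g`` (drawn from ``rng`` unless a
    precomputed ``field`` is given); the amplitude ``a`` (mm) is bisected
    until the realized DSC is within ``tol`` of ``target_dsc``.

    Raises :class:`GenerationError` when the target is unreachable for the
    given ROI (perturbation amplitude capped at ``max_amplitude_mm``).
    """
    if target_dsc >= 1.0:
        return ROIMask(manual.data.copy(), manual.spacing)
    sd = _signed_distance(manual.data, manual.spacing)
    g = (
        field
        if field is not None
        else _smooth_field(rng.standard_normal(manual.data.shape), field_sigma_mm, manual.spacing)
    )
    if max_amplitude_mm is None:
        max_amplitude_mm = 4.0 * float(np.max(manual.spacing)) + 0.5 * float(
            np.abs(sd[manual.data]).max()
        )

    def realized(a: float) -> float:
        pert = sd <= a * g
        if not pert.any():
            return 0.0
        return dice(manual, ROIMask(pert, manual.spacing))

    lo, hi = 0.0, max_amplitude_mm
    if realized(hi) > target_dsc + tol:
        raise GenerationError(
            f"DSC target {target_dsc} unreachable: even amplitude {hi:.1f} mm "
            f"gives DSC {realized(hi):.3f}"
        )
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        d = realized(mid)
        if abs(d - target_dsc) <= tol:
            lo = hi = mid
            break
        if d > target_dsc:
            lo = mid
        else:
            hi = mid
    a = 0.5 * (lo + hi)
    pert = sd <= a * g
    if not pert.any():
        raise GenerationError("perturbed mask became empty")
    return ROIMask(pert, manual.spacing)


def _place_fiducials(
    roi: np.ndarray, spacing, count: int, dilation_mm: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(bright voxel mask, dilated fiducial exclusion mask within ROI)."""
    bright = np.zeros(roi.shape, dtype=bool)
    if count == 0:
        return bright, bright.copy()
    # keep seeds away from the surface so the artifact sits inside the gland
    interior = ndimage.binary_erosion(roi, iterations=2)
    candidates = np.argwhere(interior if interior.any() else roi)
    idx = rng.choice(len(candidates), size=min(count, len(candidates)), replace=False)
    for c in candidates[idx]:
        bright[tuple(c)] = True
        for ax in range(3):  # small cross-shaped marker, ~seed size
            for step in (-1, 1):
                cc = c.copy()
                cc[ax] += step
                if 0 <= cc[ax] < roi.shape[ax]:
                    bright[tuple(cc)] = True
    bright &= roi
    struct = _dilation_structure(dilation_mm, spacing)
    excl = ndimage.binary_dilation(bright, structure=struct) if struct is not None else bright
    return bright, excl & roi


def generate_patient(
    config: CohortConfig,
    patient_id: str,
    schedule: FractionationSchedule,
    responder: bool,
    rng: np.random.Generator,
) -> PatientCourse:
    shape, spacing = config.image_shape, config.voxel_spacing_mm
    j = config.roi_radius_jitter
    radii = [r * (1.0 + rng.uniform(-j, j)) for r in config.roi_radius_mm]
    roi = _ellipsoid_mask(shape, spacing, radii)
    if not roi.any():
        raise GenerationError("ROI radii produce an empty mask on this grid")
    manual = ROIMask(roi, spacing)

    slope_sd = (
        config.drift_slope_sd
        if config.drift_slope_sd is not None
        else 0.25 * abs(config.drift_effect_size)
    )
    slope = rng.normal(config.drift_effect_size if responder else 0.0, slope_sd)

    bright, fid_excl = _place_fiducials(
        roi, spacing, config.fiducial_count, config.fiducial_mask_dilation_mm, rng
    )

    # DIR contour error: a persistent per-patient component plus a smaller
    # per-fraction refresh, mimicking systematic registration bias
    w = float(np.clip(config.auto_error_refresh, 0.0, 1.0))
    g_patient = _smooth_field(rng.standard_normal(shape), 3.0, spacing)

    fractions: list[Fraction] = []
    ell0 = config.texture_correlation_length_mm
    for k in range(schedule.n_fractions):
        ell = max(ell0 + slope * k, 0.25 * ell0)
        # fresh field realization per fraction: day-to-day texture sampling
        # variation is the dominant, arm-shared noise source in the DRFs
        tex = _smooth_field(rng.standard_normal(shape), ell, spacing)
        img = tex + rng.normal(0.0, config.noise_sd, size=shape)
        img[bright] = config.fiducial_intensity
        image = VolumeImage(img, spacing)
        g_fx = _smooth_field(rng.standard_normal(shape), 3.0, spacing)
        g = np.sqrt(1.0 - w) * g_patient + np.sqrt(w) * g_fx
        automated = perturb_mask_to_dsc(manual, config.target_auto_dsc, rng, field=g)
        fractions.append(
            Fraction(
                image=image,
                manual=ROIMask(roi.copy(), spacing),
                automated=automated,
                fiducial=ROIMask(fid_excl.copy(), spacing),
            )
        )

    acute = int(responder)
    subacute = int(responder != (rng.random() < config.subacute_flip_prob))
    ipss_baseline = int(rng.integers(5, 20))
    shift = config.ipss_shift if responder else 0.0
    ipss_post = max(0, int(round(ipss_baseline + shift + rng.normal(0, config.ipss_noise_sd))))
    return PatientCourse(
        patient_id=patient_id,
        schedule=schedule,
        fractions=fractions,
        outcome_acute=acute,
        outcome_subacute=subacute,
        ipss_baseline=ipss_baseline,
        ipss_post=ipss_post,
        latent_slope=float(slope),
    )


def generate_cohort(config: CohortConfig) -> list[PatientCourse]:
    """Generate a deterministic synthetic cohort from a config."""
    ss = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.spawn(config.n_patients)

    weights = np.asarray(config.schedule_weights, dtype=float)
    weights = weights / weights.sum()
    sched_idx = master.choice(len(config.schedules), size=config.n_patients, p=weights)
    responders = master.random(config.n_patients) < config.outcome_prevalence

    cohort = []
    for i in range(config.n_patients):
        total, n_fx = config.schedules[sched_idx[i]]
        schedule = FractionationSchedule.uniform(total, n_fx, config.alpha_beta_gy)
        cohort.append(
            generate_patient(
                config,
                patient_id=f"P{i:03d}",
                schedule=schedule,
                responder=bool(responders[i]),
                rng=np.random.default_rng(child_seeds[i]),
            )
        )
    return cohort


def summarize_cohort(cohort: list[PatientCourse]) -> pd.DataFrame:
    """One QA row per patient: schedule, outcomes, mean DSC, fiducial fraction."""
    if not cohort:
        raise ValueError("empty cohort")
    rows = []
    for p in cohort:
        dscs = [dice(fx.manual, fx.automated) for fx in p.fractions]
        fid_fracs = [
            (fx.fiducial.data & fx.manual.data).sum() / fx.manual.n_voxels
            for fx in p.fractions
        ]
        rows.append(
            {
                "patient": p.patient_id,
                "n_fractions": p.schedule.n_fractions,
                "total_dose_gy": sum(p.schedule.dose_per_fraction_gy),
                "outcome_acute": p.outcome_acute,
                "outcome_subacute": p.outcome_subacute,
                "ipss_baseline": p.ipss_baseline,
                "ipss_post": p.ipss_post,
                "delta_ipss": p.delta_ipss,
                "mean_dsc": float(np.mean(dscs)),
                "fiducial_volume_fraction": float(np.mean(fid_fracs)),
            }
        )
    return pd.DataFrame(rows).set_index("patient")


def cohort_outcomes(
    cohort: list[PatientCourse], delta_ipss_threshold: int = 0
) -> pd.DataFrame:
    """Binary endpoint table for modeling, indexed by patient.

    ``delta_ipss`` is dichotomized as an IPSS increase strictly greater
    than ``delta_ipss_threshold`` (default: any increase).
    """
    return pd.DataFrame(
        {
            "acute_gu": [p.outcome_acute for p in cohort],
            "subacute_gu": [p.outcome_subacute for p in cohort],
            "delta_ipss": [int(p.delta_ipss > delta_ipss_threshold) for p in cohort],
            "ipss_baseline": [p.ipss_baseline for p in cohort],
        },
        index=pd.Index([p.patient_id for p in cohort], name="patient"),
    )
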
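"""Seeded synthetic SHG phantoms and cohorts with known ground truth.

No patient images are distributed with this package, so every pipeline
stage is exercised against generated data whose truth is known by
construction:

* :func:`generate_phantom` renders a two-channel fibrous image stack —
  ribbon-shaped fibers with axially wrapped-normal orientations, a
  uniform (or per-fiber) true F/B ratio, per-channel background
  offsets, and shot-like noise — and returns the ground-truth fiber
  mask, fiber angles and ratio alongside the stack.
* :func:`generate_cohort` draws a two-group patient cohort with
  group-by-region metric means, a per-patient random intercept and
  per-ROI noise, plus clinical covariates, mirroring the repeated-
  measures structure of a two-region, three-fields-of-view-per-region
  imaging study.

Both generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .fibers import Fiber
from .io import ImagePairStack
from .stats import CohortTable, MEASUREMENT_COLUMNS

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "CohortConfig",
    "generate_phantom",
    "generate_cohort",
    "PackingError",
]


class PackingError(RuntimeError):
    """Could not place the requested number of fibers in the image."""


@dataclass(frozen=True)
class PhantomConfig:
    """Ground-truth parameters of a fibrous two-channel phantom.

    Defaults emulate the acquisition geometry of the imaging study the
    pipeline targets: 512x512 fields, 3-slice z-stacks, fiber-scale
    structures with a tumor-stroma-interface-like true F/B of 16.

    Attributes
    ----------
    true_fb : float or sequence of float
        Uniform per-pixel F/B ratio, or one ratio per fiber.
    f_amplitude : float
        Forward-channel intensity at the fiber core. The backward
        channel renders at ``f_amplitude / true_fb`` so that
        F = true_fb x B exactly before background and noise.
    angle_mean_deg, angle_sd_deg : float
        Axial wrapped-normal orientation distribution: draw
        Normal(mean, sd), reduce mod 180.
    curvature : float
        Fractional sinusoidal bending of each fiber (0 = straight).
    noise_model : {"none", "poisson", "gaussian"}
        Poisson mimics shot noise: ``noise_scale`` is the detector gain
        in intensity units per detected photon, so photon counts are
        ``intensity / noise_scale`` and the noisy image is
        ``Poisson(intensity / noise_scale) * noise_scale``. Gaussian
        adds N(0, noise_scale) for analytic tests. The default
        amplitude/gain pair puts the backward channel in the
        several-thousand-photon regime of a bright acquisition, where
        the small-sample biases of the ratio estimator (1/B curvature,
        max-projection order statistics, mask selection) are well below
        the estimator's own spread.
    allow_overlap : bool
        When False, fibers are packed with rejection sampling so their
        footprints (padded by ``min_separation_px``) do not touch;
        infeasible packings raise :class:`PackingError` after bounded
        retries.
    """

    shape: tuple[int, int] = (512, 512)
    n_fibers: int = 30
    fiber_width_px: float = 4.0
    fiber_length_range_px: tuple[float, float] = (100.0, 300.0)
    angle_mean_deg: float = 90.0
    angle_sd_deg: float = 20.0
    curvature: float = 0.02
    true_fb: float | tuple[float, ...] = 16.0
    f_amplitude: float = 40000.0
    background_f: float = 200.0
    background_b: float = 200.0
    noise_model: Literal["none", "poisson", "gaussian"] = "poisson"
    noise_scale: float = 0.25
    n_slices: int = 3
    seed: int = 0
    allow_overlap: bool = True
    min_separation_px: float = 2.0
    max_retries_per_fiber: int = 2000

    def __post_init__(self) -> None:
        if min(self.shape) < 16:
            raise ValueError("shape must be at least 16x16")
        ratios = np.atleast_1d(np.asarray(self.true_fb, dtype=float))
        if np.any(ratios <= 0):
            raise ValueError("true_fb must be > 0")
        if ratios.size not in (1, self.n_fibers):
            raise ValueError("true_fb must be scalar or one value per fiber")
        if self.angle_sd_deg < 0:
            raise ValueError("angle_sd_deg must be >= 0")
        if self.n_fibers < 1 or self.n_slices < 1:
            raise ValueError("n_fibers and n_slices must be >= 1")
        if self.background_f < 0 or self.background_b < 0:
            raise ValueError("backgrounds must be >= 0")


@dataclass(frozen=True)
class PhantomTruth:
    """What the generator actually drew.

    ``fiber_mask`` is the ground-truth fiber footprint (centerline
    distance within half the nominal width); ``rendered_mask`` is the
    full extent carrying any fiber signal, including the soft
    transverse falloff outside the nominal width. True background —
    pixels with no signal at all — is the complement of
    ``rendered_mask``.
    """

    fiber_mask: np.ndarray
    rendered_mask: np.ndarray
    fibers: tuple[Fiber, ...]
    true_fb: float | tuple[float, ...]


def _render_fiber(
    shape: tuple[int, int],
    center: tuple[float, float],
    angle_deg: float,
    length: float,
    width: float,
    curvature: float,
    phase: float,
) -> tuple[tuple[slice, slice], np.ndarray, np.ndarray] | None:
    """Render one fiber as a ridge with a Gaussian cross-profile.

    Returns ``(window, dist_patch, profile_patch)`` — the bounding-box
    slices into the image, the centerline distance field over that
    patch, and the [0, 1] intensity profile — or None if too much of
    the fiber falls outside the image. The profile sigma is 0.75 x
    width, so the whole ground-truth core (distance <= width/2) lies in
    the concave part of the cross-section; this mirrors the soft
    transverse falloff of real imaged fibers (point-spread blur plus
    out-of-focus light) and makes the core locally brighter than any
    window mean around it. Rendering is patch-local for speed.
    """
    nr, nc = shape
    a = np.deg2rad(angle_deg)
    d = np.array([-np.sin(a), np.cos(a)])  # (d_row, d_col), row axis = 0 deg
    perp = np.array([-d[1], d[0]])
    t = np.arange(-length / 2.0, length / 2.0 + 0.25, 0.5)
    offset = curvature * length * np.sin(2.0 * np.pi * t / length + phase)
    pts = np.asarray(center) + t[:, None] * d + offset[:, None] * perp
    rr = np.round(pts[:, 0]).astype(int)
    cc = np.round(pts[:, 1]).astype(int)
    keep = (rr >= 0) & (rr < nr) & (cc >= 0) & (cc < nc)
    if keep.sum() < 0.75 * len(t):  # too much of the fiber off-image
        return None
    rr, cc = rr[keep], cc[keep]
    sigma = 0.75 * width
    pad = int(np.ceil(3.0 * sigma)) + 2
    r0 = max(int(rr.min()) - pad, 0)
    r1 = min(int(rr.max()) + pad + 1, nr)
    c0 = max(int(cc.min()) - pad, 0)
    c1 = min(int(cc.max()) + pad + 1, nc)
    patch = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    patch[rr - r0, cc - c0] = True
    dist = ndimage.distance_transform_edt(~patch)
    profile = np.where(
        dist <= 3.0 * sigma, np.exp(-(dist**2) / (2.0 * sigma**2)), 0.0
    )
    return (slice(r0, r1), slice(c0, c1)), dist, profile


def generate_phantom(config: PhantomConfig) -> tuple[ImagePairStack, PhantomTruth]:
    """Render a seeded two-channel fibrous phantom with known truth.

    The noiseless construction satisfies F = true_fb x B exactly on
    every pixel (before background/noise); all slices share the fiber
    geometry and differ only in noise, so maximum projection acts as an
    autofocus surrogate. Identical configs produce bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    nr, nc = config.shape
    ratios = np.atleast_1d(np.asarray(config.true_fb, dtype=float))
    if ratios.size == 1:
        ratios = np.repeat(ratios, config.n_fibers)

    base_b = np.zeros(config.shape, dtype=np.float64)
    base_f = np.zeros(config.shape, dtype=np.float64)
    union = np.zeros(config.shape, dtype=bool)  # ground-truth cores
    occupied = np.zeros(config.shape, dtype=bool)  # full rendered extents
    fibers: list[Fiber] = []
    lo, hi = config.fiber_length_range_px
    margin = 0.1 * min(nr, nc)

    sigma = 0.75 * config.fiber_width_px
    extent = 3.0 * sigma
    for i in range(config.n_fibers):
        # angle and length are drawn once per fiber; only the placement is
        # retried on collision, so non-overlap packing cannot skew the
        # realized orientation distribution toward the mean direction
        angle = float(
            (rng.normal(config.angle_mean_deg, config.angle_sd_deg)) % 180.0
        )
        length = float(rng.uniform(lo, hi))
        placed = False
        for _ in range(config.max_retries_per_fiber):
            center = (
                rng.uniform(margin, nr - margin),
                rng.uniform(margin, nc - margin),
            )
            phase = float(rng.uniform(0, 2 * np.pi))
            rendered = _render_fiber(
                config.shape, center, angle, length, config.fiber_width_px,
                config.curvature, phase,
            )
            if rendered is None:
                continue
            window, dist, profile = rendered
            if not config.allow_overlap:
                padded = dist <= extent + config.min_separation_px
                if (padded & occupied[window]).any():
                    continue
            amp_b = config.f_amplitude / ratios[i]
            base_b[window] = np.maximum(base_b[window], amp_b * profile)
            base_f[window] = np.maximum(base_f[window], ratios[i] * (amp_b * profile))
            core = dist <= config.fiber_width_px / 2.0
            union[window] |= core
            occupied[window] |= profile > 0
            rr, cc = np.nonzero(core)
            fibers.append(
                Fiber(
                    angle_deg=angle,
                    centroid=(
                        float(rr.mean()) + window[0].start,
                        float(cc.mean()) + window[1].start,
                    ),
                    length_px=length,
                    mean_intensity=float(config.f_amplitude),
                )
            )
            placed = True
            break
        if not placed:
            raise PackingError(
                f"could not place fiber {i + 1}/{config.n_fibers} in shape "
                f"{config.shape} after {config.max_retries_per_fiber} retries"
            )

    f_clean = base_f + config.background_f
    b_clean = base_b + config.background_b

    def _noisy(img: np.ndarray) -> np.ndarray:
        if config.noise_model == "none":
            return img.copy()
        if config.noise_model == "poisson":
            s = config.noise_scale
            return rng.poisson(img / s).astype(np.float64) * s
        if config.noise_model == "gaussian":
            return np.clip(img + rng.normal(0.0, config.noise_scale, img.shape), 0, None)
        raise ValueError(f"unknown noise_model {config.noise_model!r}")

    f_stack = np.stack([_noisy(f_clean) for _ in range(config.n_slices)])
    b_stack = np.stack([_noisy(b_clean) for _ in range(config.n_slices)])

    stack = ImagePairStack(
        f_stack=f_stack.astype(np.float32),
        b_stack=b_stack.astype(np.float32),
        patient_id=f"phantom-{config.seed}",
    )
    truth = PhantomTruth(
        fiber_mask=union,
        rendered_mask=occupied,
        fibers=tuple(fibers),
        true_fb=config.true_fb,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# synthetic cohorts


def _default_group_means() -> dict:
    # group x region means for FB and FAV, loosely shaped like a
    # two-region carcinoma imaging study (interface F/B above bulk F/B)
    return {
        "A": {"TSI": {"FB": 16.0, "FAV": 39.0}, "TB": {"FB": 7.0, "FAV": 44.0}},
        "B": {"TSI": {"FB": 18.5, "FAV": 40.5}, "TB": {"FB": 8.3, "FAV": 44.0}},
    }


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a two-group repeated-measures cohort.

    Per-ROI measurement = group/region mean + patient intercept
    (Normal(0, patient_sd)) + ROI noise (Normal(0, roi_sd)). Covariates
    (age, BMI, sex, pT stage, grade, smoking) are drawn per group from
    simple parametric models and may be missing at a configurable rate.
    """

    n_patients_per_group: tuple[int, int] = (77, 11)
    group_labels: tuple[str, str] = ("A", "B")
    rois_per_region: int = 3
    regions: tuple[str, ...] = ("TB", "TSI")
    metrics: tuple[str, ...] = ("FB", "FAV")
    group_means: Mapping = field(default_factory=_default_group_means)
    patient_sd: float = 3.0
    roi_sd: float = 2.0
    age_mean: tuple[float, float] = (67.8, 62.6)
    age_sd: tuple[float, float] = (13.0, 8.6)
    bmi_mean: tuple[float, float] = (28.5, 30.9)
    bmi_sd: tuple[float, float] = (5.0, 6.5)
    female_frac: tuple[float, float] = (0.49, 0.36)
    pt_probs: tuple[tuple[float, ...], tuple[float, ...]] = (
        (0.69, 0.31, 0.0),
        (0.73, 0.27, 0.0),
    )
    grade_probs: tuple[tuple[float, ...], tuple[float, ...]] = (
        (0.21, 0.60, 0.19),
        (0.09, 0.82, 0.09),
    )
    smoking_frac: tuple[float, float] = (0.47, 0.36)
    missing_bmi_frac: float = 0.13
    cohort_name: str = "CRC"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patient_sd < 0 or self.roi_sd < 0:
            raise ValueError("SDs must be >= 0")
        if any(n < 1 for n in self.n_patients_per_group):
            raise ValueError("counts must be >= 1")
        if self.rois_per_region < 1:
            raise ValueError("rois_per_region must be >= 1")


def generate_cohort(config: CohortConfig) -> CohortTable:
    """Draw a seeded synthetic cohort with known statistical structure."""
    rng = np.random.default_rng(config.seed)
    patient_rows = []
    meas_rows = []
    pt_levels = ("T1", "T2", "T3")
    for gi, (glabel, n) in enumerate(
        zip(config.group_labels, config.n_patients_per_group)
    ):
        for k in range(n):
            pid = f"{glabel}{k:04d}"
            bmi = float(rng.normal(config.bmi_mean[gi], config.bmi_sd[gi]))
            bmi = max(bmi, 15.0)
            if rng.uniform() < config.missing_bmi_frac:
                bmi = np.nan
            patient_rows.append(
                {
                    "patient_id": pid,
                    "group": glabel,
                    "cohort": config.cohort_name,
                    "age_years": float(
                        np.clip(rng.normal(config.age_mean[gi], config.age_sd[gi]), 18, 100)
                    ),
                    "sex": "F" if rng.uniform() < config.female_frac[gi] else "M",
                    "bmi": bmi,
                    "pt_stage": pt_levels[
                        rng.choice(len(pt_levels), p=np.asarray(config.pt_probs[gi]))
                    ],
                    "grade": int(
                        rng.choice((1, 2, 3), p=np.asarray(config.grade_probs[gi]))
                    ),
                    "smoking": bool(rng.uniform() < config.smoking_frac[gi]),
                }
            )
            # one random intercept per patient per metric
            intercepts = {m: rng.normal(0.0, config.patient_sd) for m in config.metrics}
            for region in config.regions:
                for metric in config.metrics:
                    mu = config.group_means[glabel][region][metric]
                    for roi in range(1, config.rois_per_region + 1):
                        meas_rows.append(
                            {
                                "patient_id": pid,
                                "region_label": region,
                                "roi_index": roi,
                                "metric": metric,
                                "value": float(
                                    mu
                                    + intercepts[metric]
                                    + rng.normal(0.0, config.roi_sd)
                                ),
                            }
                        )
    return CohortTable(
        patients=pd.DataFrame(patient_rows),
        measurements=pd.DataFrame(meas_rows, columns=MEASUREMENT_COLUMNS),
    )
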
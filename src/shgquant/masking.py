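"""Adaptive progressive-window thresholding and the F/B metric.

The forward/backward scattering ratio (F/B) of an SHG field of view is
the mean per-pixel ratio of forward to backward intensity over pixels
that lie inside collagen fibers in *both* channels. Fiber pixels are
found with a two-stage threshold:

1. A global seed: the image is binarized at ``global_factor`` (default
   0.6) times its mean intensity.
2. A locally adaptive pass: for every pixel, a series of progressively
   smaller windows is centered on it and the fraction of seed-mask
   pixels inside each window is computed. The smallest window whose
   fill fraction exceeds ``min_fill_fraction`` (default 5%) supplies
   the local threshold, and the pixel is set iff its intensity is
   strictly greater than the mean intensity within that window.

The F mask and B mask are multiplied to form the combined F/B mask,
which is applied to the background-subtracted ratio image; the reported
F/B value is the mean of the strictly positive finite ratios.

Both an optimized implementation (integral images, one pass per window
size) and a naive per-pixel double-loop reference are provided; they
are bit-identical by construction because both compare
``pixel * window_area > window_sum`` in float64 (no division), which is
exact for integer-valued data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io import ImagePairStack, ProjectedPair, max_project, subtract_background

__all__ = [
    "MaskingParams",
    "FBMask",
    "FBResult",
    "EmptyMaskError",
    "default_window_schedule",
    "global_binarize",
    "adaptive_window_threshold",
    "adaptive_window_threshold_naive",
    "build_masks",
    "compute_fb",
    "fb_fov_batch",
]


class EmptyMaskError(ValueError):
    """Raised when the combined F/B mask selects no usable ratio pixels."""


def default_window_schedule(shape: tuple[int, int]) -> tuple[int, ...]:
    """Geometric window schedule: odd sizes halving from the image down to 3.

    For a 512x512 image this yields (511, 255, 127, 63, 31, 15, 7, 3),
    spanning all scales at logarithmic cost.
    """
    n = min(shape)
    if n < 3:
        raise ValueError(f"image too small for windowing: shape {shape}")
    s = n if n % 2 == 1 else n - 1
    schedule = [s]
    while s > 3:
        s = s // 2
        if s % 2 == 0:
            s -= 1
        s = max(s, 3)
        schedule.append(s)
    return tuple(schedule)


@dataclass(frozen=True)
class MaskingParams:
    """Parameters of the progressive-window adaptive threshold.

    Attributes
    ----------
    global_factor : float
        Multiple of the whole-image mean used for the seed binarization
        (default 0.6).
    min_fill_fraction : float
        A window qualifies when its fraction of seed-mask pixels is
        strictly greater than this (default 0.05).
    window_schedule : tuple of int or None
        Strictly decreasing odd window side lengths (px), all >= 3.
        ``None`` (default) derives the geometric schedule from the
        image shape at call time.
    nodata_policy : {"background", "largest_window"}
        What to do for pixels where no window qualifies: treat as
        background (0) or threshold with the largest window anyway.
    """

    global_factor: float = 0.6
    min_fill_fraction: float = 0.05
    window_schedule: tuple[int, ...] | None = None
    nodata_policy: Literal["background", "largest_window"] = "background"

    def __post_init__(self) -> None:
        if not self.global_factor > 0:
            raise ValueError("global_factor must be > 0")
        if not 0 < self.min_fill_fraction < 1:
            raise ValueError("min_fill_fraction must be in (0, 1)")
        if self.nodata_policy not in ("background", "largest_window"):
            raise ValueError(f"unknown nodata_policy {self.nodata_policy!r}")
        if self.window_schedule is not None:
            sched = tuple(int(s) for s in self.window_schedule)
            if len(sched) == 0:
                raise ValueError("window_schedule must be nonempty")
            for s in sched:
                if s < 3 or s % 2 == 0:
                    raise ValueError(
                        f"window sizes must be odd and >= 3; got {s} in {sched}"
                    )
            if any(b >= a for a, b in zip(sched, sched[1:])):
                raise ValueError(f"window_schedule must be strictly decreasing: {sched}")
            object.__setattr__(self, "window_schedule", sched)

    def schedule_for(self, shape: tuple[int, int]) -> tuple[int, ...]:
        if self.window_schedule is not None:
            return self.window_schedule
        return default_window_schedule(shape)


@dataclass(frozen=True)
class FBMask:
    """Binary F and B masks and their elementwise product."""

    f_mask: np.ndarray
    b_mask: np.ndarray
    combined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        f = np.asarray(self.f_mask, dtype=bool)
        b = np.asarray(self.b_mask, dtype=bool)
        if f.shape != b.shape:
            raise ValueError("f_mask and b_mask must have identical shape")
        object.__setattr__(self, "f_mask", f)
        object.__setattr__(self, "b_mask", b)
        object.__setattr__(self, "combined", f & b)


@dataclass(frozen=True)
class FBResult:
    """Scalar F/B metric for one field of view.

    ``ratio_image`` is 0 outside the combined mask; ``fb_value`` is the
    mean of its strictly positive finite entries and ``n_pixels`` their
    count.
    """

    fb_value: float
    n_pixels: int
    ratio_image: np.ndarray


def global_binarize(img: np.ndarray, factor: float = 0.6) -> np.ndarray:
    """Seed mask: pixel is set iff intensity > factor * mean(image).

    An all-zero image yields an all-zero mask (strict inequality
    against a zero threshold), not an error.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise ValueError("image must be nonempty")
    if np.any(img < 0):
        raise ValueError("image must be nonnegative")
    return img > factor * img.mean()


def _integral(img: np.ndarray) -> np.ndarray:
    s = np.zeros((img.shape[0] + 1, img.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(img, axis=0), axis=1, out=s[1:, 1:])
    return s


def _box_sums(integral: np.ndarray, half: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel sums over (2*half+1)-windows clipped at the borders.

    Returns the sum array and the clipped window areas.
    """
    nr, nc = integral.shape[0] - 1, integral.shape[1] - 1
    r = np.arange(nr)
    c = np.arange(nc)
    r0 = np.maximum(r - half, 0)
    r1 = np.minimum(r + half + 1, nr)
    c0 = np.maximum(c - half, 0)
    c1 = np.minimum(c + half + 1, nc)
    s = (
        integral[np.ix_(r1, c1)]
        - integral[np.ix_(r0, c1)]
        - integral[np.ix_(r1, c0)]
        + integral[np.ix_(r0, c0)]
    )
    area = (r1 - r0)[:, None] * (c1 - c0)[None, :]
    return s, area


def adaptive_window_threshold(
    img: np.ndarray, seed_mask: np.ndarray, params: MaskingParams
) -> np.ndarray:
    """Progressive-window adaptive threshold (optimized implementation).

    For each pixel the window schedule is scanned and, among the
    (border-clipped) windows whose seed-mask fill fraction strictly
    exceeds ``min_fill_fraction``, the smallest is selected; the output
    pixel is 1 iff its intensity strictly exceeds the mean intensity
    within that window. Pixels with no qualifying window follow
    ``nodata_policy``.
    """
    img = np.asarray(img, dtype=np.float64)
    seed = np.asarray(seed_mask)
    if img.shape != seed.shape:
        raise ValueError("img and seed_mask must have identical shape")
    schedule = params.schedule_for(img.shape)

    img_int = _integral(img)
    seed_int = _integral((seed != 0).astype(np.float64))

    chosen_sum = np.zeros_like(img)
    chosen_area = np.zeros(img.shape, dtype=np.int64)
    any_qualified = np.zeros(img.shape, dtype=bool)
    largest_sum = largest_area = None
    # largest -> smallest: each later qualifying (smaller) window overrides,
    # leaving the smallest qualifying window selected at every pixel.
    for size in schedule:
        half = size // 2
        s_img, area = _box_sums(img_int, half)
        s_seed, _ = _box_sums(seed_int, half)
        if largest_sum is None:
            largest_sum, largest_area = s_img, area
        qual = s_seed > params.min_fill_fraction * area
        chosen_sum = np.where(qual, s_img, chosen_sum)
        chosen_area = np.where(qual, area, chosen_area)
        any_qualified |= qual

    # pixel * area > sum  <=>  pixel > mean, exact for integer-valued data
    out = any_qualified & (img * chosen_area > chosen_sum)
    if params.nodata_policy == "largest_window":
        fallback = img * largest_area > largest_sum
        out = np.where(any_qualified, out, fallback)
    return out


def adaptive_window_threshold_naive(
    img: np.ndarray, seed_mask: np.ndarray, params: MaskingParams
) -> np.ndarray:
    """Per-pixel double-loop reference for :func:`adaptive_window_threshold`.

    Quadratic in the window size and meant for small images; kept as
    the executable definition of the algorithm that the optimized path
    must match bit for bit.
    """
    img = np.asarray(img, dtype=np.float64)
    seed = np.asarray(seed_mask) != 0
    if img.shape != seed.shape:
        raise ValueError("img and seed_mask must have identical shape")
    schedule = params.schedule_for(img.shape)
    nr, nc = img.shape
    out = np.zeros(img.shape, dtype=bool)
    for r in range(nr):
        for c in range(nc):
            selected = None  # (sum, area) of smallest qualifying window
            largest = None
            for size in schedule:
                half = size // 2
                r0, r1 = max(r - half, 0), min(r + half + 1, nr)
                c0, c1 = max(c - half, 0), min(c + half + 1, nc)
                area = (r1 - r0) * (c1 - c0)
                win_sum = float(img[r0:r1, c0:c1].sum())
                if largest is None:
                    largest = (win_sum, area)
                if float(seed[r0:r1, c0:c1].sum()) > params.min_fill_fraction * area:
                    selected = (win_sum, area)  # schedule decreasing: keep last
            if selected is None:
                if params.nodata_policy == "largest_window":
                    selected = largest
                else:
                    continue
            win_sum, area = selected
            out[r, c] = img[r, c] * area > win_sum
    return out


def build_masks(pair: ProjectedPair, params: MaskingParams | None = None) -> FBMask:
    """Adaptive masks for both channels of a background-subtracted pair."""
    params = params or MaskingParams()
    f_mask = adaptive_window_threshold(
        pair.f_img, global_binarize(pair.f_img, params.global_factor), params
    )
    b_mask = adaptive_window_threshold(
        pair.b_img, global_binarize(pair.b_img, params.global_factor), params
    )
    return FBMask(f_mask=f_mask, b_mask=b_mask)


def compute_fb(pair: ProjectedPair, mask: FBMask) -> FBResult:
    """F/B metric: mean of positive finite per-pixel ratios inside the mask.

    Pixels with nonpositive backward intensity are excluded (the mean
    of the nonzero ratio pixels is only defined over finite ratios).

    Raises
    ------
    EmptyMaskError
        If no pixel contributes a positive finite ratio.
    """
    f = np.asarray(pair.f_img, dtype=np.float64)
    b = np.asarray(pair.b_img, dtype=np.float64)
    if f.shape != mask.combined.shape:
        raise ValueError("pair and mask must have identical shape")
    valid = mask.combined & (b > 0)
    ratio = np.zeros_like(f)
    np.divide(f, b, out=ratio, where=valid)
    contributing = valid & (ratio > 0) & np.isfinite(ratio)
    n = int(contributing.sum())
    if n == 0:
        raise EmptyMaskError("combined mask contains no positive finite F/B pixels")
    ratio[~contributing] = 0.0
    return FBResult(fb_value=float(ratio[contributing].mean()), n_pixels=n, ratio_image=ratio)


def fb_pipeline(
    stack: ImagePairStack,
    params: MaskingParams | None = None,
    *,
    background_method: str = "constant",
    background_f: float = 0.0,
    background_b: float = 0.0,
) -> FBResult:
    """project -> subtract background -> mask -> F/B for one acquisition."""
    pair = subtract_background(
        max_project(stack), background_method, background_f, background_b
    )
    return compute_fb(pair, build_masks(pair, params))


def fb_fov_batch(
    stacks: Iterable[ImagePairStack],
    params: MaskingParams | None = None,
    *,
    background_method: str = "constant",
    background_f: float = 0.0,
    background_b: float = 0.0,
) -> pd.DataFrame:
    """Per-field-of-view F/B table: one row per acquisition.

    Columns: patient_id, region_label, roi_index, fb_value, n_pixels.

    Raises
    ------
    ValueError
        If two stacks share a (patient_id, region_label, roi_index) key.
    """
    rows = []
    seen: set[tuple] = set()
    for stack in stacks:
        key = stack.key()
        if key in seen:
            raise ValueError(f"duplicate field-of-view key {key}")
        seen.add(key)
        res = fb_pipeline(
            stack,
            params,
            background_method=background_method,
            background_f=background_f,
            background_b=background_b,
        )
        rows.append(
            {
                "patient_id": key[0],
                "region_label": key[1],
                "roi_index": key[2],
                "fb_value": res.fb_value,
                "n_pixels": res.n_pixels,
            }
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "region_label", "roi_index", "fb_value", "n_pixels"]
    )
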
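"""Data model and I/O for paired two-channel SHG z-stacks.

Second-harmonic generation (SHG) microscopy of collagen records two
detector channels per field of view: the forward-scattered signal (F,
collected through the condenser, in the direction of laser propagation)
and the backward-scattered signal (B, epi-collected through the
objective). Each channel is acquired as a short z-stack (typically
three 512x512 slices at a 2 um step) and reduced to a single image by
maximum-intensity projection, which acts as a per-pixel autofocus when
the section is not perfectly parallel to the image plane.

This module holds the in-memory containers (:class:`ImagePairStack`,
:class:`ProjectedPair`), TIFF reading/writing, the projection, and
background subtraction. Pixel coordinates are 0-based ``(row, col)``;
intensities are nonnegative reals after background subtraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import tifffile

__all__ = [
    "ImagePairStack",
    "ProjectedPair",
    "read_pair",
    "write_pair",
    "max_project",
    "subtract_background",
    "estimate_offscene_background",
]

RegionLabel = Literal["TB", "TSI"]
_VALID_REGIONS = ("TB", "TSI")


@dataclass(frozen=True)
class ImagePairStack:
    """Paired forward/backward SHG z-stacks with acquisition metadata.

    Parameters
    ----------
    f_stack, b_stack : ndarray, shape (slices, rows, cols)
        Nonnegative intensity stacks for the forward (F) and backward
        (B) channels. Shapes must match exactly.
    pixel_size_um : float
        Lateral pixel size in micrometres per pixel.
    z_step_um : float
        Axial step between slices in micrometres.
    region_label : {"TB", "TSI"}
        Imaged region: cellular tumor bulk or collagenous tumor-stroma
        interface.
    patient_id : str
        Opaque patient identifier.
    roi_index : int
        Field-of-view index within the region (1-based, typically 1..3).
    """

    f_stack: np.ndarray
    b_stack: np.ndarray
    pixel_size_um: float = 0.5
    z_step_um: float = 2.0
    region_label: RegionLabel = "TSI"
    patient_id: str = "unknown"
    roi_index: int = 1

    def __post_init__(self) -> None:
        f = np.asarray(self.f_stack)
        b = np.asarray(self.b_stack)
        if f.ndim != 3 or b.ndim != 3:
            raise ValueError(
                f"stacks must be 3-D (slices, rows, cols); got {f.ndim}-D / {b.ndim}-D"
            )
        if f.shape != b.shape:
            raise ValueError(
                f"F and B stacks must have identical shape; got {f.shape} vs {b.shape}"
            )
        if f.shape[0] < 1:
            raise ValueError("stack must contain at least one slice")
        if np.any(f < 0) or np.any(b < 0):
            raise ValueError("intensities must be nonnegative")
        if self.region_label not in _VALID_REGIONS:
            raise ValueError(
                f"region_label must be one of {_VALID_REGIONS}; got {self.region_label!r}"
            )
        if not 1 <= int(self.roi_index):
            raise ValueError("roi_index must be >= 1")
        object.__setattr__(self, "f_stack", f)
        object.__setattr__(self, "b_stack", b)

    @property
    def n_slices(self) -> int:
        return self.f_stack.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.f_stack.shape

    def key(self) -> tuple[str, str, int]:
        """(patient_id, region_label, roi_index) identity of this field of view."""
        return (self.patient_id, self.region_label, int(self.roi_index))


@dataclass(frozen=True)
class ProjectedPair:
    """Maximum-intensity-projected F/B image pair.

    ``background_f``/``background_b`` record the per-channel offsets
    already subtracted from ``f_img``/``b_img`` (0 before subtraction).
    ``provenance`` carries the source :class:`ImagePairStack` metadata.
    """

    f_img: np.ndarray
    b_img: np.ndarray
    background_f: float = 0.0
    background_b: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.f_img)
        b = np.asarray(self.b_img)
        if f.ndim != 2 or b.ndim != 2:
            raise ValueError("projected images must be 2-D")
        if f.shape != b.shape:
            raise ValueError(
                f"F and B images must have identical shape; got {f.shape} vs {b.shape}"
            )
        if self.background_f < 0 or self.background_b < 0:
            raise ValueError("background offsets must be >= 0")
        object.__setattr__(self, "f_img", f)
        object.__setattr__(self, "b_img", b)

    @property
    def shape(self) -> tuple[int, int]:
        return self.f_img.shape


def read_pair(
    f_path: str | Path,
    b_path: str | Path | None = None,
    *,
    pixel_size_um: float = 0.5,
    z_step_um: float = 2.0,
    region_label: RegionLabel = "TSI",
    patient_id: str = "unknown",
    roi_index: int = 1,
) -> ImagePairStack:
    """Read a paired F/B acquisition from TIFF file(s).

    Two dialects are accepted: two separate single-channel multi-page
    TIFFs (``f_path`` and ``b_path``, matching two-detector
    acquisition), or a single file whose pages interleave two channels
    in F,B order along a channel axis (``b_path=None``; the file must
    then have shape ``(slices, 2, rows, cols)`` or ``(2, slices, rows,
    cols)``).

    Raises
    ------
    ValueError
        If page counts or dimensions of the two channels differ.
    OSError
        If a file cannot be read.
    """
    if b_path is not None:
        f = _read_stack(f_path)
        b = _read_stack(b_path)
        if f.shape != b.shape:
            raise ValueError(
                f"channel shape mismatch: F {f.shape} from {f_path} vs "
                f"B {b.shape} from {b_path}"
            )
    else:
        arr = tifffile.imread(str(f_path))
        arr = np.asarray(arr)
        if arr.ndim != 4 or 2 not in (arr.shape[0], arr.shape[1]):
            raise ValueError(
                "single-file pairs must be 4-D with a length-2 channel axis "
                f"(F,B order); got shape {arr.shape}"
            )
        if arr.shape[1] == 2:  # (slices, 2, rows, cols)
            f, b = arr[:, 0], arr[:, 1]
        else:  # (2, slices, rows, cols)
            f, b = arr[0], arr[1]
    return ImagePairStack(
        f_stack=f,
        b_stack=b,
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        region_label=region_label,
        patient_id=patient_id,
        roi_index=roi_index,
    )


def _read_stack(path: str | Path) -> np.ndarray:
    arr = np.asarray(tifffile.imread(str(path)))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a single-channel (multi-page) TIFF, got shape {arr.shape}")
    return arr


def write_pair(stack: ImagePairStack, f_path: str | Path, b_path: str | Path) -> None:
    """Write the two channels as multi-page grayscale TIFFs (dtype preserved)."""
    tifffile.imwrite(str(f_path), stack.f_stack, photometric="minisblack")
    tifffile.imwrite(str(b_path), stack.b_stack, photometric="minisblack")


def max_project(stack: ImagePairStack) -> ProjectedPair:
    """Maximum-intensity projection of each channel over slices.

    Each output pixel is the maximum over z of that pixel; the two
    channels are projected independently.
    """
    prov = {
        "patient_id": stack.patient_id,
        "region_label": stack.region_label,
        "roi_index": int(stack.roi_index),
        "pixel_size_um": float(stack.pixel_size_um),
        "z_step_um": float(stack.z_step_um),
        "n_slices": int(stack.n_slices),
    }
    return ProjectedPair(
        f_img=stack.f_stack.max(axis=0),
        b_img=stack.b_stack.max(axis=0),
        provenance=prov,
    )


def estimate_offscene_background(img: np.ndarray) -> float:
    """Background offset as the mean of pixels at or below the 5th percentile.

    A deterministic stand-in for an off-specimen measurement: the
    dimmest 5% of a projected SHG image is dominated by detector offset
    plus dark noise rather than collagen signal.
    """
    img = np.asarray(img, dtype=float)
    cutoff = np.percentile(img, 5)
    return float(img[img <= cutoff].mean())


def subtract_background(
    pair: ProjectedPair,
    method: Literal["constant", "offscene-mean"] = "constant",
    value_f: float = 0.0,
    value_b: float = 0.0,
) -> ProjectedPair:
    """Subtract a per-channel background offset, clipping at zero.

    ``method="constant"`` subtracts the supplied ``value_f``/``value_b``;
    ``method="offscene-mean"`` estimates each offset with
    :func:`estimate_offscene_background` and ignores the supplied
    values. Offsets actually used are recorded on the returned pair.
    """
    if method == "offscene-mean":
        value_f = estimate_offscene_background(pair.f_img)
        value_b = estimate_offscene_background(pair.b_img)
    elif method != "constant":
        raise ValueError(f"unknown background method {method!r}")
    if value_f < 0 or value_b < 0:
        raise ValueError("background offsets must be >= 0")
    prov = dict(pair.provenance)
    prov["background_method"] = method
    return ProjectedPair(
        f_img=np.clip(np.asarray(pair.f_img, dtype=float) - value_f, 0.0, None),
        b_img=np.clip(np.asarray(pair.b_img, dtype=float) - value_b, 0.0, None),
        background_f=float(pair.background_f) + float(value_f),
        background_b=float(pair.background_b) + float(value_b),
        provenance=prov,
    )


def save_provenance(pair: ProjectedPair, path: str | Path) -> None:
    """Persist a projected pair's provenance (metadata + offsets) as JSON."""
    payload = dict(pair.provenance)
    payload["background_f"] = float(pair.background_f)
    payload["background_b"] = float(pair.background_b)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
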
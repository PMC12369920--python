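"""QC figure rendering: mask overlays and F/B ratio heatmaps."""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import tifffile

from .io import ProjectedPair
from .masking import FBMask, FBResult

__all__ = ["render_qc"]

log = logging.getLogger(__name__)


def _add_scalebar(ax, shape: tuple[int, int], pixel_size_um: float | None) -> None:
    if not pixel_size_um:
        return
    bar_um = 100.0
    bar_px = bar_um / pixel_size_um
    nr, nc = shape
    y = nr * 0.95
    x0 = nc * 0.05
    ax.plot([x0, x0 + bar_px], [y, y], color="white", lw=3)
    ax.text(
        x0, y - nr * 0.02, f"{bar_um:.0f} µm", color="white", fontsize=8
    )


def render_qc(
    pair: ProjectedPair,
    mask: FBMask,
    result: FBResult | None,
    out_dir: str | Path,
    prefix: str = "qc",
) -> dict[str, Path]:
    """Write QC figures for one field of view.

    Produces ``<prefix>_overlay.png`` (F image with the combined mask
    outlined), ``<prefix>_ratio.png`` (F/B heatmap, low values dark
    purple, with a scale bar when the pixel size is known) and
    ``<prefix>_ratio.tif`` (the raw float32 ratio image for
    quantitative readback). With ``result=None`` (empty mask) the
    heatmap is rendered all-background and a warning is emitted.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    px = pair.provenance.get("pixel_size_um")
    paths: dict[str, Path] = {}

    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    axes[0].imshow(pair.f_img, cmap="gray")
    axes[0].contour(mask.combined.astype(float), levels=[0.5], colors="red", linewidths=0.5)
    axes[0].set_title("F + combined mask")
    axes[1].imshow(pair.b_img, cmap="gray")
    axes[1].contour(mask.combined.astype(float), levels=[0.5], colors="red", linewidths=0.5)
    axes[1].set_title("B + combined mask")
    for ax in axes:
        ax.set_axis_off()
        _add_scalebar(ax, pair.shape, px)
    overlay = out_dir / f"{prefix}_overlay.png"
    fig.savefig(overlay, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths["overlay"] = overlay

    if result is None:
        warnings.warn(f"{prefix}: empty mask, rendering all-background heatmap")
        ratio = np.zeros(pair.shape, dtype=np.float32)
    else:
        ratio = np.asarray(result.ratio_image, dtype=np.float32)

    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(ratio, cmap="viridis")
    fig.colorbar(im, ax=ax, label="F/B")
    ax.set_axis_off()
    _add_scalebar(ax, pair.shape, px)
    if result is not None:
        ax.set_title(f"F/B = {result.fb_value:.2f} ({result.n_pixels} px)")
    heat = out_dir / f"{prefix}_ratio.png"
    fig.savefig(heat, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths["heatmap"] = heat

    tif = out_dir / f"{prefix}_ratio.tif"
    tifffile.imwrite(tif, ratio)
    paths["ratio_tiff"] = tif
    return paths
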
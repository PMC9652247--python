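"""Cropping the four dataset variants and resizing to the model input shape.

Each compound screenshot yields four images: the full B-mode panel (US),
the full SWE panel (SWE), and the two panels restricted to the elastogram
rectangle (RE-US, RE-SWE).  Cropping is pure array slicing — bitwise
exact — and all variants are then resized to a square (224, 224, 3) by
default using bilinear interpolation with an anti-alias blur on
downscale.  The square resize intentionally distorts aspect ratio; that
is the studied protocol, not an accident.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .phantom import CompoundScreenshot, PairedSample, crop_box

__all__ = ["CropVariant", "ResizeSpec", "crop_variants", "resize_image",
           "build_variant_dataset", "variant_stack"]


class CropVariant(str, Enum):
    US = "US"          # entire B-mode panel
    SWE = "SWE"        # entire SWE panel
    RE_US = "RE-US"    # B-mode restricted to the elastogram rectangle
    RE_SWE = "RE-SWE"  # SWE restricted to the elastogram rectangle


@dataclass(frozen=True)
class ResizeSpec:
    target_height: int = 224
    target_width: int = 224
    channels: int = 3
    antialias_on_downscale: bool = True

    def __post_init__(self):
        if self.target_height <= 0 or self.target_width <= 0:
            raise ValueError("target size must be positive")
        if self.channels != 3:
            raise ValueError("the classifier expects 3-channel input")


def _check_roi_in_panel(roi, panel) -> None:
    r0, c0, r1, c1 = roi
    ph = panel[2] - panel[0]
    pw = panel[3] - panel[1]
    if not (0 <= r0 < r1 <= ph and 0 <= c0 < c1 <= pw):
        raise ValueError(f"roi_box {roi} falls outside the {ph}x{pw} panel")


def crop_variants(screenshot: CompoundScreenshot) -> dict[CropVariant, np.ndarray]:
    """Slice the four dataset variants out of a compound screenshot.

    No interpolation happens here; outputs are views-turned-copies of the
    raster, so synthetic round trips are bitwise exact.
    """
    us_panel = crop_box(screenshot.raster, screenshot.us_panel_box).copy()
    swe_panel = crop_box(screenshot.raster, screenshot.swe_panel_box).copy()
    if us_panel.shape != swe_panel.shape:
        raise ValueError("US and SWE panels must have identical dimensions")
    roi = screenshot.roi_box_in_us_panel
    _check_roi_in_panel(roi, screenshot.us_panel_box)
    return {
        CropVariant.US: us_panel,
        CropVariant.SWE: swe_panel,
        CropVariant.RE_US: crop_box(us_panel, roi).copy(),
        CropVariant.RE_SWE: crop_box(swe_panel, roi).copy(),
    }


def resize_image(raster: np.ndarray, spec: ResizeSpec = ResizeSpec()) -> np.ndarray:
    """Resize to ``(target_height, target_width, 3)`` in [0, 1].

    Bilinear interpolation; on downscale a Gaussian anti-alias blur is
    applied first (sigma grows with the downscale factor), on upscale no
    blur.  Grayscale inputs are replicated to three channels.
    """
    raster = np.asarray(raster, dtype=np.float64)
    if raster.size == 0:
        raise ValueError("cannot resize an empty image")
    if raster.ndim == 2:
        raster = np.repeat(raster[:, :, None], 3, axis=2)
    if raster.shape[2] != 3:
        raise ValueError("expected a grayscale or 3-channel image")
    downscaling = (raster.shape[0] > spec.target_height
                   or raster.shape[1] > spec.target_width)
    out = _sk_resize(
        raster, (spec.target_height, spec.target_width),
        order=1, mode="reflect",
        anti_aliasing=spec.antialias_on_downscale and downscaling,
        preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _variant_from_pair(pair: PairedSample, variant: CropVariant) -> np.ndarray:
    if variant == CropVariant.US:
        return pair.us_image
    if variant == CropVariant.SWE:
        return pair.swe_image
    _check_roi_in_panel(pair.roi_box,
                        (0, 0, pair.us_image.shape[0], pair.us_image.shape[1]))
    if variant == CropVariant.RE_US:
        return crop_box(pair.us_image, pair.roi_box)
    if variant == CropVariant.RE_SWE:
        return crop_box(pair.swe_image, pair.roi_box)
    raise ValueError(f"unknown variant {variant}")


def variant_stack(samples: list[PairedSample], variant: CropVariant,
                  spec: ResizeSpec = ResizeSpec()) -> tuple[np.ndarray, np.ndarray]:
    """In-memory counterpart of :func:`build_variant_dataset`."""
    if not samples:
        shape = (0, spec.target_height, spec.target_width, spec.channels)
        return np.empty(shape, np.float32), np.empty(0, np.int64)
    stack = np.stack([resize_image(_variant_from_pair(s, variant), spec)
                      for s in samples])
    labels = np.array([s.label for s in samples], dtype=np.int64)
    return stack, labels


def build_variant_dataset(manifest: pd.DataFrame, variant: CropVariant,
                          spec: ResizeSpec = ResizeSpec()
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Load one crop variant for every manifest row, resized and stacked.

    Row order equals manifest order; a missing or unreadable image raises
    with the offending ``sample_id``.
    """
    from .phantom import _load_png

    variant = CropVariant(variant)
    rasters, labels = [], []
    for _, row in manifest.iterrows():
        try:
            col = "swe_path" if variant in (CropVariant.SWE, CropVariant.RE_SWE) else "us_path"
            img = _load_png(Path(row[col]))
            if img.ndim == 3 and variant in (CropVariant.US, CropVariant.RE_US):
                img = img[:, :, 0]
            if variant in (CropVariant.RE_US, CropVariant.RE_SWE):
                roi = (int(row["roi_row_start"]), int(row["roi_col_start"]),
                       int(row["roi_row_stop"]), int(row["roi_col_stop"]))
                _check_roi_in_panel(roi, (0, 0, img.shape[0], img.shape[1]))
                img = crop_box(img, roi)
            rasters.append(resize_image(img, spec))
        except (OSError, ValueError, KeyError) as exc:
            raise ValueError(f"failed to load sample {row['sample_id']!r}: {exc}") from exc
        labels.append(int(row["label"]))
    if not rasters:
        shape = (0, spec.target_height, spec.target_width, spec.channels)
        return np.empty(shape, np.float32), np.empty(0, np.int64)
    return np.stack(rasters), np.asarray(labels, dtype=np.int64)
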
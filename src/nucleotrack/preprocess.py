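"""Image preprocessing: focus selection, flat-field, background subtraction.

The recipes mirror common practice for bacterial live-cell imaging: pick the
best-focused Z slice, divide out illumination inhomogeneity, smooth the
transmitted-light (TL) channel with a small Gaussian, and remove diffuse
fluorescence background with a sliding-paraboloid (rolling-ball family)
opening or a large-radius median filter.  All operations are deterministic
and shape-preserving.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, Field
from scipy import ndimage
from skimage.morphology import disk

from .records import ImageStack


class PreprocessConfig(BaseModel):
    """Radii of the standard preprocessing recipe.

    ``tl_gaussian_radius_px`` defaults to 1.5 px (middle of the usual
    1-2 px range for TL smoothing); fluorescence background uses a 1-um
    paraboloid and the TL alternative a 2-um median filter.
    """

    tl_gaussian_radius_px: float = Field(default=1.5, ge=1.0, le=2.0)
    paraboloid_radius_um: float = Field(default=1.0, gt=0)
    median_radius_um: float = Field(default=2.0, gt=0)


def best_focus_slice(zstack: np.ndarray) -> tuple[np.ndarray, int]:
    """Pick the sharpest slice of a Z x Y x X stack.

    Sharpness is the normalized intensity variance var/mean^2, which is
    monotone in defocus blur and insensitive to overall brightness.  Ties
    break to the lowest z index.
    """
    zstack = np.asarray(zstack, dtype=float)
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise ValueError("expected a non-empty Z x Y x X stack")
    means = zstack.mean(axis=(1, 2))
    variances = zstack.var(axis=(1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(means > 0, variances / means**2, 0.0)
    z = int(np.argmax(scores))  # argmax returns the first (lowest) index on ties
    return zstack[z], z


def flat_field_correct(
    img: np.ndarray, flat: np.ndarray, eps: float = 1e-6
) -> np.ndarray:
    """Divide by the mean-normalized flat-field reference."""
    img = np.asarray(img, dtype=float)
    flat = np.asarray(flat, dtype=float)
    if img.shape != flat.shape:
        raise ValueError("flat-field image shape must match")
    if np.any(flat <= eps):
        raise ValueError("flat-field image must be strictly positive")
    return img / (flat / flat.mean())


def _paraboloid_profile(radius_px: float) -> np.ndarray:
    """1-D slice of the paraboloid structuring surface (apex curvature
    radius ``radius_px``), sampled on a support of ~4 radii.

    The full surface -(u^2 + v^2) / (2R) is an additive sum of per-axis
    parabolas, so 2-D erosion/dilation by it factors exactly into two 1-D
    passes.
    """
    r = int(np.ceil(2.0 * radius_px))
    u = np.arange(-r, r + 1, dtype=float)
    return -(u**2) / (2.0 * radius_px)


def _paraboloid_open(img: np.ndarray, radius_px: float) -> np.ndarray:
    prof = _paraboloid_profile(radius_px)
    ero = ndimage.grey_erosion(img, structure=prof[None, :])
    ero = ndimage.grey_erosion(ero, structure=prof[:, None])
    dil = ndimage.grey_dilation(ero, structure=prof[:, None])
    return ndimage.grey_dilation(dil, structure=prof[None, :])


def subtract_paraboloid_background(
    img: np.ndarray, radius_um: float, pixel_size_um: float
) -> np.ndarray:
    """Sliding-paraboloid background subtraction for fluorescence channels.

    The background is the grayscale opening of the image by a paraboloid
    structuring surface (the surface a paraboloid of the given apex radius
    traces when slid under the image).  Features narrower than the radius
    ride on top of the envelope and survive; broad background is removed.
    Output is clamped at zero (fluorescence is non-negative downstream).
    """
    radius_px = radius_um / pixel_size_um
    if radius_px < 1.0:
        raise ValueError("paraboloid radius must be at least one pixel")
    img = np.asarray(img, dtype=float)
    background = _paraboloid_open(img, radius_px)
    return np.clip(img - background, 0.0, None)


def subtract_median_background(
    img: np.ndarray, radius_um: float, pixel_size_um: float
) -> np.ndarray:
    """Subtract a disk-median-filtered version of the image (TL channel).

    The result is signed: TL contrast legitimately swings both ways around
    the local background, so no clamping is applied.
    """
    radius_px = radius_um / pixel_size_um
    if radius_px < 1.0:
        raise ValueError("median radius must be at least one pixel")
    img = np.asarray(img, dtype=float)
    footprint = disk(int(round(radius_px)))
    return img - ndimage.median_filter(img, footprint=footprint)


def gaussian_smooth(img: np.ndarray, radius_px: float) -> np.ndarray:
    """Gaussian blur with sigma = ``radius_px`` (TL channel denoising)."""
    if radius_px <= 0:
        raise ValueError("radius must be positive")
    return ndimage.gaussian_filter(np.asarray(img, dtype=float), radius_px)


def preprocess_stack(
    stack: ImageStack,
    config: Optional[PreprocessConfig] = None,
    flat: Optional[np.ndarray] = None,
    tl_channel: str = "tl",
) -> ImageStack:
    """Apply the fixed recipe to a whole stack.

    Order: flat-field (all channels, if a reference is given), then Gaussian
    smoothing of the TL channel and paraboloid background subtraction of
    every fluorescence channel.
    """
    cfg = config or PreprocessConfig()
    out = np.empty_like(stack.pixels, dtype=np.float32)
    for t in range(stack.n_frames):
        for c, name in enumerate(stack.channel_names):
            img = stack.pixels[t, c].astype(float)
            if flat is not None:
                img = flat_field_correct(img, flat)
            if name == tl_channel:
                img = gaussian_smooth(img, cfg.tl_gaussian_radius_px)
            else:
                img = subtract_paraboloid_background(
                    img, cfg.paraboloid_radius_um, stack.pixel_size_um
                )
            out[t, c] = img
    return ImageStack(
        pixels=out,
        pixel_size_um=stack.pixel_size_um,
        frame_interval_s=stack.frame_interval_s,
        channel_names=list(stack.channel_names),
    )
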
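"""Vessel segmentation of arterial-phase CTA slices and hemispheric split.

Arterial-phase CTA shows contrast-opacified vessels as bright, thin
structures over a darker parenchymal background.  A local-mean adaptive
threshold (pixel is vessel iff it exceeds the mean of its neighbourhood
by a margin) picks out such structures while tolerating the slow
intensity gradients typical of CT.  Small connected components are
removed as noise.

The hemispheric split supports the symptomatic-to-contralateral ratio:
a vertical midline (auto-detected from the head centroid, or supplied by
the operator for tilted heads) partitions the vessel mask, and each side
is optionally cropped to a band approximating the middle-cerebral-artery
territory.  Left/right follow the radiological convention: image right
is the patient's left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fractal import BinaryRaster

__all__ = [
    "CTASlice",
    "HemispherePair",
    "adaptive_threshold",
    "split_hemispheres",
]

GANGLIONIC = "ganglionic"
SUPRAGANGLIONIC = "supraganglionic"
LEVELS = (GANGLIONIC, SUPRAGANGLIONIC)
SIDES = ("left", "right")

DEFAULT_WINDOW = 31
DEFAULT_MIN_COMPONENT = 25


@dataclass(frozen=True)
class CTASlice:
    """One grayscale axial slice with its scoring annotations."""

    intensities: np.ndarray
    level: str
    symptomatic_side: str
    pixel_spacing: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        img = np.asarray(self.intensities, dtype=float)
        if img.ndim != 2:
            raise ValueError(f"slice must be 2-D, got shape {img.shape}")
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.symptomatic_side not in SIDES:
            raise ValueError(
                f"symptomatic_side must be one of {SIDES}, got {self.symptomatic_side!r}"
            )
        object.__setattr__(self, "intensities", img)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass(frozen=True)
class HemispherePair:
    """Disjoint symptomatic / contralateral vessel masks from one slice."""

    symptomatic_mask: BinaryRaster
    contralateral_mask: BinaryRaster
    midline_column: int
    roi_description: str = "full hemisphere half-plane"

    @property
    def degenerate(self) -> bool:
        return self.symptomatic_mask.is_empty() or self.contralateral_mask.is_empty()


def adaptive_threshold(
    slice_or_image,
    window: int = DEFAULT_WINDOW,
    offset: float | None = None,
    hu_window: tuple[float, float] | None = None,
    min_component: int = DEFAULT_MIN_COMPONENT,
    smooth_sigma: float = 0.5,
) -> BinaryRaster:
    """Segment vessels: foreground iff intensity > local mean + offset.

    A light Gaussian denoising (``smooth_sigma``) is applied before the
    local-mean comparison to suppress pixel noise; the margin ``offset``
    is computed from the *raw* intensity scale, so denoising tightens
    the effective noise floor without lowering the threshold.

    Parameters
    ----------
    slice_or_image
        A :class:`CTASlice` or bare 2-D grayscale array.
    window
        Odd neighbourhood size (pixels) for the local mean.
    offset
        Additive margin above the local mean.  When ``None`` it is set
        per-slice to half the robust standard deviation of raw
        intensities (1.4826 * MAD), so the margin scales with slice
        contrast.
    hu_window
        Optional ``(low, high)`` clamp applied before thresholding, with
        rescale to [0, 1]; use to restrict to a vascular HU band.
    min_component
        Connected components (8-connectivity) smaller than this are
        removed as noise.
    smooth_sigma
        Gaussian denoising sigma in pixels; 0 disables smoothing.
    """
    img = slice_or_image.intensities if isinstance(slice_or_image, CTASlice) else np.asarray(
        slice_or_image, dtype=float
    )
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > min(img.shape):
        raise ValueError(
            f"window {window} larger than image (min dimension {min(img.shape)})"
        )
    if np.ptp(img) == 0:
        raise ValueError("constant image: cannot segment vessels")

    if hu_window is not None:
        low, high = hu_window
        if not low < high:
            raise ValueError("hu_window must satisfy low < high")
        img = (np.clip(img, low, high) - low) / (high - low)

    if offset is None:
        mad = np.median(np.abs(img - np.median(img)))
        robust_sd = 1.4826 * mad
        if robust_sd == 0:  # e.g. a sparse bright structure on flat background
            robust_sd = img.std()
        offset = 0.5 * robust_sd

    smoothed = ndimage.gaussian_filter(img, smooth_sigma) if smooth_sigma > 0 else img
    local_mean = ndimage.uniform_filter(smoothed, size=window, mode="reflect")
    mask = smoothed > local_mean + offset
    if min_component > 1:
        labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        if n_comp:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            mask = sizes[labels] >= min_component
    return BinaryRaster(mask.astype(np.uint8))


def _auto_midline(image: np.ndarray) -> int:
    """Column through the head-mask centroid (head = above-median pixels)."""
    head = image > np.median(image)
    if not head.any():
        head = np.ones_like(image, dtype=bool)
    cols = np.nonzero(head)[1]
    return int(round(cols.mean()))


def split_hemispheres(
    mask: BinaryRaster | np.ndarray,
    cta_slice: CTASlice,
    midline: int | None = None,
    mca_band: tuple[float, float] | None = None,
) -> HemispherePair:
    """Partition a vessel mask at the midline into symptomatic / contralateral.

    The midline column itself is assigned to neither side, guaranteeing
    disjointness.  ``mca_band`` optionally crops both sides to a
    fractional row band ``(top, bottom)`` approximating the MCA
    territory; by default the full half-plane is used.  Radiological
    convention: image columns left of midline are the patient's RIGHT
    hemisphere.
    """
    if not isinstance(mask, BinaryRaster):
        mask = BinaryRaster(mask)
    if mask.pixels.shape != cta_slice.shape:
        raise ValueError("mask and slice shapes differ")
    h, w = mask.pixels.shape
    if midline is None:
        midline = _auto_midline(cta_slice.intensities)
    if not 0 < midline < w - 1:
        raise ValueError(f"midline column {midline} leaves an empty hemisphere")

    px = mask.pixels.copy()
    roi = "full hemisphere half-plane"
    if mca_band is not None:
        top, bottom = mca_band
        if not 0.0 <= top < bottom <= 1.0:
            raise ValueError("mca_band must satisfy 0 <= top < bottom <= 1")
        r0, r1 = int(round(top * h)), int(round(bottom * h))
        banded = np.zeros_like(px)
        banded[r0:r1, :] = px[r0:r1, :]
        px = banded
        roi = f"MCA band rows [{r0}, {r1}) of {h}"

    left_img = np.zeros_like(px)   # image-left columns = patient RIGHT
    right_img = np.zeros_like(px)  # image-right columns = patient LEFT
    left_img[:, :midline] = px[:, :midline]
    right_img[:, midline + 1 :] = px[:, midline + 1 :]
    patient = {"right": left_img, "left": right_img}

    sym = patient[cta_slice.symptomatic_side]
    contra = patient["left" if cta_slice.symptomatic_side == "right" else "right"]
    return HemispherePair(
        symptomatic_mask=BinaryRaster(sym, pixel_spacing=cta_slice.pixel_spacing),
        contralateral_mask=BinaryRaster(contra, pixel_spacing=cta_slice.pixel_spacing),
        midline_column=int(midline),
        roi_description=roi,
    )
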
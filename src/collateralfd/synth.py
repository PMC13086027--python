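"""Synthetic fixtures: reference fractals, vascular-tree slice phantoms,
and simulated stroke cohorts.

Three generator families make every pipeline stage testable without
clinical data:

* deterministic fractals with closed-form box-counting dimension
  (filled square D=2, line D=1, Sierpinski triangle D=log3/log2,
  Sierpinski carpet D=log8/log3, dyadic fractal percolation with
  expected D=log2(4p));
* grayscale CTA-like slice phantoms containing one recursive
  bifurcating vessel tree per hemisphere, with exact ground-truth
  vessel masks, controllable branching depth (the "collateral density"
  knob), survival probability, geometry jitter and additive noise;
* patient cohorts with the reported statistical structure: outcome-first
  sampling draws a favorable/unfavorable label and then group-conditional
  mFD (favorable 0.931 +/- 0.086, unfavorable 0.863 +/- 0.118), visual
  collateral scores via a noisy monotone latent link, and
  outcome-conditional covariates.  A covariate-first logistic mode is
  available for parameter-recovery checks.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw, morphology

from .fractal import BinaryRaster
from .preprocess import CTASlice, GANGLIONIC

__all__ = [
    "FractalFixtureSpec",
    "VascularTreeSpec",
    "CohortSimSpec",
    "make_fractal",
    "make_vascular_slice",
    "simulate_cohort",
]

FRACTAL_KINDS = (
    "filled_square",
    "line",
    "single_pixel",
    "sierpinski_triangle",
    "sierpinski_carpet",
    "random_cantor",
)


@dataclass(frozen=True)
class FractalFixtureSpec:
    kind: str
    size: int = 128
    depth: int | None = None
    retain_probability: float = 0.7  # random_cantor only
    seed: int = 0

    @property
    def theoretical_dimension(self) -> float:
        """Closed-form (similarity / expected) box-counting dimension."""
        return {
            "filled_square": 2.0,
            "line": 1.0,
            "single_pixel": 0.0,
            "sierpinski_triangle": math.log(3) / math.log(2),
            "sierpinski_carpet": math.log(8) / math.log(3),
            "random_cantor": math.log2(4 * self.retain_probability),
        }[self.kind]


def _is_power(n: int, base: int) -> bool:
    if n < 1:
        return False
    while n % base == 0:
        n //= base
    return n == 1


def make_fractal(spec: FractalFixtureSpec) -> BinaryRaster:
    """Render a reference fractal as a binary raster.

    Dyadic kinds (triangle, random_cantor) need a power-of-2 size; the
    carpet is triadic and needs a power of 3.  The returned raster's
    theoretical dimension is available on the spec.
    """
    if spec.kind not in FRACTAL_KINDS:
        raise ValueError(f"unknown fractal kind {spec.kind!r}")
    n = spec.size
    if n < 2:
        raise ValueError("size must be >= 2")

    if spec.kind == "filled_square":
        return BinaryRaster(np.ones((n, n), dtype=np.uint8))
    if spec.kind == "line":
        px = np.zeros((n, n), dtype=np.uint8)
        px[n // 2, :] = 1
        return BinaryRaster(px)
    if spec.kind == "single_pixel":
        px = np.zeros((n, n), dtype=np.uint8)
        px[n // 2, n // 2] = 1
        return BinaryRaster(px)

    if spec.kind == "sierpinski_triangle":
        depth = spec.depth if spec.depth is not None else int(round(math.log2(n)))
        size = 2**depth
        if not _is_power(size, 2):
            raise ValueError("sierpinski_triangle needs a power-of-2 size")
        i, j = np.indices((size, size))
        return BinaryRaster(((i & j) == 0).astype(np.uint8))

    if spec.kind == "sierpinski_carpet":
        depth = spec.depth if spec.depth is not None else 5
        size = 3**depth
        keep = np.ones((size, size), dtype=bool)
        i, j = np.indices((size, size))
        for d in range(depth):
            scale = 3**d
            keep &= ~(((i // scale) % 3 == 1) & (((j // scale) % 3) == 1))
        return BinaryRaster(keep.astype(np.uint8))

    # random_cantor: dyadic fractal percolation
    depth = spec.depth if spec.depth is not None else int(round(math.log2(n)))
    size = 2**depth
    p = spec.retain_probability
    if not 0.0 < p <= 1.0:
        raise ValueError("retain_probability must be in (0, 1]")
    rng = np.random.default_rng(spec.seed)
    keep = np.ones((1, 1), dtype=bool)
    for _ in range(depth):
        keep = np.kron(keep, np.ones((2, 2), dtype=bool))
        keep &= rng.random(keep.shape) < p
    if not keep.any():  # extinction: keep the root pixel so FD is defined
        keep[0, 0] = True
    return BinaryRaster(keep.astype(np.uint8))


# --------------------------------------------------------------------------
# Vascular slice phantoms


@dataclass(frozen=True)
class VascularTreeSpec:
    """Parameters of a two-hemisphere bifurcating-tree slice phantom."""

    image_size: int = 257  # odd, so the midline is a true mirror axis
    depth_symptomatic: int = 6
    depth_contralateral: int = 6
    branch_probability: float = 0.92
    length_decay: float = 0.72
    branch_angle_deg: float = 27.0
    angle_jitter_deg: float = 7.0
    vessel_width: int = 3
    noise_sigma: float = 0.0
    background: float = 100.0
    contrast: float = 100.0
    symptomatic_side: str = "left"
    level: str = GANGLIONIC
    mirror: bool = True  # contralateral tree = mirror image of the symptomatic tree
    root_row_frac: float = 0.88
    root_col_frac: float = 0.5  # within the hemisphere half-width
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.depth_symptomatic, self.depth_contralateral) < 1:
            raise ValueError("branching depth must be >= 1")
        if not 0.0 <= self.branch_probability <= 1.0:
            raise ValueError("branch_probability must be in [0, 1]")
        if not (0.0 < self.root_row_frac < 1.0 and 0.0 < self.root_col_frac < 1.0):
            raise ValueError("root position must lie inside the image")


def _grow_tree(rng: np.random.Generator, spec: VascularTreeSpec, max_depth: int):
    """Recursive bifurcation; returns segments [(r0, c0, r1, c1, level)].

    The root segment is level 1.  Children survive independently with
    ``branch_probability`` (the root's two children always survive so a
    tree of depth >= 2 is never a bare trunk).
    """
    size = spec.image_size
    segments = []
    length0 = 0.30 * size
    root_r = spec.root_row_frac * size
    # hemisphere-local column 0; the caller shifts by the hemisphere offset
    stack = [(root_r, 0.0, math.radians(-90.0), length0, 1)]
    while stack:
        r, c, theta, length, level = stack.pop()
        r1 = r + length * math.sin(theta)
        c1 = c + length * math.cos(theta)
        segments.append((r, c, r1, c1, level))
        if level >= max_depth:
            continue
        for sign in (-1.0, 1.0):
            jitter = math.radians(rng.normal(0.0, spec.angle_jitter_deg))
            angle = theta + sign * math.radians(spec.branch_angle_deg) + jitter
            survives = level == 1 or rng.random() < spec.branch_probability
            if survives:
                stack.append((r1, c1, angle, length * spec.length_decay, level + 1))
    return segments


def _render_segments(segments, shape, col_offset: float, max_level: int, width: int):
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    for r0, c0, r1, c1, level in segments:
        if level > max_level:
            continue
        rr, cc = draw.line(
            int(round(r0)), int(round(c0 + col_offset)),
            int(round(r1)), int(round(c1 + col_offset)),
        )
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        mask[rr[keep], cc[keep]] = True
    if width > 1:
        mask = ndimage.binary_dilation(mask, structure=morphology.disk((width - 1) // 2))
    return mask


def make_vascular_slice(spec: VascularTreeSpec):
    """Render a two-tree grayscale slice phantom with ground-truth masks.

    Returns ``(cta_slice, truth)`` where ``truth`` is a dict with keys
    ``"symptomatic"`` and ``"contralateral"`` holding the exact binary
    vessel masks per hemisphere, plus ``"midline"``.  With
    ``mirror=True`` the contralateral tree is the mirror image of the
    symptomatic tree's geometry, rendered at its own depth cutoff — so
    reducing ``depth_symptomatic`` below ``depth_contralateral`` prunes
    terminal branches of an otherwise identical tree.

    Intensity model: background + contrast * Gaussian-profiled vessel
    indicator, plus optional white noise (sigma in intensity units).
    """
    size = spec.image_size
    mid = size // 2
    shape = (size, size)
    rng = np.random.default_rng(spec.seed)
    max_depth = max(spec.depth_symptomatic, spec.depth_contralateral)

    half = mid  # columns per hemisphere excluding the midline column
    left_offset = spec.root_col_frac * half
    segments = _grow_tree(rng, spec, max_depth)

    if spec.mirror:
        right_segments = segments
    else:
        rng2 = np.random.default_rng(spec.seed + 1)
        right_segments = _grow_tree(rng2, spec, max_depth)

    def right_at(d):
        return _render_segments(right_segments, shape, left_offset, d, spec.vessel_width)[:, ::-1]

    # image-left hemisphere = patient RIGHT under radiological convention
    sym_on_image_left = spec.symptomatic_side == "right"
    d_left = spec.depth_symptomatic if sym_on_image_left else spec.depth_contralateral
    d_right = spec.depth_contralateral if sym_on_image_left else spec.depth_symptomatic
    left = _render_segments(segments, shape, left_offset, d_left, spec.vessel_width)
    right = right_at(d_right)
    left[:, mid:] = False
    right[:, : mid + 1] = False

    vessels = left | right
    profile = ndimage.gaussian_filter(vessels.astype(float), sigma=0.5)
    profile /= profile.max() if profile.max() > 0 else 1.0
    img = spec.background + spec.contrast * profile
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=shape)

    if vessels.sum() == 0:
        raise ValueError("degenerate geometry: no vessel pixels rendered")
    cta = CTASlice(
        intensities=img,
        level=spec.level,
        symptomatic_side=spec.symptomatic_side,
        source_id=f"phantom-seed{spec.seed}",
    )
    sym_mask = left if sym_on_image_left else right
    contra_mask = right if sym_on_image_left else left
    truth = {
        "symptomatic": BinaryRaster(sym_mask.astype(np.uint8)),
        "contralateral": BinaryRaster(contra_mask.astype(np.uint8)),
        "midline": mid,
    }
    return cta, truth


# --------------------------------------------------------------------------
# Cohort simulation

#: latent-link noise SD calibrated so Spearman(mFD, vCS-mCTA) ~= 0.58
VCS_LINK_NOISE_SD = 1.25
#: latent cutpoints mapping the standardized latent score to vCS 0..5
VCS_CUTPOINTS = (-2.35, -1.55, -0.45, 0.85, 1.80)


@dataclass(frozen=True)
class CohortSimSpec:
    """Simulated stroke cohort with the reported group structure.

    Defaults encode the study conditions: n = 54 with 24/54 favorable,
    group-conditional mFD (favorable 0.931 +/- 0.086, unfavorable
    0.863 +/- 0.118), outcome-conditional age / sex / pre-NIHSS / LDL,
    and a noisy monotone latent link from mFD to the ordinal 0-5 visual
    collateral scores.  When ``outcome_model`` is given, generation is
    covariate-first: mFD is drawn from the pooled marginal, and the
    outcome from a logistic model on standardized mFD — used for
    coefficient-recovery checks.
    """

    n: int = 54
    favorable_fraction: float = 24 / 54
    mfd_favorable: tuple[float, float] = (0.931, 0.086)
    mfd_unfavorable: tuple[float, float] = (0.863, 0.118)
    age_favorable: tuple[float, float] = (62.61, 13.59)
    age_unfavorable: tuple[float, float] = (67.00, 14.51)
    male_fraction: tuple[float, float] = (0.783, 0.548)  # (favorable, unfavorable)
    nihss_favorable: tuple[float, float] = (15.00, 6.23)
    nihss_unfavorable: tuple[float, float] = (20.74, 6.47)
    ldl_favorable: tuple[float, float] = (99.57, 31.75)
    ldl_unfavorable: tuple[float, float] = (120.84, 39.56)
    scta_shift_probs: tuple[float, float, float] = (0.15, 0.50, 0.35)  # P(-1), P(0), P(+1)
    outcome_model: dict | None = None  # {"intercept": b0, "mfd_std": b1}
    mfd_pooled: tuple[float, float] = (0.893, 0.110)
    seed: int = 0

    def __post_init__(self) -> None:
        for mean, sd in (self.mfd_favorable, self.mfd_unfavorable):
            if sd <= 0:
                raise ValueError("mFD group SDs must be positive")
        if not 0.0 < self.favorable_fraction < 1.0:
            raise ValueError("favorable_fraction must be in (0, 1)")


def _truncated_normal(rng, mean, sd, size, low=1e-3):
    x = rng.normal(mean, sd, size)
    while np.any(x <= low):
        bad = x <= low
        x[bad] = rng.normal(mean, sd, bad.sum())
    return x


def _vcs_from_mfd(rng, mfd: np.ndarray, pooled: tuple[float, float]) -> np.ndarray:
    z = (mfd - pooled[0]) / pooled[1]
    latent = (z + rng.normal(0.0, VCS_LINK_NOISE_SD, len(mfd))) / math.sqrt(
        1.0 + VCS_LINK_NOISE_SD**2
    )
    return np.digitize(latent, VCS_CUTPOINTS).astype(int)


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Draw one cohort table (schema-compatible with the clinical CSV)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    if spec.outcome_model is None:
        outcome = (rng.random(n) < spec.favorable_fraction).astype(int)
        mfd = np.where(
            outcome == 1,
            _truncated_normal(rng, *spec.mfd_favorable, n),
            _truncated_normal(rng, *spec.mfd_unfavorable, n),
        )
    else:
        mfd = _truncated_normal(rng, *spec.mfd_pooled, n)
        z = (mfd - spec.mfd_pooled[0]) / spec.mfd_pooled[1]
        logit = spec.outcome_model.get("intercept", 0.0) + spec.outcome_model.get(
            "mfd_std", 0.0
        ) * z
        outcome = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    fav = outcome == 1
    age = np.where(
        fav,
        rng.normal(*spec.age_favorable, n),
        rng.normal(*spec.age_unfavorable, n),
    ).round(0)
    male_p = np.where(fav, spec.male_fraction[0], spec.male_fraction[1])
    sex = np.where(rng.random(n) < male_p, "male", "female")
    nihss = np.clip(
        np.where(
            fav,
            rng.normal(*spec.nihss_favorable, n),
            rng.normal(*spec.nihss_unfavorable, n),
        ).round(0),
        0, 42,
    ).astype(int)
    ldl = np.where(
        fav,
        rng.normal(*spec.ldl_favorable, n),
        rng.normal(*spec.ldl_unfavorable, n),
    ).clip(min=20.0).round(1)

    vcs_mcta = _vcs_from_mfd(rng, mfd, spec.mfd_pooled)
    shift = rng.choice([-1, 0, 1], size=n, p=list(spec.scta_shift_probs))
    vcs_scta = np.clip(vcs_mcta + shift, 0, 5)

    mrs = np.where(fav, rng.integers(0, 3, n), rng.integers(3, 7, n))
    return pd.DataFrame(
        {
            "case_id": [f"sim{spec.seed:04d}-{i:04d}" for i in range(n)],
            "mfd": np.round(mfd, 4),
            "vcs_scta": vcs_scta,
            "vcs_mcta": vcs_mcta,
            "age": age,
            "sex": sex,
            "pre_nihss": nihss,
            "mrs_90": mrs,
            "ldl": ldl,
            "outcome": outcome,
        }
    )
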
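"""Patient-level mFD biomarker: hemispheric FD ratios, mean, quartiles, class.

The mean fractal dimension ratio (mFD) is the average over the two
scoring levels (ganglionic, supraganglionic) of the ratio

    FD(symptomatic hemisphere) / FD(contralateral hemisphere).

A symmetric vasculature gives mFD = 1; collateral failure on the
symptomatic side depresses it.  An mFD strictly above the operating
threshold 0.9307 predicts a favorable 90-day outcome (mRS <= 2).
Ratios above 1 are permitted and reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .fractal import FDEstimate, fd_with_default_protocol
from .preprocess import LEVELS, adaptive_threshold, split_hemispheres

__all__ = [
    "LevelRatio",
    "MFDResult",
    "UnratioableCaseError",
    "DEFAULT_MFD_THRESHOLD",
    "compute_level_ratio",
    "compute_mfd",
    "classify_mfd",
    "quartile_stratify",
    "score_case",
]

#: Youden-optimal cutoff on mFD for favorable 90-day outcome (strict >).
DEFAULT_MFD_THRESHOLD = 0.9307

FAVORABLE = "favorable"
UNFAVORABLE = "unfavorable"


class UnratioableCaseError(ValueError):
    """Hemispheric FD ratio undefined (degenerate or non-positive contralateral FD)."""


@dataclass(frozen=True)
class LevelRatio:
    """Symptomatic-to-contralateral FD ratio at one anatomical level."""

    level: str
    fd_symptomatic: float
    fd_contralateral: float
    ratio: float
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class MFDResult:
    """Per-case mFD with its two level ratios and threshold class."""

    case_id: str
    ratios: tuple[LevelRatio, LevelRatio]
    mfd: float
    threshold_used: float
    predicted_class: str
    quartile: str | None = None

    def to_dict(self) -> dict:
        d = {
            "case_id": self.case_id,
            "mfd": self.mfd,
            "threshold_used": self.threshold_used,
            "predicted_class": self.predicted_class,
            "quartile": self.quartile,
        }
        for r in self.ratios:
            d[f"ratio_{r.level}"] = r.ratio
            d[f"fd_symptomatic_{r.level}"] = r.fd_symptomatic
            d[f"fd_contralateral_{r.level}"] = r.fd_contralateral
        return d


def compute_level_ratio(
    fd_sym: FDEstimate | float,
    fd_contra: FDEstimate | float,
    level: str,
) -> LevelRatio:
    """FD(symptomatic) / FD(contralateral) at one level."""
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    prov: dict = {}

    def _val(est, side):
        if isinstance(est, FDEstimate):
            if est.degenerate:
                raise UnratioableCaseError(f"{side} hemisphere FD is degenerate")
            prov[side] = est.to_dict()
            return est.dimension
        return float(est)

    d_sym = _val(fd_sym, "symptomatic")
    d_contra = _val(fd_contra, "contralateral")
    if d_contra <= 0:
        raise UnratioableCaseError(
            f"contralateral FD {d_contra} is not positive; ratio undefined"
        )
    return LevelRatio(
        level=level,
        fd_symptomatic=d_sym,
        fd_contralateral=d_contra,
        ratio=d_sym / d_contra,
        provenance=prov,
    )


def compute_mfd(
    ratio_g: LevelRatio,
    ratio_s: LevelRatio,
    case_id: str = "",
    threshold: float = DEFAULT_MFD_THRESHOLD,
) -> MFDResult:
    """Average the ganglionic and supraganglionic ratios into the mFD."""
    if ratio_g.level == ratio_s.level:
        raise ValueError(f"duplicate level {ratio_g.level!r}; need one ratio per level")
    mfd = (ratio_g.ratio + ratio_s.ratio) / 2.0
    return MFDResult(
        case_id=case_id,
        ratios=(ratio_g, ratio_s),
        mfd=mfd,
        threshold_used=threshold,
        predicted_class=classify_mfd(mfd, threshold),
    )


def classify_mfd(mfd: float, threshold: float = DEFAULT_MFD_THRESHOLD) -> str:
    """Favorable iff mfd > threshold (strict); the boundary is unfavorable."""
    if not np.isfinite(mfd):
        raise ValueError(f"mfd must be finite, got {mfd}")
    return FAVORABLE if mfd > threshold else UNFAVORABLE


def quartile_stratify(mfd_values) -> list[str]:
    """Cohort-relative quartile labels Q1 (lowest) .. Q4 (highest).

    Cuts at the empirical 25th/50th/75th percentiles (linear
    interpolation); values equal to a cut point fall in the lower
    stratum.
    """
    values = np.asarray(list(mfd_values), dtype=float)
    if values.size < 4:
        raise ValueError(f"quartile stratification needs >= 4 values, got {values.size}")
    q1, q2, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    if q1 == q3:
        warnings.warn("degenerate mFD distribution: all quartile cuts equal", stacklevel=2)
    labels = []
    for v in values:
        if v <= q1:
            labels.append("Q1")
        elif v <= q2:
            labels.append("Q2")
        elif v <= q3:
            labels.append("Q3")
        else:
            labels.append("Q4")
    return labels


def score_case(
    slices: dict,
    case_id: str = "",
    threshold: float = DEFAULT_MFD_THRESHOLD,
    midline: int | None = None,
    window: int = 31,
    offset: float | None = None,
    hu_window: tuple[float, float] | None = None,
    min_component: int = 25,
    smooth_sigma: float = 0.5,
    n_offsets: int | str = "all",
    aggregation: str = "minimum",
    seed: int = 20150401,
) -> MFDResult:
    """End-to-end mFD for one case from its two annotated slices.

    ``slices`` maps each anatomical level (ganglionic, supraganglionic)
    to a :class:`~collateralfd.preprocess.CTASlice`.  Each slice is
    segmented by adaptive thresholding, split at the midline, box-counted
    per hemisphere under the default protocol, and the two level ratios
    are averaged into the mFD.
    """
    if set(slices) != set(LEVELS):
        raise ValueError(f"need exactly the levels {LEVELS}, got {sorted(slices)}")
    ratios = {}
    for level in LEVELS:
        sl = slices[level]
        mask = adaptive_threshold(
            sl, window=window, offset=offset, hu_window=hu_window,
            min_component=min_component, smooth_sigma=smooth_sigma,
        )
        pair = split_hemispheres(mask, sl, midline=midline)
        if pair.degenerate:
            raise UnratioableCaseError(
                f"{case_id or 'case'}: empty hemisphere mask at level {level}"
            )
        fd_s = fd_with_default_protocol(
            pair.symptomatic_mask, n_offsets=n_offsets, aggregation=aggregation, seed=seed
        )
        fd_c = fd_with_default_protocol(
            pair.contralateral_mask, n_offsets=n_offsets, aggregation=aggregation, seed=seed
        )
        ratios[level] = compute_level_ratio(fd_s, fd_c, level)
    return compute_mfd(
        ratios[LEVELS[0]], ratios[LEVELS[1]], case_id=case_id, threshold=threshold
    )
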
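"""File I/O: slice loading (DICOM / NIfTI / PNG / TIFF), cohort CSV
parsing with tolerant headers, run configuration, and result writers."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import CTASlice, LEVELS, SIDES

__all__ = [
    "RunConfig",
    "CaseManifest",
    "CohortValidationError",
    "load_slice",
    "load_cohort_csv",
    "write_json",
]

#: accepted header spellings per canonical cohort column (lower-cased)
COLUMN_SYNONYMS = {
    "case_id": ["case_id", "case", "id", "patient_id", "subject"],
    "mfd": ["mfd", "mfd_ratio", "mean_fd_ratio", "mfd ratio"],
    "vcs_scta": ["vcs_scta", "vcs-scta", "vcs_s", "scta", "vcs scta"],
    "vcs_mcta": ["vcs_mcta", "vcs-mcta", "vcs_m", "mcta", "vcs mcta"],
    "age": ["age", "age_years", "age, years"],
    "sex": ["sex", "gender", "male"],
    "pre_nihss": ["pre_nihss", "pre-nihss", "nihss", "pre_nihss_score", "prenihss"],
    "mrs_90": ["mrs_90", "mrs90", "mrs-90", "90d_mrs", "mrs", "mrs_90d"],
    "ldl": ["ldl", "ldl_mgdl", "ldl (mg/dl)"],
    "dyslipidemia": ["dyslipidemia"],
    "hypertension": ["hypertension", "htn"],
}
REQUIRED = ("mfd", "vcs_scta", "vcs_mcta", "age", "sex", "pre_nihss", "mrs_90")

RANGE_RULES = {
    "vcs_scta": (0, 5),
    "vcs_mcta": (0, 5),
    "pre_nihss": (0, 42),
    "mrs_90": (0, 6),
}


class CohortValidationError(ValueError):
    """Cohort CSV failed validation; ``problems`` itemizes row/column issues."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("cohort validation failed:\n  " + "\n  ".join(problems))


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run; serialized next to outputs."""

    window: int = 31
    offset: float | None = None
    hu_window: tuple[float, float] | None = None
    min_component: int = 25
    smooth_sigma: float = 0.5
    n_offsets: int | str = "all"  # grid origins per scale; "all" = exhaustive
    aggregation: str = "minimum"
    fit_range: tuple[int, int] | None = None
    threshold: float = 0.9307
    seed: int = 20150401
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        if not isinstance(data.get("extras"), dict):
            data.pop("extras", None)
        known = set(cls.__dataclass_fields__)
        kwargs = {k: v for k, v in data.items() if k in known}
        for key in ("hu_window", "fit_range"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass(frozen=True)
class CaseManifest:
    """Per-case input: exactly one slice file per anatomical level."""

    case_id: str
    slices: dict  # level -> path
    symptomatic_side: str
    midline: int | None = None

    def __post_init__(self) -> None:
        if set(self.slices) != set(LEVELS):
            raise ValueError(
                f"manifest must name exactly the levels {LEVELS}, got {sorted(self.slices)}"
            )
        if self.symptomatic_side not in SIDES:
            raise ValueError(f"symptomatic_side must be one of {SIDES}")

    @classmethod
    def from_file(cls, path) -> "CaseManifest":
        data = json.loads(Path(path).read_text())
        return cls(
            case_id=data["case_id"],
            slices=data["slices"],
            symptomatic_side=data["symptomatic_side"],
            midline=data.get("midline"),
        )


def _load_png_tiff(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(
            f"{path.name}: RGB image; convert to grayscale before loading"
        )
    return arr.astype(float)


def _load_dicom(path: Path) -> tuple[np.ndarray, float | None]:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    spacing = None
    if getattr(ds, "PixelSpacing", None):
        spacing = float(ds.PixelSpacing[0])
    return arr, spacing


def _load_nifti(path: Path, slice_index: int | None) -> tuple[np.ndarray, float | None]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 2:
        arr = data
    else:
        if slice_index is None:
            raise ValueError("NIfTI volume: slice_index is required")
        n_slices = data.shape[2]
        if not 0 <= slice_index < n_slices:
            raise ValueError(
                f"slice_index {slice_index} out of range [0, {n_slices - 1}]"
            )
        arr = data[:, :, slice_index]
    zooms = img.header.get_zooms()
    spacing = float(zooms[0]) if zooms else None
    return np.asarray(arr, dtype=float), spacing


def load_slice(
    path,
    level: str,
    symptomatic_side: str,
    fmt: str | None = None,
    slice_index: int | None = None,
) -> CTASlice:
    """Load one grayscale axial slice as a :class:`CTASlice`.

    ``fmt`` is inferred from the extension when omitted.  DICOM rescale
    slope/intercept are applied so intensities are HU when the file is
    calibrated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        ext = path.suffix.lower()
        fmt = {
            ".png": "png", ".tif": "tiff", ".tiff": "tiff",
            ".dcm": "dicom", ".dicom": "dicom",
            ".nii": "nifti", ".gz": "nifti",
        }.get(ext)
        if fmt is None:
            raise ValueError(f"cannot infer format from extension {ext!r}")
    spacing = None
    if fmt in ("png", "tiff"):
        arr = _load_png_tiff(path)
    elif fmt == "dicom":
        arr, spacing = _load_dicom(path)
    elif fmt == "nifti":
        arr, spacing = _load_nifti(path, slice_index)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return CTASlice(
        intensities=arr,
        level=level,
        symptomatic_side=symptomatic_side,
        pixel_spacing=spacing,
        source_id=path.name,
    )


def load_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV with tolerant headers and strict validation.

    Headers are matched case-insensitively against documented synonyms
    (e.g. ``mRS90`` / ``mrs_90``).  Scores are range-checked; every
    violation is reported with its row and column.  The binary outcome
    (favorable = mRS <= 2) is derived, never read.
    """
    df = pd.read_csv(path)
    rename = {}
    lower_map = {c.lower().strip(): c for c in df.columns}
    for canon, alts in COLUMN_SYNONYMS.items():
        for alt in alts:
            if alt in lower_map:
                rename[lower_map[alt]] = canon
                break
    df = df.rename(columns=rename)

    problems = [f"missing required column: {c}" for c in REQUIRED if c not in df.columns]
    if problems:
        raise CohortValidationError(problems)

    for col, (lo, hi) in RANGE_RULES.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[(vals < lo) | (vals > hi) | vals.isna()]:
            problems.append(
                f"row {idx}: column {col!r} value {df.loc[idx, col]!r} outside [{lo}, {hi}]"
            )
        df[col] = vals
    mfd_vals = pd.to_numeric(df["mfd"], errors="coerce")
    for idx in df.index[(mfd_vals <= 0) | mfd_vals.isna()]:
        problems.append(f"row {idx}: column 'mfd' value {df.loc[idx, 'mfd']!r} not positive")
    df["mfd"] = mfd_vals
    sex_norm = df["sex"].astype(str).str.lower().str.strip()
    sex_map = {"m": "male", "male": "male", "1": "male", "f": "female", "female": "female", "0": "female"}
    for idx in df.index[~sex_norm.isin(sex_map)]:
        problems.append(f"row {idx}: column 'sex' value {df.loc[idx, 'sex']!r} unrecognized")
    if problems:
        raise CohortValidationError(problems)

    df["sex"] = sex_norm.map(sex_map)
    for col in RANGE_RULES:
        df[col] = df[col].astype(int)
    df["outcome"] = (df["mrs_90"] <= 2).astype(int)
    if "case_id" not in df.columns:
        df.insert(0, "case_id", [f"case{idx:04d}" for idx in range(len(df))])
    return df


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
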
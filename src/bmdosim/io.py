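"""File formats: NIfTI/MetaImage volumes, calibration TOML, tidy CSV tables."""

from __future__ import annotations

import sys
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .calibration import CalibrationModel

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

__all__ = [
    "read_image",
    "write_image",
    "write_mask",
    "read_calibration_toml",
    "write_calibration_toml",
    "read_depth_series_csv",
    "read_vertebra_csv",
]


def _is_metaimage(path: Path) -> bool:
    return path.suffix.lower() in (".mha", ".mhd")


def read_image(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI or MetaImage file; returns (array, 4x4 affine)."""
    path = Path(path)
    if _is_metaimage(path):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img).astype(float)
        affine = np.eye(4)
        spacing = list(img.GetSpacing())[::-1]
        for i, s in enumerate(spacing):
            affine[i, i] = s
        return arr, affine
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def write_image(array: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_metaimage(path):
        import SimpleITK as sitk

        sitk.WriteImage(sitk.GetImageFromArray(np.asarray(array)), str(path))
        return
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float64), affine), str(path))


def write_mask(mask: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    """Write a binary mask as unsigned 8-bit NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    nib.save(
        nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path)
    )


def read_depth_series_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Calibration depth series: columns ``depth_cm``, ``count_rate_cps``."""
    df = pd.read_csv(path)
    return df["depth_cm"].to_numpy(float), df["count_rate_cps"].to_numpy(float)


def write_calibration_toml(model: CalibrationModel, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        "[calibration]",
        f'camera_id = "{model.camera_id}"',
        f"sensitivity_cps_per_mbq = {model.sensitivity!r}",
        f"mu_eff_per_cm = {model.mu_eff!r}",
        f"fit_residual = {model.fit_residual!r}",
    ]
    path.write_text("\n".join(lines) + "\n")


def read_calibration_toml(path: str | Path) -> CalibrationModel:
    data = tomllib.loads(Path(path).read_text())["calibration"]
    return CalibrationModel(
        sensitivity=data["sensitivity_cps_per_mbq"],
        mu_eff=data["mu_eff_per_cm"],
        fit_residual=data.get("fit_residual", 0.0),
        camera_id=data.get("camera_id", ""),
    )


def read_vertebra_csv(path: str | Path) -> pd.DataFrame:
    """Vertebra table: label, z_mm, y_mm, x_mm, metastasis[, visible]."""
    df = pd.read_csv(path)
    required = {"label", "z_mm", "y_mm", "x_mm", "metastasis"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"vertebra CSV missing columns: {sorted(missing)}")
    if "visible" not in df.columns:
        df["visible"] = True
    return df
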
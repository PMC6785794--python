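"""Vertebral sphere VOIs on SPECT/CT and reference-concentration selection.

A spherical volume of interest of 0.7 cm3 is placed at the centre of each
visible vertebral body on CT and transferred to the co-registered,
calibrated SPECT volume (kBq/mL); the sphere is deliberately smaller than
the vertebra to limit partial-volume contamination from adjacent high-uptake
organs.  Four hybrid dosimetry variants pick a single reference
concentration per patient:

* ``L4_SPECT`` — the L4 vertebra, falling back to L5, then L3, then L2 when
  the preferred vertebra is metastatic or not visible;
* ``V_SPECT`` / ``L_SPECT`` / ``T_SPECT`` — the median concentration over
  all visible, lumbar (L1-L5) and thoracic (T1-T12) vertebrae respectively.
  Metastatic vertebrae stay in the medians; the median itself damps their
  influence.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "VERTEBRA_LABELS",
    "THORACIC_LABELS",
    "LUMBAR_LABELS",
    "VertebraMeasurement",
    "HybridMethod",
    "sphere_voi_mask",
    "voi_concentration",
    "select_reference_concentration",
    "DEFAULT_VOI_VOLUME_CM3",
]

THORACIC_LABELS = tuple(f"T{i}" for i in range(1, 13))
LUMBAR_LABELS = tuple(f"L{i}" for i in range(1, 6))
VERTEBRA_LABELS = THORACIC_LABELS + LUMBAR_LABELS

#: Sphere volume used for vertebral-body sampling, cm^3.
DEFAULT_VOI_VOLUME_CM3 = 0.7

#: Fallback order for the single-vertebra method.
L4_FALLBACK_CHAIN = ("L4", "L5", "L3", "L2")


class HybridMethod(str, Enum):
    """The four SPECT-rescaled dosimetry variants."""

    L4_SPECT = "L4_SPECT"
    V_SPECT = "V_SPECT"
    L_SPECT = "L_SPECT"
    T_SPECT = "T_SPECT"


@dataclass
class VertebraMeasurement:
    """Per-vertebra SPECT concentration with anatomical label and flags."""

    label: str
    concentration: float  # kBq/mL
    metastasis: bool = False
    center: tuple[float, float, float] | None = None  # physical mm
    visible: bool = True

    def __post_init__(self) -> None:
        if self.label not in VERTEBRA_LABELS:
            raise ValueError(f"unknown vertebra label {self.label!r}")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


def sphere_voi_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center: tuple[float, float, float],
    volume_cm3: float = DEFAULT_VOI_VOLUME_CM3,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Boolean mask of voxels whose centres lie in a sphere of given volume.

    Parameters
    ----------
    shape, spacing, origin:
        Voxel lattice: array shape, voxel spacing in mm per axis, and the
        physical coordinate (mm) of the voxel at index (0, 0, 0).
    center:
        Sphere centre in physical mm.
    volume_cm3:
        Sphere volume; the radius is ``(3 V / 4 pi)^(1/3)``
        (about 5.51 mm for 0.7 cm^3).

    Raises
    ------
    ValueError
        If the sphere extends outside the grid or the volume is not positive.
    """
    if volume_cm3 <= 0:
        raise ValueError("volume must be > 0")
    spacing_arr = np.asarray(spacing, dtype=float)
    origin_arr = np.asarray(origin, dtype=float)
    center_arr = np.asarray(center, dtype=float)
    radius_mm = (3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)

    extent_lo = origin_arr - 0.5 * spacing_arr
    extent_hi = origin_arr + (np.asarray(shape) - 0.5) * spacing_arr
    if np.any(center_arr - radius_mm < extent_lo) or np.any(
        center_arr + radius_mm > extent_hi
    ):
        raise ValueError("VOI out of bounds")

    coords = [
        origin_arr[ax] + spacing_arr[ax] * np.arange(shape[ax]) for ax in range(3)
    ]
    dz, dy, dx = np.meshgrid(
        coords[0] - center_arr[0],
        coords[1] - center_arr[1],
        coords[2] - center_arr[2],
        indexing="ij",
    )
    return dz * dz + dy * dy + dx * dx <= radius_mm * radius_mm


def voi_concentration(spect: np.ndarray, mask: np.ndarray) -> float:
    """Mean SPECT voxel value (kBq/mL) inside a VOI mask."""
    spect_arr = np.asarray(spect, dtype=float)
    mask_arr = np.asarray(mask, dtype=bool)
    if spect_arr.shape != mask_arr.shape:
        raise ValueError("SPECT volume and mask shapes differ")
    if not mask_arr.any():
        raise ValueError("empty mask")
    return float(spect_arr[mask_arr].mean())


def _median(values: list[float]) -> float:
    return float(np.median(np.asarray(values, dtype=float)))


def select_reference_concentration(
    measurements: list[VertebraMeasurement],
    method: HybridMethod | str,
) -> float:
    """Reference marrow concentration (kBq/mL) for one hybrid method.

    ``L4_SPECT`` walks the fallback chain L4 -> L5 -> L3 -> L2, skipping
    metastatic or invisible vertebrae; the median methods pool every visible
    vertebra of the relevant region, metastatic ones included.
    """
    method = HybridMethod(method)
    labels_seen = [m.label for m in measurements]
    if len(set(labels_seen)) != len(labels_seen):
        raise ValueError("duplicate vertebra labels")
    by_label = {m.label: m for m in measurements}

    if method is HybridMethod.L4_SPECT:
        for label in L4_FALLBACK_CHAIN:
            m = by_label.get(label)
            if m is not None and m.visible and not m.metastasis:
                return m.concentration
        raise ValueError("no eligible lumbar vertebra")

    if method is HybridMethod.V_SPECT:
        pool = [m.concentration for m in measurements if m.visible]
    elif method is HybridMethod.L_SPECT:
        pool = [
            m.concentration
            for m in measurements
            if m.visible and m.label in LUMBAR_LABELS
        ]
    else:  # T_SPECT
        pool = [
            m.concentration
            for m in measurements
            if m.visible and m.label in THORACIC_LABELS
        ]
    if not pool:
        raise ValueError(f"no visible vertebrae for {method.value}")
    return _median(pool)
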
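"""ROI pixel-count contracts and per-subject scalar metrics.

The study quantified velocity and pressure gradient over 4-8 pixels at the
aqueduct entry and outlet, and rotation over 12-20 pixels; those counts are
enforced here as hard contracts. A 4D field is reduced to one scalar per
subject by (a) spatially averaging the vector magnitude over valid ROI
voxels at each cardiac phase and (b) reducing the resulting waveform to its
peak (default; time-mean and median are selectable and recorded).
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Union

import numpy as np
from scipy.ndimage import label

from .fields import DerivedField4D, VelocityField4D

__all__ = [
    "PIXEL_BOUNDS",
    "RoiMask",
    "RoiContractError",
    "validate_roi",
    "roi_timeseries",
    "subject_metric",
    "SubjectMetrics",
]

#: inclusive pixel-count bounds per measured quantity
PIXEL_BOUNDS: dict[str, tuple[int, int]] = {
    "velocity": (4, 8),
    "pressure_gradient": (4, 8),
    "rotation": (12, 20),
}


class RoiContractError(ValueError):
    """An ROI violates its pixel-count or validity contract."""


@dataclass
class RoiMask:
    """Voxel-index ROI tied to the quantity it measures.

    ``indices`` is an integer array of shape (k, 3); ``quantity`` one of
    'velocity', 'pressure_gradient', 'rotation'.
    """

    indices: np.ndarray
    quantity: str
    name: str = ""

    def __post_init__(self) -> None:
        self.indices = np.atleast_2d(np.asarray(self.indices, dtype=int))
        if self.indices.ndim != 2 or self.indices.shape[1] != 3:
            raise ValueError("indices must have shape (k, 3)")
        if self.quantity not in PIXEL_BOUNDS:
            raise ValueError(f"unknown quantity {self.quantity!r}")

    @property
    def pixel_count(self) -> int:
        return self.indices.shape[0]

    def as_tuple(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.indices.T)  # type: ignore[return-value]


def _is_connected(indices: np.ndarray) -> bool:
    if indices.shape[0] == 1:
        return True
    mins = indices.min(axis=0)
    span = indices.max(axis=0) - mins + 1
    vol = np.zeros(tuple(span), dtype=bool)
    vol[tuple((indices - mins).T)] = True
    structure = np.zeros((3, 3, 3), dtype=bool)
    structure[1, 1, :] = structure[1, :, 1] = structure[:, 1, 1] = True
    _, n = label(vol, structure=structure)
    return n == 1


def validate_roi(
    mask: RoiMask, valid_volume: np.ndarray | None = None
) -> RoiMask:
    """Enforce the pixel-count contract for the ROI's quantity.

    4-8 pixels for velocity / pressure-gradient ROIs, 12-20 for rotation;
    the ROI must be connected; and if ``valid_volume`` (the stencil-validity
    mask of a derived field) is given, at least one ROI voxel must be valid.
    Returns the mask unchanged on success.
    """
    if mask.pixel_count == 0:
        raise RoiContractError("ROI is empty")
    lo, hi = PIXEL_BOUNDS[mask.quantity]
    if mask.pixel_count < lo:
        raise RoiContractError(
            f"{mask.quantity} ROI has {mask.pixel_count} pixels, below the "
            f"lower bound {lo}"
        )
    if mask.pixel_count > hi:
        raise RoiContractError(
            f"{mask.quantity} ROI has {mask.pixel_count} pixels, above the "
            f"upper bound {hi}"
        )
    if not _is_connected(mask.indices):
        raise RoiContractError(f"{mask.quantity} ROI is not connected")
    if valid_volume is not None and not np.any(valid_volume[mask.as_tuple()]):
        raise RoiContractError(
            f"{mask.quantity} ROI contains no valid (interior) voxel"
        )
    return mask


def roi_timeseries(
    field: Union[VelocityField4D, DerivedField4D], mask: RoiMask
) -> np.ndarray:
    """Per-cardiac-phase spatial mean of the vector magnitude over the ROI.

    Voxels flagged invalid on the field are excluded; a phase with no valid
    voxel is returned as NaN (missing).
    """
    if isinstance(field, VelocityField4D):
        values, valid = field.v, field.valid
    else:
        values, valid = field.values, field.valid
    idx = mask.indices
    if valid is not None:
        keep = valid[mask.as_tuple()]
        idx = idx[keep]
    if idx.shape[0] == 0:
        return np.full(values.shape[3], np.nan)
    mags = np.linalg.norm(values[tuple(idx.T)], axis=-1)  # (k, nt)
    return mags.mean(axis=0)


def subject_metric(series: np.ndarray, reduction: str = "peak") -> float:
    """Reduce a per-phase scalar series to one number.

    'peak' (default) takes the maximum over cardiac phases — PC-MRI studies
    report peak values and the hyperdynamic question concerns amplitude;
    'mean' and 'median' are alternatives. Missing phases (NaN) are ignored;
    an all-missing series raises.
    """
    s = np.asarray(series, dtype=float)
    if s.size == 0 or np.all(np.isnan(s)):
        raise ValueError("series has no non-missing phases")
    if reduction == "peak":
        return float(np.nanmax(s))
    if reduction == "mean":
        return float(np.nanmean(s))
    if reduction == "median":
        return float(np.nanmedian(s))
    raise ValueError(f"unknown reduction {reduction!r}")


@dataclass
class SubjectMetrics:
    """One row of the cohort table: scalar metrics plus ROI provenance."""

    subject_id: str
    group: str
    velocity: float           # cm/s
    pressure_gradient: float  # Pa/m
    rotation: float           # cycles/s
    rotation_per_area: float | None = None  # cycles/s per cm^2 of ROI section
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("velocity", "pressure_gradient", "rotation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} metric must be a non-negative magnitude")
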
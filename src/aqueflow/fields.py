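"""In-memory containers for gated 4D phase-contrast data and derived fields.

Array layout is ``(nx, ny, nz, nt)`` for scalar volumes and
``(nx, ny, nz, nt, 3)`` for vector fields, matching the NIfTI axis order
(x = right-left, y = anterior-posterior, z = head-foot, then time, then
vector component). Velocities are stored in cm/s, geometry in mm; SI
conversion happens inside :mod:`aqueflow.fluid_mechanics` only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["PhaseContrastSeries", "VelocityField4D", "DerivedField4D"]


@dataclass
class PhaseContrastSeries:
    """Raw cardiac-gated phase-contrast series.

    Parameters
    ----------
    magnitude : ndarray, shape (nx, ny, nz, nt)
        Magnitude image, arbitrary units.
    phase : ndarray, shape (nx, ny, nz, nt, 3)
        Velocity-encoded phase per direction, radians in (-pi, pi].
    venc : ndarray, shape (3,)
        Velocity-encoding limit per direction, cm/s.
    voxel_size : float
        Isotropic voxel edge, mm.
    heart_rate : float
        Beats per minute of the gated acquisition.
    """

    magnitude: np.ndarray
    phase: np.ndarray
    venc: np.ndarray
    voxel_size: float
    heart_rate: float

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        self.venc = np.broadcast_to(np.asarray(self.venc, dtype=float), (3,)).copy()
        if self.phase.shape != self.magnitude.shape + (3,):
            raise ValueError(
                f"phase shape {self.phase.shape} does not match "
                f"magnitude shape {self.magnitude.shape} + (3,)"
            )
        if np.any(self.venc <= 0):
            raise ValueError("venc must be strictly positive")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be strictly positive")

    @property
    def n_phases(self) -> int:
        return self.magnitude.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.magnitude.shape[:3]


@dataclass
class VelocityField4D:
    """Three-component velocity on a regular grid over one cardiac cycle.

    ``v`` has shape ``(nx, ny, nz, nt, 3)`` in cm/s. ``phase_duration`` is the
    temporal bin width in seconds (60 / (heart_rate * nt)); the time axis is
    periodic over the cycle. ``mask`` optionally marks the flow region (e.g.
    the aqueduct lumen); ``valid`` marks voxels whose values are trustworthy
    (e.g. survived temporal unwrapping).
    """

    v: np.ndarray
    voxel_size: float
    phase_duration: float
    mask: Optional[np.ndarray] = None
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim != 5 or self.v.shape[-1] != 3:
            raise ValueError(f"v must have shape (nx,ny,nz,nt,3), got {self.v.shape}")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("velocity field contains non-finite values")
        if self.voxel_size <= 0 or self.phase_duration <= 0:
            raise ValueError("voxel_size and phase_duration must be positive")
        for name in ("mask", "valid"):
            m = getattr(self, name)
            if m is not None and m.shape != self.grid_shape:
                raise ValueError(f"{name} shape {m.shape} != grid {self.grid_shape}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.v.shape[:3]

    @property
    def n_phases(self) -> int:
        return self.v.shape[3]

    @property
    def heart_rate(self) -> float:
        return 60.0 / (self.phase_duration * self.n_phases)

    def copy_with(self, **kw) -> "VelocityField4D":
        args = dict(
            v=self.v, voxel_size=self.voxel_size, phase_duration=self.phase_duration,
            mask=self.mask, valid=self.valid,
        )
        args.update(kw)
        return VelocityField4D(**args)


@dataclass
class DerivedField4D:
    """Vector quantity derived from a velocity field (same grid and gating).

    ``units`` tags the physical meaning ('Pa/m' for pressure gradient,
    'rad/s' for rotation). ``valid`` marks voxels with full difference
    stencils inside the flow mask; values outside it are not meaningful.
    """

    values: np.ndarray
    units: str
    voxel_size: float
    phase_duration: float
    valid: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 5 or self.values.shape[-1] != 3:
            raise ValueError(f"values must be (nx,ny,nz,nt,3), got {self.values.shape}")
        if self.valid is None:
            self.valid = np.ones(self.values.shape[:3], dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.values.shape[:3]:
            raise ValueError("valid mask shape mismatch")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("non-finite derived values on valid voxels")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    @property
    def n_phases(self) -> int:
        return self.values.shape[3]


def voxel_centers(grid_shape: tuple[int, int, int], voxel_size: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World coordinates (mm) of voxel centers, 0-based indices times spacing."""
    return tuple(np.arange(n) * voxel_size for n in grid_shape)  # type: ignore[return-value]


def grid_center(grid_shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
    """Geometric center of the grid in mm."""
    return (np.asarray(grid_shape, dtype=float) - 1.0) / 2.0 * voxel_size
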
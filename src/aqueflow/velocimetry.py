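"""Phase-contrast series to calibrated velocity fields.

The linear map is v_d = phase_d / pi * VENC_d. Velocities beyond VENC wrap
(alias) with period 2*VENC; because the aqueduct waveform is smooth in time
but the vessel is thin in space, unwrapping is done along the periodic
cardiac-phase axis rather than spatially. Voxels with an inconsistent
winding around the cycle (a true jump larger than VENC cannot be told from
a wrap) are marked invalid instead of guessed.
"""
from __future__ import annotations

import numpy as np

from .fields import PhaseContrastSeries, VelocityField4D

__all__ = ["phase_to_velocity", "detect_aliasing", "unwrap_temporal"]


def phase_to_velocity(pc: PhaseContrastSeries) -> VelocityField4D:
    """Scale encoded phase to velocity: v_d = phase_d/pi * VENC_d (cm/s)."""
    v = pc.phase / np.pi * pc.venc
    return VelocityField4D(
        v=v,
        voxel_size=pc.voxel_size,
        phase_duration=60.0 / (pc.heart_rate * pc.n_phases),
    )


def _wrapped_jumps(v: np.ndarray, venc: np.ndarray) -> np.ndarray:
    """Adjacent-phase differences with periodic wrap along the time axis."""
    return np.roll(v, -1, axis=3) - v


def detect_aliasing(vf: VelocityField4D, venc: float | np.ndarray) -> np.ndarray:
    """Flag voxels whose velocity jumps between periodic time neighbors
    exceed VENC (half the 2*VENC wrap period) in any component.

    Returns a boolean (nx, ny, nz) volume.
    """
    venc = np.broadcast_to(np.asarray(venc, dtype=float), (3,))
    if np.any(venc <= 0):
        raise ValueError("venc must be > 0")
    jumps = _wrapped_jumps(vf.v, venc)
    return np.any(np.abs(jumps) > venc, axis=(3, 4))


def unwrap_temporal(vf: VelocityField4D, venc: float | np.ndarray) -> VelocityField4D:
    """Undo VENC aliasing along the cardiac-phase axis.

    Adds integer multiples of 2*VENC per time point so that adjacent-phase
    jumps are minimized, then re-centers each voxel series so its temporal
    mean lies within (-VENC, VENC]. Idempotent on already-unwrapped input.
    Voxels whose wrapped jumps do not close around the periodic cycle
    (ambiguous winding) keep their original values and are marked invalid
    in the returned field's ``valid`` mask.
    """
    venc = np.broadcast_to(np.asarray(venc, dtype=float), (3,))
    if np.any(venc <= 0):
        raise ValueError("venc must be > 0")
    v = vf.v
    out = np.empty_like(v)
    valid = np.ones(vf.grid_shape, dtype=bool)
    for d in range(3):
        period = 2.0 * venc[d]
        out[..., d] = np.unwrap(v[..., d], axis=3, period=period)
        # winding consistency: wrapped jumps must sum to zero around the cycle
        jumps = np.roll(v[..., d], -1, axis=3) - v[..., d]
        wrapped = jumps - period * np.round(jumps / period)
        winding = np.abs(wrapped.sum(axis=3)) > period / 2.0
        # re-center: temporal mean into (-venc, venc]
        shift = period * np.round(out[..., d].mean(axis=3, keepdims=True) / period)
        out[..., d] -= shift
        bad = winding
        out[bad, :, d] = v[bad, :, d]
        valid &= ~bad
    if vf.valid is not None:
        valid &= vf.valid
    return vf.copy_with(v=out, valid=valid)
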
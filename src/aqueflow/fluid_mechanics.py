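"""Navier-Stokes pressure-gradient and rotation fields from 4D velocity.

For incompressible laminar flow the momentum balance

    rho*dv/dt + rho*(v.grad)v = -grad p + mu*laplacian(v)

is solved pointwise for the pressure gradient:

    grad p = mu*laplacian(v) - rho*dv/dt - rho*(v.grad)v   [Pa/m]

All spatial derivatives are 2nd-order central differences; the time
derivative is a central difference with periodic wrap over the cardiac
cycle (cine gating covers exactly one cycle). Voxels lacking a full
6-neighborhood inside the flow mask are flagged invalid rather than
estimated one-sidedly: one-sided stencils at the aqueduct wall produce
spurious gradients, and exclusion is the conservative choice.

Velocities arrive in cm/s with geometry in mm; conversion to SI happens
here and only here. Rotation (vorticity) is the curl, reported in rad/s
with a cycles/s convenience conversion (curl / 2*pi).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion

from .fields import DerivedField4D, VelocityField4D
from .phantoms import FluidProperties

__all__ = [
    "NSTerms",
    "interior_mask",
    "time_derivative",
    "convective_term",
    "viscous_term",
    "pressure_gradient",
    "rotation",
    "RAD_TO_CYCLES",
]

RAD_TO_CYCLES = 1.0 / (2.0 * np.pi)

_CROSS6 = np.zeros((3, 3, 3), dtype=bool)
_CROSS6[1, 1, :] = _CROSS6[1, :, 1] = _CROSS6[:, 1, 1] = True


@dataclass
class NSTerms:
    """Term-by-term decomposition of the momentum balance, each in Pa/m.

    The identity ``pressure_gradient == viscosity - acceleration - convection``
    holds exactly (elementwise) on valid voxels.
    """

    acceleration: np.ndarray  # rho * dv/dt
    convection: np.ndarray    # rho * (v.grad)v
    viscosity: np.ndarray     # mu * laplacian(v)


def interior_mask(mask: np.ndarray) -> np.ndarray:
    """Voxels whose full 6-neighborhood (and themselves) lie inside ``mask``.

    Grid-boundary voxels are never interior (erosion with zero border).
    """
    return binary_erosion(np.asarray(mask, dtype=bool), structure=_CROSS6, border_value=0)


def _cdiff(a: np.ndarray, axis: int, spacing: float) -> np.ndarray:
    """Central difference via periodic roll; only interior values are used."""
    return (np.roll(a, -1, axis=axis) - np.roll(a, 1, axis=axis)) / (2.0 * spacing)


def time_derivative(vf: VelocityField4D) -> np.ndarray:
    """dv/dt with periodic wrap over the cardiac cycle, in cm/s per s.

    Central difference: phase 0 neighbors are N-1 and 1. Exact for fields
    linear in t across the stencil; requires >= 3 cardiac phases.
    """
    if vf.n_phases < 3:
        raise ValueError("time derivative needs at least 3 cardiac phases")
    return _cdiff(vf.v, axis=3, spacing=vf.phase_duration)


def convective_term(vf: VelocityField4D) -> np.ndarray:
    """(v.grad)v via central spatial differences, in cm/s per s * (cm/s scaling).

    Returned in units of (cm/s)^2 per mm; callers normalize to SI. Valid only
    on interior voxels (use :func:`interior_mask`).
    """
    v = vf.v
    out = np.zeros_like(v)
    for j in range(3):  # derivative axis
        dj = _cdiff(v, axis=j, spacing=vf.voxel_size)
        out += v[..., j:j + 1] * dj
    return out


def viscous_term(vf: VelocityField4D, fluid: FluidProperties) -> np.ndarray:
    """mu * laplacian(v) via the 7-point stencil, returned in SI (Pa/m).

    Exactly zero for fields linear in space; exact for quadratic profiles
    (the parabolic Poiseuille benchmark).
    """
    h_m = vf.voxel_size * 1e-3
    v_si = vf.v * 1e-2
    lap = np.zeros_like(v_si)
    for j in range(3):
        lap += (
            np.roll(v_si, -1, axis=j) + np.roll(v_si, 1, axis=j) - 2.0 * v_si
        ) / h_m**2
    return fluid.dynamic_viscosity * lap


def pressure_gradient(
    vf: VelocityField4D,
    fluid: FluidProperties = FluidProperties(),
    mask: np.ndarray | None = None,
) -> tuple[DerivedField4D, NSTerms]:
    """Pressure gradient grad p = mu*lap(v) - rho*dv/dt - rho*(v.grad)v, Pa/m.

    ``mask`` defaults to the field's flow mask (everything, if absent);
    validity is its interior under the full central stencil.
    """
    rho = fluid.density
    acc = rho * time_derivative(vf) * 1e-2                      # Pa/m
    conv = rho * convective_term(vf) * 1e-2 * 1e-2 / 1e-3       # (cm/s * cm/s/mm) -> SI
    visc = viscous_term(vf, fluid)                              # Pa/m
    gp = visc - acc - conv
    if mask is None:
        mask = vf.mask if vf.mask is not None else np.ones(vf.grid_shape, dtype=bool)
    valid = interior_mask(mask)
    if vf.valid is not None:
        valid = valid & interior_mask(vf.valid)
    field = DerivedField4D(
        values=gp, units="Pa/m",
        voxel_size=vf.voxel_size, phase_duration=vf.phase_duration, valid=valid,
    )
    return field, NSTerms(acceleration=acc, convection=conv, viscosity=visc)


def rotation(
    vf: VelocityField4D,
    mask: np.ndarray | None = None,
) -> DerivedField4D:
    """Vorticity curl(v) via central differences, rad/s.

    Divide by 2*pi (``RAD_TO_CYCLES``) for cycles/s. For solid-body rotation
    at angular velocity omega the curl is exactly 2*omega on interior voxels,
    and the discrete curl of a discrete gradient field vanishes identically
    (the difference operators commute).
    """
    h_m = vf.voxel_size * 1e-3
    v_si = vf.v * 1e-2
    d = [
        [_cdiff(v_si[..., c], axis=j, spacing=h_m) for c in range(3)]
        for j in range(3)
    ]  # d[j][c] = d v_c / d x_j
    curl = np.stack(
        [
            d[1][2] - d[2][1],
            d[2][0] - d[0][2],
            d[0][1] - d[1][0],
        ],
        axis=-1,
    )
    if mask is None:
        mask = vf.mask if vf.mask is not None else np.ones(vf.grid_shape, dtype=bool)
    valid = interior_mask(mask)
    if vf.valid is not None:
        valid = valid & interior_mask(vf.valid)
    return DerivedField4D(
        values=curl, units="rad/s",
        voxel_size=vf.voxel_size, phase_duration=vf.phase_duration, valid=valid,
    )
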
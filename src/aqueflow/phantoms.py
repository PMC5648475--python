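"""Analytic pulsatile-flow phantoms and a phase-contrast MR encoding model.

The phantoms stand in for in-vivo aqueduct CSF flow: an oscillatory
pressure gradient G·cos(k·omega·t + phi) drives laminar axial flow in a rigid
circular tube (Womersley's solution), optionally with several cardiac
harmonics. The encoding model maps velocity to signal phase (phase =
pi·v/VENC, wrapped), adds complex Gaussian noise at a stated magnitude SNR,
and emulates the study acquisition geometry: 32 cardiac phases, ~2 mm
isotropic voxels, 10 slices, VENC 5 cm/s (volunteers) or 30 cm/s (patients).

All generators are pure functions of (spec, seed).
"""
from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import jv

from .fields import PhaseContrastSeries, VelocityField4D, grid_center

__all__ = [
    "FluidProperties",
    "WomersleyPhantomSpec",
    "EncodingSpec",
    "GroupSimConfig",
    "CohortSimConfig",
    "womersley_velocity",
    "poiseuille_velocity",
    "rigid_rotation_velocity",
    "tissue_template",
    "encode_phase_contrast",
    "simulate_cohort",
]


class FluidProperties(BaseModel):
    """Newtonian fluid constants. CSF is water-like at body temperature."""

    model_config = ConfigDict(frozen=True)

    density: float = Field(default=1000.0, gt=0, description="kg/m^3")
    dynamic_viscosity: float = Field(default=1.0e-3, gt=0, description="Pa*s")


CSF = FluidProperties()


class WomersleyPhantomSpec(BaseModel):
    """Geometry, gating and forcing of a Womersley tube phantom.

    ``pressure_gradient_amplitude`` is the amplitude G (Pa/m) of the
    oscillatory axial driving gradient at the cardiac fundamental;
    ``harmonics`` adds components (k, amplitude, phase) at k times the
    fundamental frequency. The tube runs along ``tube_axis`` through the
    grid center.
    """

    model_config = ConfigDict(frozen=True)

    tube_radius: float = Field(default=2.0, gt=0, description="mm")
    tube_axis: int = Field(default=2, ge=0, le=2)
    pressure_gradient_amplitude: float = Field(default=100.0, ge=0, description="Pa/m")
    phase_offset: float = Field(default=0.0, description="rad, fundamental")
    heart_rate: float = Field(default=60.0, gt=0, description="bpm")
    n_cardiac_phases: int = Field(default=32, ge=4)
    voxel_size: float = Field(default=1.96, gt=0, description="mm, isotropic")
    grid_shape: tuple[int, int, int] = (16, 16, 10)
    fluid: FluidProperties = CSF
    harmonics: tuple[tuple[int, float, float], ...] = Field(
        default=(), description="(harmonic index k>=2, amplitude Pa/m, phase rad)"
    )

    @model_validator(mode="after")
    def _check(self) -> "WomersleyPhantomSpec":
        trans = [i for i in range(3) if i != self.tube_axis]
        for i in trans:
            half_extent = (self.grid_shape[i] - 1) / 2.0 * self.voxel_size
            if self.tube_radius > half_extent:
                raise ValueError(
                    f"tube radius {self.tube_radius} mm does not fit inside the "
                    f"grid (half extent {half_extent} mm along axis {i})"
                )
        for k, _, _ in self.harmonics:
            if k < 2:
                raise ValueError("harmonic indices must be >= 2")
        return self

    @property
    def omega(self) -> float:
        """Fundamental angular frequency, rad/s."""
        return 2.0 * math.pi * self.heart_rate / 60.0

    @property
    def womersley_number(self) -> float:
        f = self.fluid
        return (self.tube_radius * 1e-3) * math.sqrt(
            self.omega * f.density / f.dynamic_viscosity
        )

    def forcing_components(self) -> list[tuple[int, float, float]]:
        """All (k, G_k, phi_k) driving components, fundamental first."""
        out = []
        if self.pressure_gradient_amplitude > 0:
            out.append((1, self.pressure_gradient_amplitude, self.phase_offset))
        out.extend(self.harmonics)
        return out


class EncodingSpec(BaseModel):
    """Phase-contrast encoding parameters.

    ``snr`` is the magnitude signal-to-noise ratio at unit template
    intensity; ``None`` (or inf) disables noise. ``partial_volume`` requests
    analytic in-voxel averaging of the velocity profile in the generators.
    """

    model_config = ConfigDict(frozen=True)

    venc: float | tuple[float, float, float] = Field(default=5.0, description="cm/s")
    snr: Optional[float] = Field(default=None, description="magnitude SNR; None = noiseless")
    seed: int = 0
    partial_volume: bool = False

    @model_validator(mode="after")
    def _check(self) -> "EncodingSpec":
        venc = np.broadcast_to(np.asarray(self.venc, dtype=float), (3,))
        if np.any(venc <= 0):
            raise ValueError("venc must be > 0")
        if self.snr is not None and not (self.snr > 0):
            raise ValueError("snr must be > 0 or None")
        return self

    @property
    def venc_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.venc, dtype=float), (3,)).copy()


def _transverse_radius(
    spec_axis: int,
    grid_shape: tuple[int, int, int],
    voxel_size: float,
    offsets: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Distance (mm) of every voxel center from the tube axis, 3D array.

    ``offsets`` shifts the sample point inside the voxel (for in-voxel
    averaging), in units of mm along the two transverse axes.
    """
    trans = [i for i in range(3) if i != spec_axis]
    center = grid_center(grid_shape, voxel_size)
    coords = []
    for j, i in enumerate(trans):
        c = np.arange(grid_shape[i]) * voxel_size + offsets[j] - center[i]
        coords.append(c)
    a, b = np.meshgrid(coords[0], coords[1], indexing="ij")
    r2d = np.hypot(a, b)
    # broadcast back to 3D with the tube axis restored
    r = np.expand_dims(r2d, axis=spec_axis)
    reps = [1, 1, 1]
    reps[spec_axis] = grid_shape[spec_axis]
    return np.tile(r, reps)


def _womersley_profile(
    r_over_R: np.ndarray, alpha_k: float, G_k: float, phi_k: float,
    rho: float, k_omega: float,
) -> np.ndarray:
    """Complex velocity amplitude u_hat(r) in m/s for one harmonic.

    u(r,t) = Re{ u_hat(r) * exp(i*k*omega*t) } with driving gradient
    -dp/dz = Re{ G_k * exp(i*(k*omega*t + phi_k)) }.
    """
    i32 = np.exp(1j * 3.0 * np.pi / 4.0)  # i^(3/2)
    z = i32 * alpha_k * np.clip(r_over_R, 0.0, None)
    zR = i32 * alpha_k
    prof = 1.0 - jv(0, z) / jv(0, zR)
    return (G_k * np.exp(1j * phi_k) / (1j * rho * k_omega)) * prof


def womersley_velocity(
    spec: WomersleyPhantomSpec,
    *,
    partial_volume: bool = False,
    subsamples: int = 4,
) -> tuple[VelocityField4D, np.ndarray]:
    """Sample the Womersley solution on the phantom grid.

    Returns the velocity field (cm/s; axial component along ``tube_axis``,
    transverse components zero, zero outside the lumen) and the ground-truth
    axial pressure-gradient time series dp/dz(t) = -sum_k G_k cos(k w t +
    phi_k) in Pa/m — the series the Navier-Stokes stage should recover.

    With ``partial_volume`` the voxel value is the analytic mean of the
    profile over a ``subsamples`` x ``subsamples`` in-voxel grid, emulating
    the partial-volume mixing the segmentation stage exists to counter.
    """
    gs, h = spec.grid_shape, spec.voxel_size
    R = spec.tube_radius
    r = _transverse_radius(spec.tube_axis, gs, h)
    if not np.any(r < R):
        raise ValueError(
            f"grid too coarse: no voxel center falls inside the tube; "
            f"minimum usable radius at this spacing is {float(r.min()):.3g} mm "
            f"(requested {R} mm)"
        )
    mask = r < R

    rho = spec.fluid.density
    mu = spec.fluid.dynamic_viscosity
    omega = spec.omega
    nt = spec.n_cardiac_phases
    t = np.arange(nt) / nt * (2.0 * np.pi / omega)  # one cycle, periodic

    if partial_volume:
        offs = (np.arange(subsamples) + 0.5) / subsamples * h - h / 2.0
        sample_offsets = [(a, b) for a in offs for b in offs]
    else:
        sample_offsets = [(0.0, 0.0)]

    axial = np.zeros(gs + (nt,), dtype=float)
    truth = np.zeros(nt, dtype=float)
    comps = spec.forcing_components()
    for k, G_k, phi_k in comps:
        truth -= G_k * np.cos(k * omega * t + phi_k)
    for k, G_k, phi_k in comps:
        k_omega = k * omega
        alpha_k = (R * 1e-3) * math.sqrt(k_omega * rho / mu)
        accum = np.zeros(gs, dtype=complex)
        inside_any = np.zeros(gs, dtype=bool)
        for off in sample_offsets:
            r_s = _transverse_radius(spec.tube_axis, gs, h, off)
            ins = r_s < R
            u_hat = np.zeros(gs, dtype=complex)
            u_hat[ins] = _womersley_profile(
                (r_s[ins] / R), alpha_k, G_k, phi_k, rho, k_omega
            )
            accum += u_hat
            inside_any |= ins
        u_hat_mean = accum / len(sample_offsets)
        # time expansion: Re{u_hat e^{i k w t}}, cm/s
        axial += 100.0 * np.real(
            u_hat_mean[..., None] * np.exp(1j * k_omega * t)[None, None, None, :]
        )
        if partial_volume:
            mask = mask | inside_any

    v = np.zeros(gs + (nt, 3), dtype=float)
    v[..., spec.tube_axis] = axial
    field = VelocityField4D(
        v=v,
        voxel_size=h,
        phase_duration=60.0 / (spec.heart_rate * nt),
        mask=mask,
    )
    return field, truth


def poiseuille_velocity(
    radius: float,
    peak_velocity: float,
    axis: int = 2,
    grid_shape: tuple[int, int, int] = (16, 16, 10),
    voxel_size: float = 0.5,
    n_phases: int = 4,
    heart_rate: float = 60.0,
) -> VelocityField4D:
    """Steady parabolic tube flow: u = peak*(1 - r^2/R^2) inside, 0 outside.

    ``radius`` in mm, ``peak_velocity`` in cm/s. Time axis is constant.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    r = _transverse_radius(axis, grid_shape, voxel_size)
    mask = r < radius
    u = np.zeros(grid_shape, dtype=float)
    u[mask] = peak_velocity * (1.0 - (r[mask] / radius) ** 2)
    v = np.zeros(grid_shape + (n_phases, 3), dtype=float)
    v[..., axis] = u[..., None]
    return VelocityField4D(
        v=v, voxel_size=voxel_size,
        phase_duration=60.0 / (heart_rate * n_phases), mask=mask,
    )


def rigid_rotation_velocity(
    omega_vector: Sequence[float],
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    voxel_size: float = 1.0,
    n_phases: int = 4,
    heart_rate: float = 60.0,
) -> VelocityField4D:
    """Solid-body rotation v = omega x (x - center), steady in time.

    ``omega_vector`` in rad/s, positions in mm, so v comes out in mm/s and is
    stored in cm/s (x0.1). The analytic curl is 2*omega everywhere.
    """
    w = np.asarray(omega_vector, dtype=float)
    if w.shape != (3,) or not np.all(np.isfinite(w)):
        raise ValueError("omega_vector must be 3 finite components (rad/s)")
    center = grid_center(grid_shape, voxel_size)
    x, y, z = np.meshgrid(
        *(np.arange(n) * voxel_size for n in grid_shape), indexing="ij"
    )
    pos = np.stack([x, y, z], axis=-1) - center  # mm
    v_mm_s = np.cross(np.broadcast_to(w, pos.shape), pos)
    v = np.repeat(v_mm_s[..., None, :] * 0.1, n_phases, axis=3)  # cm/s
    return VelocityField4D(
        v=v, voxel_size=voxel_size,
        phase_duration=60.0 / (heart_rate * n_phases),
    )


def tissue_template(
    grid_shape: tuple[int, int, int],
    voxel_size: float,
    csf_mask: np.ndarray,
    brain_fraction: float = 0.9,
) -> np.ndarray:
    """Three-class magnitude template: background 0.1, brain 0.5, CSF 1.0.

    The 'brain' is a centered in-plane disc covering ``brain_fraction`` of
    the half-extent; CSF voxels come from the flow mask.
    """
    center = grid_center(grid_shape, voxel_size)
    x, y = np.meshgrid(
        np.arange(grid_shape[0]) * voxel_size - center[0],
        np.arange(grid_shape[1]) * voxel_size - center[1],
        indexing="ij",
    )
    half = min(center[0], center[1]) if min(center[0], center[1]) > 0 else voxel_size
    brain = (np.hypot(x, y) <= brain_fraction * half)[..., None]
    tpl = np.where(np.broadcast_to(brain, grid_shape), 0.5, 0.1)
    tpl = np.where(csf_mask, 1.0, tpl)
    return tpl


def encode_phase_contrast(
    vf: VelocityField4D,
    enc: EncodingSpec,
    magnitude_template: Optional[np.ndarray] = None,
) -> PhaseContrastSeries:
    """Encode a velocity field as a phase-contrast series.

    Per direction d the noiseless encoded phase is pi*v_d/VENC_d wrapped to
    (-pi, pi]; velocities beyond VENC alias silently. Noise is modelled as
    independent complex Gaussian perturbations of the two interleaved
    acquisitions whose phase difference encodes the velocity, with per-channel
    standard deviation 1/SNR relative to unit template intensity; at high SNR
    this propagates to a velocity noise SD of sqrt(2)*VENC/(pi*SNR) on
    unit-intensity voxels. Bit-reproducible for a fixed seed.
    """
    venc = enc.venc_array
    gs, nt = vf.grid_shape, vf.n_phases
    if magnitude_template is None:
        mask = vf.mask if vf.mask is not None else np.zeros(gs, dtype=bool)
        magnitude_template = tissue_template(gs, vf.voxel_size, mask)
    A = np.asarray(magnitude_template, dtype=float)[..., None]  # (nx,ny,nz,1)

    rng = np.random.default_rng(enc.seed)
    phase = np.empty(gs + (nt, 3), dtype=float)
    magnitude = np.zeros(gs + (nt,), dtype=float)
    noisy = enc.snr is not None and np.isfinite(enc.snr)
    for d in range(3):
        phi = np.pi * vf.v[..., d] / venc[d]  # true (unwrapped) phase
        s_plus = A * np.exp(0.5j * phi)
        s_minus = A * np.exp(-0.5j * phi)
        if noisy:
            sigma = 1.0 / enc.snr
            s_plus = s_plus + sigma * (
                rng.standard_normal(phi.shape) + 1j * rng.standard_normal(phi.shape)
            )
            s_minus = s_minus + sigma * (
                rng.standard_normal(phi.shape) + 1j * rng.standard_normal(phi.shape)
            )
        phase[..., d] = np.angle(s_plus * np.conj(s_minus))
        magnitude += (np.abs(s_plus) + np.abs(s_minus)) / 6.0  # mean over 3 dirs
    return PhaseContrastSeries(
        magnitude=magnitude,
        phase=phase,
        venc=venc,
        voxel_size=vf.voxel_size,
        heart_rate=vf.heart_rate,
    )


class GroupSimConfig(BaseModel):
    """Per-group phantom distributions (log-normal in amplitude and radius)."""

    model_config = ConfigDict(frozen=True)

    n: int = Field(ge=1)
    pg_amplitude_median: float = Field(gt=0, description="Pa/m")
    pg_amplitude_sigma_log: float = Field(default=0.25, ge=0)
    tube_radius_median: float = Field(default=2.0, gt=0, description="mm")
    tube_radius_sigma_log: float = Field(default=0.05, ge=0)
    harmonic: int = Field(default=1, ge=1, description="cardiac harmonic carrying the forcing")
    venc: float = Field(default=5.0, gt=0, description="cm/s")


class CohortSimConfig(BaseModel):
    """Study-scale simulation: 19 controls, 10 iNPH, 7 AD by default.

    Patients carry their (4x control) pressure-gradient amplitude in the 4th
    cardiac harmonic so velocity amplitudes stay matched to controls — the
    hyperdynamic condition: higher acceleration at equal velocity. Patient
    VENC is 30 cm/s vs 5 cm/s for volunteers, as acquired in the study.
    """

    model_config = ConfigDict(frozen=True)

    groups: dict[str, GroupSimConfig] = Field(
        default={
            "control": GroupSimConfig(n=19, pg_amplitude_median=100.0, venc=5.0),
            # patient amplitude median calibrated once (simulation, n=200/arm)
            # so measured velocity-metric medians coincide with controls
            "iNPH": GroupSimConfig(
                n=10, pg_amplitude_median=354.5, harmonic=4, venc=30.0
            ),
            "AD": GroupSimConfig(
                n=7, pg_amplitude_median=354.5, harmonic=4, venc=30.0
            ),
        }
    )
    heart_rate_mean: float = Field(default=65.0, gt=0, description="bpm")
    heart_rate_sd: float = Field(default=5.0, ge=0)
    n_cardiac_phases: int = Field(default=32, ge=4)
    voxel_size: float = Field(default=0.4, gt=0, description="mm")
    grid_shape: tuple[int, int, int] = (20, 20, 10)
    snr: Optional[float] = 30.0
    partial_volume: bool = False
    fluid: FluidProperties = CSF
    seed: int = 0


def simulate_cohort(
    cfg: CohortSimConfig,
) -> tuple[list[dict], "pandas.DataFrame"]:  # noqa: F821
    """Generate one phantom acquisition per subject plus a ground-truth table.

    Returns ``(subjects, truth)`` where each subject dict holds ``subject_id``,
    ``group``, the encoded ``series`` (PhaseContrastSeries), the phantom
    ``spec`` and the ground-truth pressure-gradient time series; ``truth`` is a
    DataFrame with the drawn amplitude, radius and heart rate per subject.
    Deterministic given ``cfg.seed``.
    """
    import pandas as pd

    root = np.random.default_rng(cfg.seed)
    subjects: list[dict] = []
    rows: list[dict] = []
    idx = 0
    for group, g in cfg.groups.items():
        for j in range(g.n):
            draw = np.random.default_rng(root.integers(0, 2**31 - 1))
            G = float(
                g.pg_amplitude_median * math.exp(g.pg_amplitude_sigma_log * draw.standard_normal())
            )
            R = float(
                g.tube_radius_median * math.exp(g.tube_radius_sigma_log * draw.standard_normal())
            )
            hr = float(max(40.0, draw.normal(cfg.heart_rate_mean, cfg.heart_rate_sd)))
            if g.harmonic == 1:
                spec = WomersleyPhantomSpec(
                    tube_radius=R, pressure_gradient_amplitude=G, heart_rate=hr,
                    n_cardiac_phases=cfg.n_cardiac_phases, voxel_size=cfg.voxel_size,
                    grid_shape=cfg.grid_shape, fluid=cfg.fluid,
                )
            else:
                spec = WomersleyPhantomSpec(
                    tube_radius=R, pressure_gradient_amplitude=0.0, heart_rate=hr,
                    n_cardiac_phases=cfg.n_cardiac_phases, voxel_size=cfg.voxel_size,
                    grid_shape=cfg.grid_shape, fluid=cfg.fluid,
                    harmonics=((g.harmonic, G, 0.0),),
                )
            vf, truth_series = womersley_velocity(
                spec, partial_volume=cfg.partial_volume
            )
            enc = EncodingSpec(
                venc=g.venc, snr=cfg.snr, seed=int(draw.integers(0, 2**31 - 1)),
                partial_volume=cfg.partial_volume,
            )
            series = encode_phase_contrast(vf, enc)
            sid = f"{group}_{j:02d}"
            subjects.append(
                dict(
                    subject_id=sid, group=group, series=series, spec=spec,
                    truth_pg_series=truth_series, encoding=enc,
                )
            )
            rows.append(
                dict(
                    subject_id=sid, group=group, pg_amplitude=G, tube_radius=R,
                    heart_rate=hr, harmonic=g.harmonic, venc=g.venc,
                )
            )
            idx += 1
    return subjects, pd.DataFrame(rows)
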
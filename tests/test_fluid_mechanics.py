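"""Differential operators and the Navier-Stokes pressure-gradient balance."""
import numpy as np
import pytest

from aqueflow.fields import VelocityField4D
from aqueflow.fluid_mechanics import (
    NSTerms,
    _cdiff,
    convective_term,
    interior_mask,
    pressure_gradient,
    rotation,
    time_derivative,
    viscous_term,
)
from aqueflow.phantoms import (
    FluidProperties,
    WomersleyPhantomSpec,
    _transverse_radius,
    poiseuille_velocity,
    rigid_rotation_velocity,
    womersley_velocity,
)


def _field(v, voxel_size=1.0, phase_duration=0.1, **kw):
    return VelocityField4D(v=v, voxel_size=voxel_size, phase_duration=phase_duration, **kw)


class TestTimeDerivative:
    def test_steady_field_has_zero_derivative(self):
        v = np.ones((4, 4, 4, 8, 3)) * 2.5
        assert np.all(time_derivative(_field(v)) == 0)

    def test_sinusoid_amplitude_within_second_order(self):
        """d/dt sin(wt) recovered with < 2% relative error at 32 phases."""
        nt, hr = 32, 60.0
        omega = 2 * np.pi * hr / 60
        dt = 60.0 / (hr * nt)
        t = np.arange(nt) * dt
        v = np.zeros((2, 2, 2, nt, 3))
        v[..., 2] = np.sin(omega * t)
        d = time_derivative(_field(v, phase_duration=dt))
        expected = omega * np.cos(omega * t)
        err = np.abs(d[0, 0, 0, :, 2] - expected).max() / omega
        assert err < 0.02

    def test_requires_three_phases(self):
        v = np.zeros((3, 3, 3, 2, 3))
        with pytest.raises(ValueError, match="3 cardiac phases"):
            time_derivative(_field(v))

    def test_ramp_sign(self):
        """An increasing ramp has positive derivative away from the wrap."""
        nt = 8
        v = np.zeros((2, 2, 2, nt, 3))
        v[..., 2] = np.arange(nt)
        d = time_derivative(_field(v))
        assert np.all(d[..., 1 : nt - 1, 2] > 0)


class TestConvection:
    def test_uniform_field_vanishes(self):
        v = np.ones((5, 5, 5, 3, 3))
        conv = convective_term(_field(v))
        inner = interior_mask(np.ones((5, 5, 5), bool))
        assert np.all(conv[inner] == 0)

    def test_linear_shear_exact(self):
        """v = (a*x, 0, 0) gives (v.grad)v_x = a^2*x exactly (central
        differences are exact on linear fields)."""
        a, h = 0.7, 0.5
        n = 7
        x = np.arange(n) * h
        v = np.zeros((n, n, n, 3, 3))
        v[..., 0] = (a * x)[:, None, None, None]
        conv = convective_term(_field(v, voxel_size=h))
        inner = interior_mask(np.ones((n, n, n), bool))
        expected = (a**2 * x)[:, None, None, None] * np.ones((n, n, n, 3))
        assert np.allclose(conv[inner][..., 0], expected[inner], atol=1e-12)
        assert np.allclose(conv[inner][..., 1:], 0, atol=1e-12)

    def test_developed_poiseuille_has_no_convection(self):
        """Axial velocity varying only transversely: (v.grad)v = 0."""
        vf = poiseuille_velocity(2.0, 1.0, voxel_size=0.5, grid_shape=(24, 24, 8))
        conv = convective_term(vf)
        valid = interior_mask(vf.mask)
        assert np.allclose(conv[valid], 0, atol=1e-14)


class TestViscousTerm:
    def test_linear_field_has_zero_laplacian(self):
        h = 0.5
        n = 6
        x = np.arange(n) * h
        v = np.zeros((n, n, n, 3, 3))
        v[..., 2] = x[:, None, None, None] * 3.0 + 1.0
        visc = viscous_term(_field(v, voxel_size=h), FluidProperties())
        inner = interior_mask(np.ones((n, n, n), bool))
        assert np.allclose(visc[inner], 0, atol=1e-10)

    def test_poiseuille_closed_form(self):
        """mu*lap(u) = -4*mu*U0/R^2, exact for the quadratic profile:
        U0 = 1 cm/s, R = 2 mm, mu = 1e-3 Pa*s -> -10 Pa/m."""
        vf = poiseuille_velocity(2.0, 1.0, voxel_size=0.25, grid_shape=(40, 40, 8))
        visc = viscous_term(vf, FluidProperties())
        valid = interior_mask(vf.mask)
        assert np.allclose(visc[valid][..., 2], -10.0, rtol=1e-10)

    def test_zero_viscosity(self):
        vf = poiseuille_velocity(2.0, 1.0, voxel_size=0.5)
        visc = viscous_term(vf, FluidProperties(dynamic_viscosity=1e-30))
        assert np.allclose(visc, 0, atol=1e-20)


class TestPressureGradient:
    def test_steady_uniform_flow_gives_zero(self):
        v = np.ones((6, 6, 6, 4, 3))
        gp, terms = pressure_gradient(_field(v))
        assert np.allclose(gp.values[gp.valid], 0, atol=1e-12)

    def test_steady_poiseuille_closed_form(self):
        """Axial grad p = -4*mu*U0/R^2 = -10 Pa/m to machine precision;
        transverse components ~ 0."""
        vf = poiseuille_velocity(2.0, 1.0, voxel_size=0.5, grid_shape=(24, 24, 10))
        gp, terms = pressure_gradient(vf, FluidProperties())
        vals = gp.values[gp.valid]
        assert np.allclose(vals[..., 2], -10.0, rtol=1e-12)
        assert np.allclose(vals[..., :2], 0.0, atol=1e-9)
        assert np.allclose(terms.acceleration, 0) and np.allclose(terms.convection, 0)

    def test_womersley_waveform_recovery(self, study_phantom):
        """Spatial-mean axial grad p per phase tracks the driving gradient
        G*cos(wt+phi) with < 5% relative amplitude error at 0.5 mm."""
        vf, truth = study_phantom
        gp, _ = pressure_gradient(vf)
        rec = gp.values[gp.valid][:, :, 2].mean(axis=0)
        amp_rec = 0.5 * (rec.max() - rec.min())
        amp_true = 0.5 * (truth.max() - truth.min())
        assert abs(amp_rec - amp_true) / amp_true < 0.05
        # waveform (not just amplitude) matches
        assert np.max(np.abs(rec - truth)) / amp_true < 0.05

    def test_ns_terms_identity(self, study_phantom):
        """Returned grad p equals viscosity - acceleration - convection
        elementwise, exactly."""
        vf, _ = study_phantom
        gp, terms = pressure_gradient(vf)
        recomposed = terms.viscosity - terms.acceleration - terms.convection
        assert np.array_equal(gp.values, recomposed)

    def test_linearity_of_linear_operators(self, rng):
        """time_derivative and viscous_term are linear; convection is
        quadratic (checked via polarization: c(u+v) - c(u) - c(v) equals the
        cross terms, not zero)."""
        shape = (5, 5, 5, 6, 3)
        u = rng.standard_normal(shape)
        w = rng.standard_normal(shape)
        a, b = 2.0, -0.5
        combo = _field(a * u + b * w)
        fu, fw = _field(u), _field(w)
        assert np.allclose(
            time_derivative(combo), a * time_derivative(fu) + b * time_derivative(fw)
        )
        fl = FluidProperties()
        assert np.allclose(
            viscous_term(combo, fl), a * viscous_term(fu, fl) + b * viscous_term(fw, fl)
        )
        cross = (
            convective_term(_field(u + w))
            - convective_term(fu)
            - convective_term(fw)
        )
        assert not np.allclose(cross, 0)


class TestRotation:
    def test_rigid_rotation_curl_is_2omega(self):
        """curl(omega x r) = 2*omega on interior voxels, to 1e-10."""
        omega = np.array([0.3, -0.2, 1.0])
        vf = rigid_rotation_velocity(omega, grid_shape=(10, 10, 10), voxel_size=1.0)
        rot = rotation(vf)
        vals = rot.values[rot.valid]
        assert np.max(np.abs(vals - 2 * omega)) < 1e-10

    def test_curl_of_gradient_vanishes(self, rng):
        """Discrete curl of a discrete gradient field is zero to rounding
        (the difference operators commute)."""
        from scipy.ndimage import gaussian_filter

        phi = gaussian_filter(rng.standard_normal((14, 14, 14)), 2.0)
        h = 1.0
        g = np.stack([_cdiff(phi, j, h * 1e-3) for j in range(3)], axis=-1)
        v = np.repeat(g[..., None, :], 4, axis=3) * 100.0  # to cm/s
        vf = _field(v, voxel_size=h)
        rot = rotation(vf)
        scale = np.abs(g).max() / (h * 1e-3)
        assert np.abs(rot.values[rot.valid]).max() <= 1e-12 * scale

    def test_uniform_field_has_zero_curl(self):
        v = np.ones((5, 5, 5, 3, 3))
        rot = rotation(_field(v))
        assert np.all(rot.values[rot.valid] == 0)


class TestConvergence:
    def test_womersley_error_decreases_second_order(self):
        """log-log slope of the core-region pressure-gradient error vs voxel
        size lies in [1.7, 2.3] over three refinements."""
        hs = [0.8, 0.4, 0.2]
        grids = [(16, 16, 6), (28, 28, 6), (52, 52, 6)]
        errs = []
        for h, gs in zip(hs, grids):
            spec = WomersleyPhantomSpec(
                tube_radius=2.0, heart_rate=60.0, n_cardiac_phases=128,
                voxel_size=h, grid_shape=gs, pressure_gradient_amplitude=100.0,
            )
            vf, truth = womersley_velocity(spec)
            gp, _ = pressure_gradient(vf)
            r = _transverse_radius(2, gs, h)
            core = gp.valid & (r < spec.tube_radius / 2)
            rec = gp.values[core][:, :, 2].mean(axis=0)
            errs.append(np.max(np.abs(rec - truth)) / 100.0)
        slope = np.polyfit(np.log(hs), np.log(errs), 1)[0]
        assert 1.7 <= slope <= 2.3
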
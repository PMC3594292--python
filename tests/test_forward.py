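import dataclasses
import math

import numpy as np
import pytest

from talbotct.forward import (
    AcquisitionConfig,
    TruncationError,
    project,
    simulate_stepping,
    stepping_phase,
)
from talbotct.optics import ShiftType, talbot_lau_geometry, wavelength
from talbotct.phantom import build_phantom, tissue_table


class TestProject:
    def test_cylinder_center_ray_chord_oracle(self, cylinder_phantom):
        ph = cylinder_phantom
        proj = project(ph, 4)
        r_cm = ph.features["cylinder"]["radius_px"] * ph.pixel_size_um * 1e-4
        mu = 0.62
        center = proj.att_sino.shape[1] // 2
        assert proj.att_sino[0, center] == pytest.approx(2 * r_cm * mu, rel=0.01)

    def test_empty_phantom_projects_to_zero(self):
        table = tissue_table(23.0, {"soft_tissue": {"delta": 0.0, "mu": 0.0}})
        ph = build_phantom(128, scene="cylinder", seed=0, tissues=table)
        proj = project(ph, 8)
        assert np.allclose(proj.att_sino, 0)
        assert np.allclose(proj.phase_sino, 0)
        assert np.allclose(proj.vis_sino, 1)

    def test_quarter_turn_permutes_angle_axis(self):
        # odd grid size so the quarter-turn maps the sample lattice onto
        # itself and the relation is exact: angles span [0, 180), so a 90
        # degree phantom rotation shifts the angle index by N/2, with the
        # wrapped half re-entering mirrored along the detector
        ph = build_phantom(129, scene="bone_streak", seed=3)
        n_ang = 16
        a = project(ph, n_ang).att_sino
        ph_rot = dataclasses.replace(
            ph,
            mu_map=np.ascontiguousarray(np.rot90(ph.mu_map)),
            delta_map=np.ascontiguousarray(np.rot90(ph.delta_map)),
            scatter_map=np.ascontiguousarray(np.rot90(ph.scatter_map)),
            labels=np.ascontiguousarray(np.rot90(ph.labels)),
        )
        b = project(ph_rot, n_ang).att_sino
        half = n_ang // 2
        for j in range(n_ang):
            expected = a[j - half] if j >= half else a[j + half][::-1]
            assert np.allclose(b[j], expected, atol=1e-9)

    def test_narrow_detector_rejected(self, cylinder_phantom):
        with pytest.raises(TruncationError):
            project(cylinder_phantom, 4, n_detector_pixels=100)

    def test_wide_detector_pads_symmetrically(self, cylinder_phantom):
        proj = project(cylinder_phantom, 2, n_detector_pixels=500)
        assert proj.att_sino.shape == (2, 500)
        assert proj.att_sino[:, :40].max() == 0.0
        assert proj.vis_sino[:, :40].min() == 1.0


class TestSteppingPhase:
    def test_uniform_slab_interior_is_zero(self, design):
        phase = np.ones((3, 50)) * 7.0
        phi = stepping_phase(phase, design, 30.0)
        assert np.allclose(phi[:, 1:-1], 0.0)

    def test_linearity_in_intergrating_distance(self):
        d1 = talbot_lau_geometry(math.inf, 3.51, 23.0, 1, ShiftType.PI_HALF)
        d3 = talbot_lau_geometry(math.inf, 3.51, 23.0, 3, ShiftType.PI_HALF)
        phase = np.random.default_rng(0).normal(size=(4, 64))
        assert np.allclose(
            stepping_phase(phase, d3, 30.0), 3 * stepping_phase(phase, d1, 30.0)
        )

    def test_cylinder_edge_matches_chord_derivative(self, design):
        # phi along one projection vs the closed-form derivative of the
        # chord profile of a disc, compared inside |x| < 0.9 r
        ph = build_phantom(512, pixel_size_um=30.0, scene="cylinder", seed=2)
        r = ph.features["cylinder"]["radius_px"]
        delta = ph.delta_map.max()
        proj = project(ph, 1)
        phi = stepping_phase(proj.phase_sino, design, ph.pixel_size_um)[0]
        n = phi.size
        x = np.arange(n) - n // 2
        lam_um = wavelength(23.0) * 1e-4
        with np.errstate(invalid="ignore"):
            dchord = np.where(
                np.abs(x) < r, -2 * x / np.sqrt(np.maximum(r * r - x * x, 1e-12)), 0.0
            )
        phi_true = design.phase_sensitivity_um() * (2 * np.pi / lam_um) * delta * dchord
        sel = np.abs(x) < 0.85 * r
        peak = np.abs(phi_true[sel]).max()
        assert np.abs(phi[sel] - phi_true[sel]).max() < 0.05 * peak

    def test_wrap_warning_emitted(self, design):
        steep = np.zeros((1, 32))
        steep[0, 16:] = 10.0  # huge jump in Phi
        with pytest.warns(RuntimeWarning, match="wraps"):
            stepping_phase(steep, design, 1.0)


class TestSimulateStepping:
    def test_noiseless_unit_transmission_equals_flat(self, design):
        att = np.zeros((5, 40))
        phi = np.zeros_like(att)
        cfg = AcquisitionConfig(n_projections=5, n_steps=4, design=design, noiseless=True)
        scan = simulate_stepping(att, phi, cfg)
        for j in range(5):
            assert np.allclose(scan.sample_intensities[:, j, :], scan.flat_intensities)

    def test_step_mean_is_flux_times_transmission(self, design):
        rng = np.random.default_rng(1)
        att = rng.uniform(0, 1, size=(4, 30))
        phi = rng.uniform(-2, 2, size=(4, 30))
        cfg = AcquisitionConfig(n_projections=4, n_steps=7, design=design, noiseless=True)
        scan = simulate_stepping(att, phi, cfg)
        assert np.allclose(
            scan.sample_intensities.mean(axis=0), cfg.flux * np.exp(-att)
        )

    def test_poisson_variance_matches_mean(self, design):
        att = np.zeros((250, 400))
        phi = np.zeros_like(att)
        cfg = AcquisitionConfig(
            n_projections=250, n_steps=3, flux=1e4, design=design, seed=5
        )
        scan = simulate_stepping(att, phi, cfg)
        step0 = scan.sample_intensities[0]  # 1e5 iid Poisson samples
        assert step0.var() == pytest.approx(step0.mean(), rel=0.05)

    def test_deterministic_under_seed(self, design):
        att = np.zeros((3, 20))
        phi = np.zeros_like(att)
        cfg = AcquisitionConfig(n_projections=3, n_steps=4, design=design, seed=11)
        a = simulate_stepping(att, phi, cfg)
        b = simulate_stepping(att, phi, cfg)
        assert np.array_equal(a.sample_intensities, b.sample_intensities)
        assert np.array_equal(a.flat_intensities, b.flat_intensities)

    def test_too_few_steps_rejected(self, design):
        with pytest.raises(ValueError):
            AcquisitionConfig(n_projections=3, n_steps=2, design=design)
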
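import numpy as np
import pytest
import scipy.ndimage as ndi
from skimage.transform import iradon

from talbotct.forward import AcquisitionConfig, acquire, simulate_stepping
from talbotct.phantom import Tissue, build_phantom
from talbotct.recon import (
    RetrievalError,
    SinogramSet,
    fbp_attenuation,
    fbp_phase,
    reconstruct,
    retrieve,
    sharpen,
    stepping_visibility,
    visibility_weighting,
    _apply_filter,
    _backproject,
)


def _uniform_scan(design, n_ang=6, n_det=40, K=4, flux=1e4, **kw):
    att = np.zeros((n_ang, n_det))
    phi = np.zeros_like(att)
    cfg = AcquisitionConfig(
        n_projections=n_ang, n_steps=K, flux=flux, design=design, **kw
    )
    return simulate_stepping(att, phi, cfg)


class TestRetrieve:
    @pytest.mark.parametrize("K", [3, 4, 10])
    def test_noiseless_round_trip_machine_precision(self, design, K):
        rng = np.random.default_rng(K)
        att = rng.uniform(0, 1.5, size=(8, 50))
        phi = rng.uniform(-2.5, 2.5, size=(8, 50))
        cfg = AcquisitionConfig(
            n_projections=8, n_steps=K, design=design, noiseless=True
        )
        scan = simulate_stepping(att, phi, cfg)
        s = retrieve(scan)
        assert np.allclose(s.transmission, np.exp(-att), atol=1e-12)
        assert np.allclose(s.dphase, phi, atol=1e-10)
        assert np.allclose(s.rel_visibility, 1.0, atol=1e-10)

    def test_sample_equal_flat_gives_identity_sinograms(self, design):
        scan = _uniform_scan(design, noiseless=True)
        s = retrieve(scan)
        assert np.allclose(s.transmission, 1.0)
        assert np.allclose(s.dphase, 0.0)
        assert np.allclose(s.rel_visibility, 1.0)

    def test_flat_stepping_curve_has_design_visibility_exactly(self, design):
        scan = _uniform_scan(design, noiseless=True)
        v = stepping_visibility(scan.flat_intensities)
        assert np.allclose(v, design.design_visibility, atol=1e-12)

    def test_phase_noise_scales_with_inverse_sqrt_flux(self, design):
        # wide uniform field; total phi noise (sample + shared flat
        # components) must drop by sqrt(2) when the flux doubles
        stds = []
        for flux in (1e4, 2e4):
            scan = _uniform_scan(design, n_ang=200, n_det=400, flux=flux, seed=21)
            stds.append(retrieve(scan).dphase.std())
        assert stds[0] / stds[1] == pytest.approx(np.sqrt(2), rel=0.10)

    def test_transmission_clipping_counted(self, design):
        scan = _uniform_scan(design, noiseless=True)
        scan.sample_intensities *= 2.0  # sample brighter than flat: T = 2
        s = retrieve(scan)
        assert s.meta["n_transmission_clipped"] == s.transmission.size
        assert s.transmission.max() <= 1.5

    def test_zero_flat_rejected(self, design):
        scan = _uniform_scan(design, noiseless=True)
        scan.flat_intensities[:] = 0.0
        with pytest.raises(RetrievalError):
            retrieve(scan)


class TestFbpAttenuation:
    def test_cylinder_parameter_recovery(self, cylinder_phantom, cylinder_sinos):
        ph = cylinder_phantom
        mu_map = fbp_attenuation(cylinder_sinos, output_size=ph.size)
        disc = ndi.binary_erosion(ph.labels == int(Tissue.SOFT_TISSUE), iterations=3)
        outside = ~ndi.binary_dilation(ph.labels > 0, iterations=5)
        assert mu_map[disc].mean() == pytest.approx(0.62, rel=0.02)
        assert abs(mu_map[outside].mean()) < 0.02 * 0.62

    def test_matches_independent_fbp_implementation(self, cylinder_phantom, cylinder_sinos):
        # cross-check against the scikit-image ramp-filter FBP
        ph = cylinder_phantom
        mine = fbp_attenuation(cylinder_sinos, output_size=ph.size)
        px_cm = ph.pixel_size_um * 1e-4
        ref = (
            iradon(
                -np.log(cylinder_sinos.transmission).T,
                theta=cylinder_sinos.angles_deg,
                filter_name="ramp",
                circle=False,
                output_size=ph.size,
            )
            / px_cm
        )
        disc = ndi.binary_erosion(ph.labels == int(Tissue.SOFT_TISSUE), iterations=3)
        assert mine[disc].mean() == pytest.approx(ref[disc].mean(), rel=0.01)
        rms = np.sqrt(np.mean((mine[disc] - ref[disc]) ** 2))
        assert rms < 0.02 * 0.62

    def test_zero_sinogram_reconstructs_to_zero(self, design):
        s = SinogramSet(
            transmission=np.ones((12, 64)),
            dphase=np.zeros((12, 64)),
            rel_visibility=np.ones((12, 64)),
            angles_deg=np.arange(12) * 15.0,
            detector_pitch_um=30.0,
            design=design,
        )
        assert np.allclose(fbp_attenuation(s, output_size=32), 0.0)

    def test_linearity(self, cylinder_sinos):
        a = fbp_attenuation(cylinder_sinos, output_size=64)
        doubled = SinogramSet(
            transmission=cylinder_sinos.transmission**2,
            dphase=cylinder_sinos.dphase,
            rel_visibility=cylinder_sinos.rel_visibility,
            angles_deg=cylinder_sinos.angles_deg,
            detector_pitch_um=cylinder_sinos.detector_pitch_um,
            design=cylinder_sinos.design,
        )
        b = fbp_attenuation(doubled, output_size=64)
        assert np.allclose(b, 2 * a, atol=1e-9)

    def test_nonpositive_transmission_rejected(self, cylinder_sinos, design):
        s = SinogramSet(
            transmission=np.zeros((4, 16)),
            dphase=np.zeros((4, 16)),
            rel_visibility=np.ones((4, 16)),
            angles_deg=np.arange(4) * 45.0,
            detector_pitch_um=30.0,
            design=design,
        )
        with pytest.raises(ValueError):
            fbp_attenuation(s)


class TestFbpPhase:
    def test_cylinder_parameter_recovery(self, cylinder_phantom, cylinder_sinos):
        ph = cylinder_phantom
        delta = fbp_phase(cylinder_sinos, output_size=ph.size)
        disc = ndi.binary_erosion(ph.labels == int(Tissue.SOFT_TISSUE), iterations=3)
        assert delta[disc].mean() == pytest.approx(1.40e-7, rel=0.02)

    def test_hilbert_agrees_with_integrate_then_ramp_oracle(
        self, cylinder_phantom, cylinder_sinos
    ):
        # brute-force route: cumulative-sum the differential phase into the
        # delta line integral, then ordinary ramp FBP
        ph, s = cylinder_phantom, cylinder_sinos
        delta_h = fbp_phase(s, output_size=ph.size)
        d = s.design
        g = s.dphase * d.p2_um / (2 * np.pi * d.d_mm * 1e3)
        p = np.cumsum(g, axis=1) * s.detector_pitch_um
        q = _apply_filter(p, s.detector_pitch_um, "ramp")
        delta_r = _backproject(q, s.angles_deg, ph.size)
        support = ndi.binary_erosion(ph.labels > 0, iterations=2)
        rms = np.sqrt(np.mean((delta_h[support] - delta_r[support]) ** 2))
        assert rms < 0.01 * 1.40e-7

    def test_zero_phase_gives_zero_delta(self, design):
        s = SinogramSet(
            transmission=np.ones((12, 64)),
            dphase=np.zeros((12, 64)),
            rel_visibility=np.ones((12, 64)),
            angles_deg=np.arange(12) * 15.0,
            detector_pitch_um=30.0,
            design=design,
        )
        assert np.allclose(fbp_phase(s, output_size=32), 0.0)

    def test_missing_design_rejected(self):
        s = SinogramSet(
            transmission=np.ones((4, 16)),
            dphase=np.zeros((4, 16)),
            rel_visibility=np.ones((4, 16)),
            angles_deg=np.arange(4) * 45.0,
            detector_pitch_um=30.0,
            design=None,
        )
        with pytest.raises(ValueError):
            fbp_phase(s)


class TestVisibilityWeighting:
    def test_unit_visibility_is_identity(self):
        phi = np.random.default_rng(0).normal(size=(5, 9))
        assert np.array_equal(visibility_weighting(phi, np.ones_like(phi)), phi)

    def test_zero_visibility_ray_contributes_nothing(self):
        phi = np.ones((4, 8))
        v = np.ones_like(phi)
        v[2] = 0.0
        out = visibility_weighting(phi, v)
        assert np.allclose(out[2], 0.0)
        assert np.allclose(out[[0, 1, 3]], 1.0)

    def test_weights_clipped_to_one(self):
        phi = np.ones((2, 3))
        v = np.full_like(phi, 1.3)  # noisy visibility above the flat level
        assert np.allclose(visibility_weighting(phi, v), phi)

    def test_streak_suppression_in_low_dose_scan(self):
        # paired simulation, one seed: squared-visibility weighting must
        # strictly lower the delta std in an off-bone soft-tissue region
        ph = build_phantom(256, pixel_size_um=30.0, scene="bone_streak", seed=5)
        cfg = AcquisitionConfig(n_projections=301, n_steps=4, flux=1e3, seed=5)
        s = retrieve(acquire(ph, cfg))
        d_plain = fbp_phase(s, output_size=ph.size)
        d_weighted = fbp_phase(s, output_size=ph.size, weight_visibility=True)
        soft = ph.labels == int(Tissue.SOFT_TISSUE)
        bx, by = ph.features["bone"]["center_px"]
        Y, X = np.ogrid[: ph.size, : ph.size]
        c = ph.size // 2
        far = (X - c - bx) ** 2 + (Y - c - by) ** 2 > (0.12 * ph.size) ** 2
        roi = ndi.binary_erosion(soft & far, iterations=3)
        assert d_weighted[roi].std() < d_plain[roi].std()


class TestSharpen:
    def test_zero_amount_is_identity(self):
        img = np.random.default_rng(1).normal(size=(20, 20))
        assert np.array_equal(sharpen(img, amount=0.0), img)

    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 3.5)
        assert np.allclose(sharpen(img, amount=2.0, radius=1.5), img)

    def test_interior_mean_preserved(self):
        img = np.random.default_rng(2).normal(loc=5.0, size=(64, 64))
        out = sharpen(img, amount=1.0, radius=1.0)
        assert out[8:-8, 8:-8].mean() == pytest.approx(
            img[8:-8, 8:-8].mean(), rel=1e-3
        )


class TestReconstruct:
    def test_maps_registered_and_provenance_recorded(self, cylinder_sinos):
        rec = reconstruct(cylinder_sinos, output_size=64, sharpen_amount=1.0)
        assert rec.mu_map.shape == rec.delta_map.shape
        assert rec.provenance["registered"] is True
        assert rec.provenance["sharpen_amount"] == 1.0
        assert "seed" in rec.provenance

    def test_reconstruction_noise_scales_with_inverse_sqrt_flux(self):
        # two-point check: quadrupled flux halves the mu-map noise
        ph = build_phantom(128, pixel_size_um=30.0, scene="cylinder", seed=3)
        mask = ndi.binary_erosion(ph.labels == int(Tissue.SOFT_TISSUE), iterations=4)
        stds = []
        for flux in (1e4, 4e4):
            cfg = AcquisitionConfig(n_projections=180, n_steps=4, flux=flux, seed=12)
            s = retrieve(acquire(ph, cfg))
            stds.append(fbp_attenuation(s, output_size=ph.size)[mask].std())
        assert stds[0] / stds[1] == pytest.approx(2.0, rel=0.15)
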
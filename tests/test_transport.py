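"""Monte Carlo transport: elementary kernels, conservation, scaling laws."""

import math

import numpy as np
import pytest
from scipy import stats

from nirpdt.optics import OpticalProperties, OpticsTable, assign_optics
from nirpdt.phantom import LabeledVolume, TissueLabel
from nirpdt.transport import (
    BeamSpec,
    fresnel_reflectance,
    hg_cdf,
    run_transport,
    sample_free_path,
    sample_hg_cosine,
)


class TestFreePath:
    def test_closed_form(self):
        assert sample_free_path(1.0, 0.5) == pytest.approx(math.log(2))

    def test_mean_is_inverse_mu_t(self):
        # fat total attenuation mu_t = 0.09 + 108 = 108.09 cm^-1
        rng = np.random.default_rng(11)
        mu_t = 108.09
        draws = np.array([sample_free_path(mu_t, u)
                          for u in rng.random(100_000)])
        se = (1 / mu_t) / math.sqrt(draws.size)
        assert abs(draws.mean() - 1 / mu_t) < 3 * se

    def test_nonpositive_mu_rejected(self):
        with pytest.raises(ValueError):
            sample_free_path(0.0, 0.5)


class TestHenyeyGreenstein:
    def test_isotropic_mean_zero(self):
        rng = np.random.default_rng(1)
        c = np.array([sample_hg_cosine(0.0, u) for u in rng.random(50_000)])
        assert abs(c.mean()) < 3 * c.std() / math.sqrt(c.size)

    def test_first_moment_equals_g(self):
        rng = np.random.default_rng(2)
        g = 0.9
        c = np.array([sample_hg_cosine(g, u) for u in rng.random(50_000)])
        assert abs(c.mean() - g) < 3 * c.std() / math.sqrt(c.size)

    def test_empirical_cdf_matches_analytic(self):
        rng = np.random.default_rng(3)
        g = 0.9
        c = np.array([sample_hg_cosine(g, u) for u in rng.random(20_000)])
        res = stats.kstest(c, lambda x: hg_cdf(x, g))
        assert res.pvalue > 0.01

    def test_invalid_g_rejected(self):
        with pytest.raises(ValueError):
            sample_hg_cosine(1.5, 0.5)


class TestFresnel:
    def test_matched_indices_reflect_nothing(self):
        assert fresnel_reflectance(1.4, 1.4, 0.7) == 0.0

    def test_normal_incidence_closed_form(self):
        expected = ((1.37 - 1.0) / (1.37 + 1.0)) ** 2  # ~0.0244
        assert fresnel_reflectance(1.0, 1.37, 1.0) == pytest.approx(expected)

    def test_total_internal_reflection(self):
        # 1.45 -> 1.0 beyond the critical angle (~43.6 deg)
        assert fresnel_reflectance(1.45, 1.0, 0.3) == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fresnel_reflectance(0.5, 1.0, 1.0)
        with pytest.raises(ValueError):
            fresnel_reflectance(1.0, 1.4, 0.0)


class TestTransportRuns:
    def test_beer_lambert_decay_scatter_free(self, scatterfree_fat_optvol):
        fv = run_transport(scatterfree_fat_optvol, BeamSpec(),
                           n_photons=100_000, seed=1, internal_fresnel=False)
        prof = fv.phi[10, 10, :]
        for k in (10, 30, 50):
            expected = math.exp(-0.09 * k * 0.33 / 10.0)
            assert prof[k] / prof[0] == pytest.approx(expected, rel=0.01)

    def test_conservation_ledger(self, fat_optvol):
        fv = run_transport(fat_optvol, BeamSpec(), n_photons=20_000, seed=2)
        assert fv.conservation_error() < 1e-6
        assert np.all(fv.phi >= 0)

    def test_fluence_linear_in_irradiance(self, fat_optvol):
        f1 = run_transport(fat_optvol, BeamSpec(irradiance_mW_cm2=330.0),
                           n_photons=5_000, seed=3)
        f2 = run_transport(fat_optvol, BeamSpec(irradiance_mW_cm2=660.0),
                           n_photons=5_000, seed=3)
        np.testing.assert_allclose(f2.phi, 2.0 * f1.phi, rtol=1e-12)

    def test_all_air_phantom_transmits_everything(self):
        vol = LabeledVolume(np.zeros((10, 10, 10), dtype=np.uint8), 0.33)
        fv = run_transport(assign_optics(vol), BeamSpec(), n_photons=2_000, seed=4)
        assert fv.ledger["transmitted"] == pytest.approx(1.0)
        assert fv.phi.max() == 0.0

    def test_zero_absorption_roulette_terminates(self):
        # open boundaries absorb escaping packets; the run must finish
        table = OpticsTable()
        table.properties[TissueLabel.FAT] = OpticalProperties(0.0, 50.0, 1.45, 0.9)
        labels = np.full((20, 20, 20), int(TissueLabel.FAT), dtype=np.uint8)
        fv = run_transport(assign_optics(LabeledVolume(labels, 0.33), table),
                           BeamSpec(), n_photons=2_000, seed=5)
        assert fv.ledger["absorbed"] == pytest.approx(0.0, abs=1e-12)
        assert fv.conservation_error() < 1e-6

    def test_depth_profile_monotone_beyond_backscatter_peak(self):
        labels = np.full((40, 40, 60), int(TissueLabel.FAT), dtype=np.uint8)
        fv = run_transport(assign_optics(LabeledVolume(labels, 0.33)),
                           BeamSpec(), n_photons=50_000, seed=6)
        means = fv.phi.mean(axis=(0, 1))
        peak = int(np.argmax(means))
        assert peak < 15  # sub-surface backscatter peak is shallow
        smoothed = np.convolve(means, np.ones(5) / 5, mode="valid")
        tail = smoothed[max(peak, 2):]
        assert np.all(np.diff(tail) <= 0.02 * tail[:-1])

    def test_lateral_mirror_symmetry(self):
        # half-fat / half-duct medium mirrored along x gives mirrored fluence
        labels = np.full((40, 40, 40), int(TissueLabel.FAT), dtype=np.uint8)
        labels[:20, :, :] = int(TissueLabel.DUCT)
        vol = LabeledVolume(labels, 0.33)
        mirrored = LabeledVolume(labels[::-1, :, :].copy(), 0.33)
        f1 = run_transport(assign_optics(vol), BeamSpec(), n_photons=40_000, seed=7)
        f2 = run_transport(assign_optics(mirrored), BeamSpec(),
                           n_photons=40_000, seed=8)
        # coarse-grain to suppress Monte Carlo noise before comparing
        def coarse(phi):
            return phi.reshape(8, 5, 8, 5, 8, 5).mean(axis=(1, 3, 5))
        a = coarse(f1.phi)
        b = coarse(f2.phi[::-1, :, :])
        mask = a > 0.05 * a.max()
        rel = np.abs(a[mask] - b[mask]) / a[mask]
        assert np.median(rel) < 0.10

    def test_sampling_error_scales_inverse_sqrt(self):
        labels = np.full((24, 24, 24), int(TissueLabel.FAT), dtype=np.uint8)
        ov = assign_optics(LabeledVolume(labels, 0.33))
        mask = np.zeros(labels.shape, dtype=bool)
        mask[8:16, 8:16, 8:16] = True

        def means(n, seeds):
            return [run_transport(ov, BeamSpec(), n_photons=n,
                                  seed=s).phi[mask].mean() for s in seeds]

        lo = np.std(means(2_000, range(100, 140)), ddof=1)
        hi = np.std(means(4_000, range(300, 340)), ddof=1)
        assert 1.15 < lo / hi < 1.75  # ~sqrt(2) with 40 replicates of slack

    def test_determinism_same_seed(self, fat_optvol):
        f1 = run_transport(fat_optvol, BeamSpec(), n_photons=3_000, seed=9)
        f2 = run_transport(fat_optvol, BeamSpec(), n_photons=3_000, seed=9)
        np.testing.assert_array_equal(f1.phi, f2.phi)

    def test_invalid_inputs_rejected(self, fat_optvol):
        with pytest.raises(ValueError):
            run_transport(fat_optvol, BeamSpec(), n_photons=0)
        with pytest.raises(ValueError):
            run_transport(fat_optvol,
                          BeamSpec(field=("disc", (2.0, 2.0, 50.0))),
                          n_photons=100)

    def test_disc_and_rect_fields(self, fat_optvol):
        lx = 40 * 0.33
        fd = run_transport(fat_optvol,
                           BeamSpec(field=("disc", (lx / 2, lx / 2, 3.0))),
                           n_photons=5_000, seed=10)
        fr = run_transport(fat_optvol,
                           BeamSpec(field=("rect", (2.0, 8.0, 2.0, 8.0))),
                           n_photons=5_000, seed=10)
        for f in (fd, fr):
            assert f.conservation_error() < 1e-6
            assert f.phi.sum() > 0


class TestAssignOptics:
    def test_default_table_rows(self):
        labels = np.array([[[int(TissueLabel.SKIN), int(TissueLabel.TUMOR)]]],
                          dtype=np.uint8)
        ov = assign_optics(LabeledVolume(labels, 0.33))
        assert ov.mu_a[int(TissueLabel.SKIN)] == pytest.approx(1.35)
        assert ov.mu_s[int(TissueLabel.SKIN)] == pytest.approx(196.0)
        assert ov.n[int(TissueLabel.SKIN)] == pytest.approx(1.37)
        assert ov.g[int(TissueLabel.SKIN)] == pytest.approx(0.9)
        # tumor absorption = 0.10 tissue baseline + 0.38 nanoparticle loading
        assert ov.mu_a[int(TissueLabel.TUMOR)] == pytest.approx(0.48)

    def test_air_is_transparent(self):
        labels = np.zeros((2, 2, 2), dtype=np.uint8)
        ov = assign_optics(LabeledVolume(labels, 0.33))
        assert ov.mu_a[0] == 0.0 and ov.mu_s[0] == 0.0 and ov.n[0] == 1.0

    def test_unmapped_label_rejected(self):
        labels = np.full((2, 2, 2), int(TissueLabel.TUMOR), dtype=np.uint8)
        table = OpticsTable()
        del table.properties[TissueLabel.TUMOR]
        with pytest.raises(ValueError, match="no optical properties"):
            assign_optics(LabeledVolume(labels, 0.33), table)
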
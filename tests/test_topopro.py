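"""Two-level TopoPro fitting: penalty, Level-1/2, whole-volume driver."""

import numpy as np
import pytest

from topoivim.ivim import (
    AcquisitionScheme,
    ConfigurationError,
    IVIMParams,
    VoxelSignal,
    full_residual,
    ivim_signal,
)
from topoivim.phantom import ivim_bvalues
from topoivim.topopro import (
    FLAG_BAD_S0,
    FLAG_CLIPPED,
    TopoProConfig,
    fit_volume,
    fit_voxel,
    fit_voxel_level1,
    fit_voxel_level2,
    normalize_signal,
    penalty,
    physical_form,
)


@pytest.fixture(scope="module")
def config():
    return TopoProConfig()


class TestPenalty:
    def test_formula_values(self):
        cfg = TopoProConfig(penalty_weight=1.0)
        assert penalty(IVIMParams(f=0.1, D=0.001, Dstar=0.05), cfg) == pytest.approx(0.0025)
        assert penalty(IVIMParams(f=0.3, D=0.001, Dstar=0.05), cfg) == 0.0
        assert penalty(IVIMParams(f=0.2, D=0.001, Dstar=0.0), cfg) == 0.0

    def test_threshold_boundary_inclusive(self):
        cfg = TopoProConfig(penalty_weight=2.0)
        assert penalty(IVIMParams(f=0.2, D=0.001, Dstar=0.1), cfg) == pytest.approx(0.02)


class TestPhysicalForm:
    def test_majority_perfusion_swapped(self):
        p = physical_form(IVIMParams(f=0.7, D=0.001, Dstar=0.04))
        assert (p.f, p.D, p.Dstar) == (pytest.approx(0.3), 0.04, 0.001)

    def test_minority_kept(self):
        p = IVIMParams(f=0.3, D=0.001, Dstar=0.04)
        assert physical_form(p) is p

    def test_axis_maps_to_zero_fraction(self, scheme54):
        p = physical_form(IVIMParams(f=0.42, D=0.003, Dstar=0.003))
        assert p.f == 0.0
        np.testing.assert_allclose(
            ivim_signal(p, scheme54),
            ivim_signal(IVIMParams(f=0.42, D=0.003, Dstar=0.003), scheme54))

    def test_signal_preserved_off_axis(self, scheme54):
        rng = np.random.default_rng(0)
        n = 0
        while n < 30:
            D = float(rng.uniform(1e-4, 0.02))
            Dstar = float(rng.uniform(1e-4, 0.2))
            if abs(Dstar - D) <= 0.05 * max(D, Dstar):
                continue  # near-axis points are deliberately collapsed to f = 0
            p = IVIMParams(f=float(rng.uniform(0, 1)), D=D, Dstar=Dstar)
            np.testing.assert_allclose(ivim_signal(physical_form(p), scheme54),
                                       ivim_signal(p, scheme54), rtol=1e-12)
            n += 1


class TestNormalize:
    def test_scaling(self):
        scheme = AcquisitionScheme([0.0, 1000.0])
        y, flags = normalize_signal([100.0, 36.79], scheme)
        np.testing.assert_allclose(y.y, [1.0, 0.3679])
        assert flags == 0

    def test_mean_of_b0s(self):
        scheme = AcquisitionScheme([0.0, 0.0, 500.0])
        y, _ = normalize_signal([100.0, 102.0, 50.0], scheme)
        assert y.y[0] == pytest.approx(100.0 / 101.0)

    def test_clipping_flagged(self):
        scheme = AcquisitionScheme([0.0, 1000.0])
        y, flags = normalize_signal([100.0, -2.0], scheme)
        np.testing.assert_allclose(y.y, [1.0, 0.0])
        assert flags & FLAG_CLIPPED

    def test_bad_s0_flagged(self):
        scheme = AcquisitionScheme([0.0, 1000.0])
        y, flags = normalize_signal([-5.0, 10.0], scheme)
        assert flags & FLAG_BAD_S0
        assert np.all(y.y == 0)


class TestLevel1:
    def test_noiseless_recovery(self, config, noiseless_voxel):
        truth, y = noiseless_voxel
        res = fit_voxel_level1(y, config, seed=0)
        assert res.s_hat[0] == pytest.approx(truth.D, rel=1e-3)
        assert res.s_hat[1] == pytest.approx(truth.Dstar, rel=1e-3)
        assert res.f_hat == pytest.approx(truth.f, abs=1e-3)

    def test_pure_diffusion_limit(self, config, scheme54):
        y = VoxelSignal(ivim_signal(IVIMParams(f=0, D=0.0015, Dstar=0.05), scheme54),
                        scheme54)
        res = fit_voxel_level1(y, config, seed=1)
        assert res.f_hat < 0.02
        # the diffusion rate appears in one of the two fitted rates
        assert min(abs(res.s_hat[0] - 0.0015), abs(res.s_hat[1] - 0.0015)) < 0.0015 * 0.01

    def test_bimodal_voxel_yields_multiple_minima(self, config, scheme54):
        truth = IVIMParams(f=0.349, D=0.005, Dstar=0.04)
        y = VoxelSignal(ivim_signal(truth, scheme54), scheme54)
        res = fit_voxel_level1(y, config, seed=2)
        assert len(res.minima) >= 2

    def test_unnormalized_signal_rejected(self, config, scheme54):
        y = VoxelSignal(2.0 * np.ones(scheme54.m), scheme54)
        with pytest.raises(ConfigurationError):
            fit_voxel_level1(y, config)


class TestLevel2:
    def test_refinement_never_worse(self, config, noiseless_voxel):
        truth, y = noiseless_voxel
        lvl1 = fit_voxel_level1(y, config, seed=3)
        res = fit_voxel_level2(y, (lvl1.f_hat, lvl1.s_hat), config, seed=4)
        assert res.residual <= lvl1.reduced_value + 1e-12

    def test_fixed_point_at_truth(self, config, noiseless_voxel):
        truth, y = noiseless_voxel
        res = fit_voxel_level2(y, (truth.f, (truth.D, truth.Dstar)), config, seed=5)
        assert res.params.f == pytest.approx(truth.f, abs=1e-6)
        assert res.params.D == pytest.approx(truth.D, rel=1e-4)
        assert res.params.Dstar == pytest.approx(truth.Dstar, rel=1e-4)
        assert res.residual < 1e-10

    def test_penalty_shrinks_dstar_in_low_perfusion_regime(self, scheme54):
        """Paired comparison: same noisy low-f voxel, penalty on vs off."""
        rng = np.random.default_rng(6)
        truth = IVIMParams(f=0.08, D=0.001, Dstar=0.05)
        raw = 100 * ivim_signal(truth, scheme54) + rng.normal(0, 8, scheme54.m)
        y, _ = normalize_signal(raw, scheme54)
        on = fit_voxel(y, TopoProConfig(), seed=7)
        off = fit_voxel(y, TopoProConfig(penalty_weight=0.0, penalty_scale=0.0), seed=7)
        assert on.params.Dstar < off.params.Dstar

    def test_penalty_inert_when_perfusion_clearly_above_threshold(self, scheme54):
        rng = np.random.default_rng(8)
        for i in range(5):
            truth = IVIMParams(f=float(rng.uniform(0.3, 0.5)), D=0.001,
                               Dstar=float(rng.uniform(0.02, 0.06)))
            raw = 100 * ivim_signal(truth, scheme54) + rng.normal(0, 1.0, scheme54.m)
            y, _ = normalize_signal(raw, scheme54)
            on = fit_voxel(y, TopoProConfig(), seed=100 + i)
            off = fit_voxel(y, TopoProConfig(penalty_weight=0.0, penalty_scale=0.0),
                            seed=100 + i)
            if on.params.f > 0.25 and off.params.f > 0.25:
                assert on.params.Dstar == pytest.approx(off.params.Dstar, rel=1e-6)


class TestFitVoxel:
    def test_noiseless_recovery_well_posed_regime(self, scheme54):
        """Sanity floor: < 0.5% relative error where the model is identifiable."""
        rng = np.random.default_rng(9)
        cfg = TopoProConfig()
        for i in range(10):
            truth = IVIMParams(f=float(rng.uniform(0.05, 0.5)),
                               D=float(rng.uniform(5e-4, 2e-3)), Dstar=0.0)
            truth = IVIMParams(f=truth.f, D=truth.D,
                               Dstar=truth.D * float(rng.uniform(5, 20)))
            y = VoxelSignal(ivim_signal(truth, scheme54), scheme54)
            fit = fit_voxel(y, cfg, seed=i)
            assert fit.params.f == pytest.approx(truth.f, rel=5e-3)
            assert fit.params.D == pytest.approx(truth.D, rel=5e-3)
            assert fit.params.Dstar == pytest.approx(truth.Dstar, rel=5e-3)

    def test_degenerate_cavity_voxel_pinned(self, scheme54):
        y = VoxelSignal(ivim_signal(IVIMParams(f=0, D=0.003, Dstar=0), scheme54),
                        scheme54)
        fit = fit_voxel(y, TopoProConfig(), seed=10)
        assert fit.params.f == pytest.approx(0.0, abs=1e-6)
        assert fit.params.D == pytest.approx(0.003, rel=1e-3)
        assert fit.params.Dstar < 0.005


class TestFitVolume:
    def _block(self, scheme):
        truth = IVIMParams(f=0.25, D=0.001, Dstar=0.02)
        sig = 100 * ivim_signal(truth, scheme)
        data = np.tile(sig, (4, 4, 1, 1))
        return truth, data

    def test_noiseless_block_recovery(self, scheme27):
        truth, data = self._block(scheme27)
        maps = fit_volume(data, scheme27, config=TopoProConfig(seed=0))
        np.testing.assert_allclose(maps.f, truth.f, atol=1e-3)
        np.testing.assert_allclose(maps.D, truth.D, rtol=1e-3)
        np.testing.assert_allclose(maps.Dstar, truth.Dstar, rtol=2e-3)

    def test_masked_voxels_zero(self, scheme27):
        truth, data = self._block(scheme27)
        mask = np.zeros((4, 4, 1), dtype=bool)
        mask[0, 0, 0] = True
        maps = fit_volume(data, scheme27, mask, TopoProConfig(seed=0))
        assert maps.f[0, 0, 0] > 0
        assert np.all(maps.f[~mask] == 0) and np.all(maps.Dstar[~mask] == 0)

    def test_deterministic(self, scheme27):
        rng = np.random.default_rng(11)
        truth, data = self._block(scheme27)
        data = data + rng.normal(0, 5, data.shape)
        m1 = fit_volume(data, scheme27, config=TopoProConfig(seed=42))
        m2 = fit_volume(data, scheme27, config=TopoProConfig(seed=42))
        np.testing.assert_array_equal(m1.f, m2.f)
        np.testing.assert_array_equal(m1.Dstar, m2.Dstar)

    def test_all_zero_voxel_flagged(self, scheme27):
        truth, data = self._block(scheme27)
        data[1, 1, 0, :] = 0.0
        mask = np.ones((4, 4, 1), dtype=bool)
        maps = fit_volume(data, scheme27, mask, TopoProConfig(seed=0))
        assert maps.flags[1, 1, 0] != 0
        assert maps.f[1, 1, 0] == 0.0

    def test_shape_validation(self, scheme27):
        with pytest.raises(ConfigurationError):
            fit_volume(np.zeros((4, 4, 27)), scheme27)
        with pytest.raises(ConfigurationError):
            fit_volume(np.zeros((4, 4, 1, 20)), scheme27)
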
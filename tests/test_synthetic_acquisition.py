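"""Generator contracts: projection geometry, component scaling, Poisson noise."""

import warnings

import numpy as np
import pytest

from petiq.phantom_geometry import (
    MATERIAL_AIR,
    MATERIAL_WATER,
    CylinderRegion,
    VoxelGrid,
    voxelize_region,
)
from petiq.pgf_sensitivity import compute_pgf, sensitivity_from_acquisition
from petiq.synthetic_acquisition import (
    F18,
    I124,
    AcquisitionConfig,
    EnergyWindow,
    SinogramSet,
    apply_poisson,
    attenuation_factors,
    expected_trues_sinogram,
    forward_project,
    prompt_gamma_component,
    randoms_component,
    scatter_component,
    simulate_countrates,
    simulate_sensitivity_acquisition,
)

CFG = AcquisitionConfig()
GRID2D = VoxelGrid.centered((64, 64, 1), (0.776, 0.776, 2.0))


def _disk(radius_mm: float, value: float = 1.0) -> np.ndarray:
    mask = voxelize_region(CylinderRegion((0, 0, 0), radius_mm, 2.0), GRID2D)
    return np.where(mask, value, 0.0)


class TestForwardProject:
    def test_zero_volume_zero_sinogram(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sino = forward_project(np.zeros(GRID2D.shape), GRID2D, CFG)
        assert not sino.any()

    def test_centered_point_source_peaks_centrally(self):
        vol = np.zeros(GRID2D.shape)
        vol[32, 32, 0] = 1.0
        sino = forward_project(vol, GRID2D, CFG)
        peaks = sino[:, :, 0].argmax(axis=1)
        assert np.all(np.abs(peaks - 32) <= 1)

    def test_uniform_disk_matches_chord_profile(self):
        # disk centered on the projector's rotation-center pixel; the oracle
        # is the analytic Radon of a disk, averaged over each radial bin
        r_mm, bw = 10.0, GRID2D.voxel_size[0]
        c = GRID2D.axis_coords(0)[32]
        mask = voxelize_region(CylinderRegion((c, c, 0), r_mm, 2.0), GRID2D)
        sino = forward_project(np.where(mask, 1.0, 0.0), GRID2D, CFG)

        def antideriv(x):
            x = np.clip(x, -r_mm, r_mm)
            return x * np.sqrt(np.maximum(r_mm**2 - x**2, 0)) + r_mm**2 * np.arcsin(
                x / r_mm
            )

        edges = (np.arange(65) - 32.5) * bw
        chord = (antideriv(edges[1:]) - antideriv(edges[:-1])) / bw
        for ang in (0, 45, 90, 137):
            rms = np.sqrt(np.mean((sino[ang, :, 0] - chord) ** 2)) / chord.max()
            assert rms < 0.02

    def test_mass_proportional_to_duration(self):
        vol = _disk(8.0, value=1000.0)
        w = EnergyWindow(350, 750)
        s1 = expected_trues_sinogram(vol, GRID2D, CFG, I124, w, 100.0)
        s2 = expected_trues_sinogram(vol, GRID2D, CFG, I124, w, 200.0)
        # equal up to 124I decay over the extra 100 s (~1e-4)
        assert s2.sum() == pytest.approx(2.0 * s1.sum(), rel=1e-3)


class TestAttenuation:
    def test_air_only_gives_unity(self):
        material = np.full(GRID2D.shape, MATERIAL_AIR, dtype=np.int8)
        att = attenuation_factors(material, GRID2D, CFG)
        assert np.allclose(att, 1.0)

    def test_central_line_through_30mm_water(self):
        mask = voxelize_region(CylinderRegion((0, 0, 0), 15.0, 2.0), GRID2D)
        material = np.where(mask, MATERIAL_WATER, MATERIAL_AIR).astype(np.int8)
        att = attenuation_factors(material, GRID2D, CFG)
        # exp(-0.096/cm * 3 cm) = 0.750; voxelized diameter within one voxel
        assert att[:, 32, 0].mean() == pytest.approx(np.exp(-0.096 * 3.0), rel=0.02)

    def test_factors_increase_away_from_object(self):
        mask = voxelize_region(CylinderRegion((0, 0, 0), 10.0, 2.0), GRID2D)
        material = np.where(mask, MATERIAL_WATER, MATERIAL_AIR).astype(np.int8)
        att = attenuation_factors(material, GRID2D, CFG)
        prof = att[0, :, 0]
        assert prof[32] == prof.min()
        assert prof[0] == pytest.approx(1.0) and prof[-1] == pytest.approx(1.0)
        left = prof[:33]
        assert np.all(np.diff(left) <= 1e-12)  # decreasing toward center


@pytest.fixture(scope="module")
def trues():
    return forward_project(_disk(10.0, 50.0), GRID2D, CFG)


class TestComponents:

    def test_scatter_zero_fraction(self, trues):
        assert not scatter_component(trues, 0.0).any()

    def test_scatter_mass_ratio(self, trues):
        sc = scatter_component(trues, 0.3)
        assert sc.sum() / trues.sum() == pytest.approx(0.3 / 0.7, abs=1e-6)

    def test_scatter_smoother_than_trues(self):
        rod = forward_project(_disk(1.5, 50.0), GRID2D, CFG)
        sc = scatter_component(rod, 0.3)
        sc_scaled = sc * (rod.sum() / sc.sum())
        assert np.abs(np.diff(sc_scaled, axis=1)).max() < np.abs(np.diff(rod, axis=1)).max()

    def test_prompt_gamma_zero(self, trues):
        sc = scatter_component(trues, 0.3)
        assert not prompt_gamma_component(trues, sc, 0.0).any()

    def test_prompt_gamma_mass_fraction(self, trues):
        sc = scatter_component(trues, 0.3)
        pg = prompt_gamma_component(trues, sc, 0.31)
        frac = pg.sum() / (trues.sum() + sc.sum() + pg.sum())
        assert frac == pytest.approx(0.31, abs=1e-6)

    def test_prompt_gamma_flat_is_flat(self, trues):
        sc = scatter_component(trues, 0.3)
        pg = prompt_gamma_component(trues, sc, 0.2, shape="flat")
        assert pg.std() / pg.mean() < 1e-6

    def test_prompt_gamma_rejects_pgf_one(self, trues):
        with pytest.raises(ValueError):
            prompt_gamma_component(trues, trues, 1.0)

    def test_randoms_zero_activity(self):
        assert not randoms_component(0.0, CFG, (10, 10, 1)).any()

    def test_randoms_square_law(self):
        r1 = randoms_component(2.0, CFG, (10, 10, 1)).sum()
        r2 = randoms_component(4.0, CFG, (10, 10, 1)).sum()
        assert r2 == pytest.approx(4.0 * r1, rel=1e-9)

    def test_randoms_total_rate_from_coefficient(self):
        cfg = AcquisitionConfig(randoms_coefficient=40.0)
        w = EnergyWindow(350, 750)  # width 400 keV -> width factor 1
        total = randoms_component(5.0, cfg, (8, 8, 2), duration_s=1.0, window=w).sum()
        assert total == pytest.approx(40.0 * 25.0, rel=1e-9)


class TestPoisson:
    def _set(self, expectation):
        z = np.zeros_like(expectation)
        return SinogramSet(expectation, z, z, z, EnergyWindow(350, 750), 1.0, seed=5)

    def test_zero_expectation_zero_counts(self):
        s = apply_poisson(self._set(np.zeros((4, 4, 1))))
        assert not s.noisy_prompts.any()

    def test_sample_mean_near_expectation(self):
        s = apply_poisson(self._set(np.full((100, 10, 1), 50.0)), seed=11)
        mean = s.noisy_prompts.mean()
        assert abs(mean - 50.0) < 3.0 * np.sqrt(50.0 / 1000.0)

    def test_same_seed_identical(self):
        e = np.full((6, 6, 2), 17.0)
        a = apply_poisson(self._set(e), seed=3).noisy_prompts
        b = apply_poisson(self._set(e), seed=3).noisy_prompts
        assert np.array_equal(a, b)

    def test_components_sum_to_prompts_before_noise(self):
        t = np.full((4, 4, 1), 2.0)
        s = SinogramSet(t, t * 0.5, t * 0.25, t * 0.1, EnergyWindow(350, 750), 1.0)
        assert np.array_equal(s.prompts, t * 1.85)

    def test_save_load_roundtrip(self, tmp_path):
        t = np.random.default_rng(0).random((8, 8, 2))
        s = apply_poisson(SinogramSet(t, t * 0.3, t * 0.1, t * 0.2,
                                      EnergyWindow(350, 750), 10.0, seed=9))
        s.save(tmp_path / "sino")
        back = SinogramSet.load(tmp_path / "sino")
        assert np.array_equal(back.true_, t)
        assert np.array_equal(back.noisy_prompts, s.noisy_prompts)
        assert back.window == s.window and back.duration_s == 10.0


class TestSensitivitySim:
    def test_pure_emitter_recovers_geometric_sensitivity(self):
        cfg = AcquisitionConfig(geometric_sensitivity=0.0681,
                                intrinsic_background_rate=0.0)
        acq = simulate_sensitivity_acquisition(
            F18, EnergyWindow(350, 750), 0.0, 673e3, 300.0, cfg, seed=4
        )
        m = sensitivity_from_acquisition(acq)
        assert m.sensitivity_br_corrected_pct == pytest.approx(6.81, rel=0.01)

    def test_protocol_activities_no_deadtime_warning(self):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            simulate_sensitivity_acquisition(
                I124, EnergyWindow(350, 750), 0.31, 506e3, 300.0, seed=1
            )
            simulate_sensitivity_acquisition(
                F18, EnergyWindow(350, 750), 0.0, 673e3, 300.0, seed=2
            )

    def test_high_activity_warns(self):
        with pytest.warns(UserWarning, match="dead-time"):
            simulate_sensitivity_acquisition(
                F18, EnergyWindow(350, 750), 0.0, 50e6, 300.0, seed=1
            )

    @pytest.mark.parametrize("true_pgf", [0.0, 0.13, 0.31])
    def test_pgf_parameter_recovery(self, true_pgf):
        est = []
        for s in range(20):
            ai = simulate_sensitivity_acquisition(
                I124, EnergyWindow(350, 750), true_pgf, 506e3, 300.0, seed=300 + 2 * s
            )
            af = simulate_sensitivity_acquisition(
                F18, EnergyWindow(350, 750), 0.0, 673e3, 300.0, seed=301 + 2 * s
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # PGF=0 can clip at -1e-3
                est.append(
                    compute_pgf(
                        sensitivity_from_acquisition(ai).sensitivity_br_corrected_pct,
                        sensitivity_from_acquisition(af).sensitivity_br_corrected_pct,
                    )
                )
        assert np.mean(est) == pytest.approx(true_pgf, abs=0.01)
        assert np.abs(np.array(est) - true_pgf).max() < 0.02


class TestCountRates:
    def test_no_penalties_linear_in_activity(self):
        cfg = AcquisitionConfig(deadtime_tau=0.0, randoms_coefficient=0.0)
        rates = simulate_countrates([1.0, 2.0, 4.0], EnergyWindow(350, 750), cfg, pgf=0.0)
        t = [r.trues for r in rates]
        assert t[1] == pytest.approx(2 * t[0], rel=1e-9)
        assert t[2] == pytest.approx(4 * t[0], rel=1e-9)

    def test_observed_rate_approaches_inverse_tau(self):
        cfg = AcquisitionConfig(deadtime_tau=1e-6, randoms_coefficient=0.0)
        rates = simulate_countrates([1e4, 1e6], EnergyWindow(350, 750), cfg, pgf=0.0)
        for r in rates:
            total = r.trues + r.scatter + r.randoms + r.prompt_gamma
            assert total < 1e6
        big = rates[-1]
        assert big.trues + big.scatter == pytest.approx(1e6, rel=0.05)

    def test_pg_share_matches_pgf_at_400_590(self):
        rates = simulate_countrates([5.0], EnergyWindow(400, 590), AcquisitionConfig())[0]
        share = rates.prompt_gamma / (rates.trues + rates.scatter + rates.prompt_gamma)
        assert share == pytest.approx(0.02, abs=0.005)
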
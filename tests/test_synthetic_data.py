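"""Synthetic specimen generation, grayscale rendering, traces and fixture."""

import numpy as np
import pandas as pd
import pytest

from femload.image import VoxelImage
from femload.synthetic_data import (
    ActivitySpec,
    RemodellingConvergenceError,
    RemodellingParams,
    generate_adapted_structure,
    generate_load_traces,
    remodelling_update,
    synthesize_grayscale,
    table2_fixture,
)

from oracles import two_pass_mean_sd


class TestRemodellingRule:
    def test_uniform_stimulus_at_target_is_a_fixed_point(self):
        params = RemodellingParams()
        rho = np.full(100, 0.6)
        out = remodelling_update(rho, np.full(100, params.target_stimulus), params)
        np.testing.assert_array_equal(out, rho)

    def test_update_moves_density_towards_loading(self):
        params = RemodellingParams(step_size=0.1)
        rho = np.full(2, 0.5)
        out = remodelling_update(rho, np.array([0.04, 0.01]), params)
        assert out[0] > 0.5 > out[1]

    def test_density_clipped_to_floor_and_one(self):
        params = RemodellingParams(step_size=10.0)
        out = remodelling_update(np.array([0.5, 0.5]), np.array([10.0, 0.0]), params)
        assert out[0] == 1.0 and out[1] == params.density_floor

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RemodellingParams(density_floor=1.5)
        with pytest.raises(ValueError):
            RemodellingParams(step_size=0.0)


class TestGenerateAdaptedStructure:
    def test_specimen_is_deterministic_and_converged(self, adapted_specimen):
        again = generate_adapted_structure(
            domain_shape=(40, 40, 40), params=RemodellingParams(seed=3)
        )
        np.testing.assert_array_equal(
            again.binary_structure.values, adapted_specimen.binary_structure.values
        )
        assert adapted_specimen.meta["final_density_change"] < RemodellingParams().convergence_tol
        assert adapted_specimen.binary_structure.values.any()

    def test_oversized_step_raises_convergence_error(self):
        params = RemodellingParams(seed=0, step_size=20.0, max_iterations=12)
        with pytest.raises(RemodellingConvergenceError):
            generate_adapted_structure(domain_shape=(24, 24, 24), params=params)

    def test_all_zero_mix_rejected(self):
        with pytest.raises(ValueError, match="positive magnitude"):
            generate_adapted_structure(load_mix=[(20.0, 0.0)])

    def test_desk_scale_limit_enforced(self):
        with pytest.raises(ValueError, match="desk scale"):
            generate_adapted_structure(domain_shape=(96, 96, 96))


class TestSynthesizeGrayscale:
    @pytest.fixture()
    def binary(self):
        rng = np.random.default_rng(0)
        return VoxelImage((rng.random((16, 16, 16)) > 0.6).astype(np.uint8), 0.5)

    def test_no_noise_passthrough_takes_exactly_two_levels(self, binary):
        grey = synthesize_grayscale(binary, 6000.0, 1000.0)
        assert set(np.unique(grey.values)) == {1000.0, 6000.0}

    def test_threshold_between_levels_recovers_binary_exactly(self, binary):
        grey = synthesize_grayscale(binary, 6000.0, 1000.0)
        for thr in (1500.0, 3000.0, 5500.0):
            np.testing.assert_array_equal(grey.values >= thr, binary.values.astype(bool))

    def test_blur_and_noise_change_mask_only_near_boundary(self, binary):
        from scipy.ndimage import binary_dilation, binary_erosion

        grey = synthesize_grayscale(binary, 6000.0, 1000.0, blur_sigma=1.0,
                                    noise_sd=200.0, seed=4)
        mask = grey.values >= 3000.0
        truth = binary.values.astype(bool)
        band = binary_dilation(truth, iterations=2) & ~binary_erosion(truth, iterations=2)
        assert not (mask ^ truth)[~band].any()

    def test_same_seed_bit_identical(self, binary):
        a = synthesize_grayscale(binary, 6000.0, 1000.0, blur_sigma=1.0, noise_sd=200.0, seed=9)
        b = synthesize_grayscale(binary, 6000.0, 1000.0, blur_sigma=1.0, noise_sd=200.0, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_invalid_inputs_rejected(self, binary):
        with pytest.raises(ValueError, match="bone_grey"):
            synthesize_grayscale(binary, 1000.0, 6000.0)
        with pytest.raises(ValueError, match="noise_sd"):
            synthesize_grayscale(binary, 6000.0, 1000.0, noise_sd=-1.0)


class TestGenerateLoadTraces:
    def test_configured_peak_and_inclination_pass_through(self):
        spec = [ActivitySpec("walk", 2700.0, 18.0, 1.0, 100.0)]
        df = generate_load_traces(spec, n_subjects=1, seed=0)
        F = df[["f_ml_N", "f_ap_N", "f_vert_N"]].to_numpy()
        mags = np.linalg.norm(F, axis=1)
        k = mags.argmax()
        assert mags[k] == pytest.approx(2700.0, rel=1e-12)
        inc = np.degrees(np.arctan2(F[k, 0], F[k, 2]))
        assert inc == pytest.approx(18.0, abs=1e-9)

    def test_default_activities_span_printed_inclination_range(self):
        df = generate_load_traces(seed=0)
        F = df[["f_ml_N", "f_ap_N", "f_vert_N"]].to_numpy()
        mags = np.linalg.norm(F, axis=1)
        inc = np.degrees(np.arctan2(F[mags > 1e-9, 0], F[mags > 1e-9, 2]))
        assert inc.min() == pytest.approx(3.7, abs=1e-6)
        assert inc.max() == pytest.approx(66.6, abs=1e-6)

    def test_same_seed_identical_tables(self):
        a = generate_load_traces(seed=11, magnitude_jitter_sd=150.0)
        b = generate_load_traces(seed=11, magnitude_jitter_sd=150.0)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_activity_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_load_traces([], n_subjects=2)


class TestTable2Fixture:
    def test_exactly_ten_specimen_records(self):
        assert len(table2_fixture().records) == 10

    def test_specimen_three_initial_cov(self):
        fix = table2_fixture()
        row = fix.records[fix.records["specimen"] == "3"].iloc[0]
        assert row["cov_init"] == 1515.66

    def test_alpha2_column_mean_matches_printed_summary(self):
        fix = table2_fixture()
        mean, _ = two_pass_mean_sd(fix.alphas[:, 1])
        assert round(mean, 2) == 3.37 == round(fix.printed_mean["alpha_2"], 2)

    def test_invariants_hold(self):
        fix = table2_fixture()
        assert (fix.alphas >= 0).all()
        assert (fix.cov_init > 0).all() and (fix.cov_opt > 0).all()
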
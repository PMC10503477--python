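"""Synthetic cohort generator: determinism, effect structure, invariants."""
import numpy as np
import pandas as pd
import pytest

from pigait.cohort import (
    ScalingTransform,
    apply_scaling,
    generate_cohort,
    generate_grf_trace,
    generate_joint_traces,
    hip_height_increase,
    maturation_value,
)
from pigait.config import CohortConfig, MaturationProfile
from pigait.errors import ConfigurationError, DomainError
from pigait.kinematics import JOINTS, fourier_decompose, fourier_reconstruct
from pigait.normalization import normalize_stride_table
from pigait.templates import JointTemplate, default_template_bank


# ------------------------------------------------------------- maturation law

class TestMaturation:
    def test_zero_at_birth(self):
        assert maturation_value(0.0, MaturationProfile()) == 0.0

    def test_ninety_percent_of_plateau_at_8h(self):
        # calibration: 0.9 * 0.28 = 0.252
        assert maturation_value(8.0, MaturationProfile()) == pytest.approx(0.252, abs=1e-9)

    def test_plateau_reached_by_96h(self):
        assert maturation_value(96.0, MaturationProfile()) == pytest.approx(0.28, abs=1e-3)

    def test_monotone_nondecreasing(self):
        p = MaturationProfile()
        ages = np.linspace(0, 96, 200)
        vals = [maturation_value(a, p) for a in ages]
        assert np.all(np.diff(vals) >= 0)

    def test_negative_age_rejected(self):
        with pytest.raises(DomainError):
            maturation_value(-1.0, MaturationProfile())

    def test_stall_freezes_value(self):
        p = MaturationProfile(stall_age=4.0)
        v4 = maturation_value(4.0, p)
        assert maturation_value(10.0, p) == v4
        assert maturation_value(96.0, p) == v4


# ------------------------------------------------------------------ generator

class TestGenerateCohort:
    def test_determinism_byte_identical_csv(self, tmp_path):
        cfg = CohortConfig(n_aga=3, n_sga=2, ages=(1.0, 8.0), strides_per_recording=2)
        p1 = generate_cohort(cfg, 7).write_csvs(tmp_path / "a")
        p2 = generate_cohort(cfg, 7).write_csvs(tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_different_seed_differs(self):
        cfg = CohortConfig(n_aga=3, n_sga=2, ages=(1.0,), strides_per_recording=1)
        a = generate_cohort(cfg, 1).strides
        b = generate_cohort(cfg, 2).strides
        assert not np.allclose(a["speed_ms"], b["speed_ms"])

    def test_category_mass_gap(self, small_cohort):
        m = small_cohort.piglets.groupby("category")["birth_mass_kg"].mean()
        assert m["SGA"] / m["AGA"] == pytest.approx(0.5, abs=0.1)

    def test_isometric_segment_scaling(self, zero_noise_cohort):
        pg = zero_noise_cohort.piglets
        ratio = pg["seg_femur_m"] / pg["birth_mass_kg"] ** (1 / 3)
        assert np.allclose(ratio, ratio.iloc[0], rtol=1e-12)

    def test_every_stride_has_six_joint_traces(self, small_cohort):
        counts = small_cohort.joint_traces.groupby("stride_id")["joint"].nunique()
        assert (counts == 6).all()

    def test_stride_consistency_speed_length_frequency(self, small_cohort):
        st = small_cohort.strides
        assert np.allclose(
            st["speed_ms"], st["stride_length_m"] * st["stride_frequency_hz"], atol=1e-9
        )
        assert (st["stance_time_s"] <= st["stride_time_s"]).all()
        assert ((st["duty_factor"] > 0) & (st["duty_factor"] <= 1)).all()

    def test_dimensionless_identical_across_sizes_zero_noise(self, zero_noise_cohort):
        norm = normalize_stride_table(zero_noise_cohort.strides)
        aga = norm[norm["category"] == "AGA"]
        for col in ("froude_speed", "rel_stride_length", "rel_frequency", "duty_factor"):
            spread = aga.groupby("age_h")[col].std()
            assert spread.max() < 1e-10

    def test_hip_height_nondecreasing_with_age_zero_noise(self, zero_noise_cohort):
        st = zero_noise_cohort.strides
        for _, grp in st.groupby("piglet_id"):
            h = grp.groupby("age_h")["hip_height_midstance_m"].mean().sort_index()
            assert np.all(np.diff(h.to_numpy()) >= 0)

    def test_hip_height_increase_about_28_percent(self):
        cfg = CohortConfig(ages=(1.0, 2.0, 6.0, 8.0, 24.0, 28.0))
        inc = hip_height_increase(generate_cohort(cfg, 3).strides)
        assert inc["AGA"] == pytest.approx(28.0, abs=3.0)
        assert inc["SGA"] == pytest.approx(28.0, abs=3.0)

    def test_bad_config_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_aga=0)
        with pytest.raises(ConfigurationError):
            CohortConfig(rel_noise=-0.1)


# ---------------------------------------------------------------- joint bank

class TestJointTraces:
    def test_zero_noise_equals_template(self, rng):
        bank = default_template_bank()
        traces = generate_joint_traces(bank, {}, 1.0, 0.0, 100, rng)
        for j in JOINTS:
            ref = fourier_reconstruct(bank[j].coeffs(), 100, j)
            assert np.allclose(traces[j].angle, ref.angle, atol=1e-12)

    def test_band_limited_roundtrip(self, rng):
        traces = generate_joint_traces(
            default_template_bank(), {}, 1.0, 0.02, 100, rng, amplitude_jitter=0.05
        )
        for j in JOINTS:
            coeffs = fourier_decompose(traces[j])
            rec = fourier_reconstruct(coeffs, 100, j)
            assert np.max(np.abs(rec.angle - traces[j].angle)) < 1e-9

    def test_knee_offset_shifts_time_average(self, rng):
        bank = default_template_bank()
        traces = generate_joint_traces(bank, {"knee": -0.192}, 1.0, 0.0, 100, rng)
        assert traces["knee"].angle.mean() - bank["knee"].mean_angle == pytest.approx(
            -0.192, abs=1e-12
        )

    def test_zero_amplitude_gives_constant_trace(self, rng):
        traces = generate_joint_traces(default_template_bank(), {}, 0.0, 0.0, 100, rng)
        for j in JOINTS:
            assert np.ptp(traces[j].angle) == 0.0

    def test_angles_within_open_interval(self, small_cohort):
        a = small_cohort.joint_traces["angle_rad"]
        assert (a > 0).all() and (a < np.pi).all()

    def test_excess_harmonics_rejected(self):
        with pytest.raises(ConfigurationError):
            JointTemplate("knee", 1.9, {9: 0.1})


# ----------------------------------------------------------------------- GRF

class TestGRF:
    def test_limb_force_closure_zero_noise(self, zero_noise_cohort):
        vert = zero_noise_cohort.grf_traces.query("component == 'vertical'")
        st = zero_noise_cohort.strides.set_index("stride_id")
        for sid in st.index[:5]:
            total = 0.0
            for limb, col in (("fore", "duty_factor"), ("hind", "duty_factor_hind")):
                c = vert[(vert["stride_id"] == sid) & (vert["limb"] == limb)]
                total += 2 * st.loc[sid, col] * c["force_bw"].mean()
            assert total == pytest.approx(1.0, rel=0.02)

    def test_whole_body_impulse_equals_body_weight(self, zero_noise_cohort):
        # sum over 4 limbs of stance impulse = 1 BW * stride time
        vert = zero_noise_cohort.grf_traces.query("component == 'vertical'")
        st = zero_noise_cohort.strides.set_index("stride_id")
        sid = st.index[0]
        impulse = 0.0
        for limb, col in (("fore", "duty_factor"), ("hind", "duty_factor_hind")):
            c = vert[(vert["stride_id"] == sid) & (vert["limb"] == limb)]
            stance_t = st.loc[sid, col] * st.loc[sid, "stride_time_s"]
            impulse += 2 * c["force_bw"].mean() * stance_t
        assert impulse == pytest.approx(st.loc[sid, "stride_time_s"], rel=0.02)

    def test_double_hump_and_fore_exceeds_hind(self, rng):
        vf, _ = generate_grf_trace("fore", 0.68, 0.30, rng, 0.0)
        vh, _ = generate_grf_trace("hind", 0.66, 0.20, rng, 0.0)
        assert vf.samples.max() > vh.samples.max()
        # two local maxima around a midstance dip
        mid = vf.samples[len(vf.samples) // 2]
        assert vf.samples.max() > mid

    def test_fore_aft_zero_net_impulse_and_single_crossing(self, rng):
        _, fa = generate_grf_trace("fore", 0.68, 0.30, rng, 0.0)
        assert np.trapezoid(fa.samples, fa.sample_times) == pytest.approx(0.0, abs=1e-12)
        interior = fa.samples[1:-1]
        assert np.sum(np.diff(np.sign(interior)) != 0) == 1

    def test_vertical_nonnegative_with_noise(self, small_cohort):
        vert = small_cohort.grf_traces.query("component == 'vertical'")
        assert (vert["force_bw"] >= 0).all()

    def test_bad_inputs_rejected(self, rng):
        with pytest.raises(DomainError):
            generate_grf_trace("fore", 0.0, 0.3, rng, 0.0)
        with pytest.raises(DomainError):
            generate_grf_trace("fore", 0.6, 1.5, rng, 0.0)


# ------------------------------------------------------------------- scaling

class TestScaling:
    def test_identity_leaves_dataset_unchanged(self, small_cohort):
        scaled = apply_scaling(small_cohort, ScalingTransform.identity())
        pd.testing.assert_frame_equal(scaled.strides, small_cohort.strides)
        pd.testing.assert_frame_equal(scaled.piglets, small_cohort.piglets)

    def test_dynamic_similarity_preserves_dimensionless(self, small_cohort):
        norm0 = normalize_stride_table(small_cohort.strides)
        scaled = apply_scaling(small_cohort, ScalingTransform.dynamic_similarity(2.0))
        norm1 = normalize_stride_table(scaled.strides)
        for col in ("froude_speed", "rel_stride_length", "rel_frequency", "duty_factor"):
            assert np.max(np.abs(norm1[col].to_numpy() - norm0[col].to_numpy())) < 1e-10

    def test_time_only_scaling_changes_rel_frequency_by_root_alpha(self, small_cohort):
        # alpha=2 with beta=1: F unchanged, h doubled -> F*sqrt(h/g) grows by sqrt(2)
        norm0 = normalize_stride_table(small_cohort.strides)
        scaled = apply_scaling(small_cohort, ScalingTransform(2.0, 1.0, 8.0))
        norm1 = normalize_stride_table(scaled.strides)
        ratio = norm1["rel_frequency"].to_numpy() / norm0["rel_frequency"].to_numpy()
        assert np.allclose(ratio, np.sqrt(2.0), rtol=1e-12)

    def test_nonpositive_factors_rejected(self):
        with pytest.raises(DomainError):
            ScalingTransform(0.0, 1.0, 1.0)
        with pytest.raises(DomainError):
            ScalingTransform(1.0, -1.0, 1.0)
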
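import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apichap import kinetics, synth
from apichap.kinetics import (AveragedCurve, SigmoidFit, TimeCourse,
                              average_replicates, compare_halftimes,
                              eval_sigmoid, fit_sigmoid, halftime_scaling,
                              load_plate, normalize_curve, sigmoid,
                              subtract_control)

from conftest import make_curve


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

class TestTimeCourse:
    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            TimeCourse(times=[0, 1, 2, 3], fluorescence=[0, 1, 2],
                       tau_conc=10.0)

    def test_non_monotone(self):
        with pytest.raises(ValueError, match="increasing"):
            TimeCourse(times=[0, 1, 1, 2], fluorescence=[0, 1, 2, 3],
                       tau_conc=10.0)

    def test_too_short(self):
        with pytest.raises(ValueError):
            TimeCourse(times=[0, 1, 2], fluorescence=[0, 1, 2],
                       tau_conc=10.0)

    def test_negative_conc(self):
        with pytest.raises(ValueError):
            TimeCourse(times=[0, 1, 2, 3], fluorescence=[0, 1, 2, 3],
                       tau_conc=-1.0)


# ---------------------------------------------------------------------------
# load_plate
# ---------------------------------------------------------------------------

class TestLoadPlate:
    def test_count_preservation(self, tmp_path):
        (tmp_path / "plate.csv").write_text(
            "time_h,W1,W2,W3\n0,1,2,3\n1,2,3,4\n2,3,4,5\n3,4,5,6\n4,5,6,7\n")
        (tmp_path / "meta.csv").write_text(
            "well,tau_conc_uM,inhibitor,inhibitor_conc_uM,heparin,replicate\n"
            "W1,10,none,0,True,r1\nW2,10,none,0,True,r2\n"
            "W3,10,none,0,True,r3\n")
        curves = load_plate(tmp_path / "plate.csv", tmp_path / "meta.csv")
        assert len(curves) == 3
        assert all(c.times.size == 5 for c in curves)

    def test_duplicate_time_rejected(self, tmp_path):
        (tmp_path / "plate.csv").write_text(
            "time_h,W1\n0,1\n1,2\n1,3\n2,4\n3,5\n")
        (tmp_path / "meta.csv").write_text(
            "well,tau_conc_uM,inhibitor,inhibitor_conc_uM,heparin,replicate\n"
            "W1,10,none,0,True,r1\n")
        with pytest.raises(ValueError, match="increasing"):
            load_plate(tmp_path / "plate.csv", tmp_path / "meta.csv")

    def test_missing_metadata_names_well(self, tmp_path):
        (tmp_path / "plate.csv").write_text(
            "time_h,W1,W9\n0,1,1\n1,2,2\n2,3,3\n3,4,4\n")
        (tmp_path / "meta.csv").write_text(
            "well,tau_conc_uM,inhibitor,inhibitor_conc_uM,heparin,replicate\n"
            "W1,10,none,0,True,r1\n")
        with pytest.raises(ValueError, match="W9"):
            load_plate(tmp_path / "plate.csv", tmp_path / "meta.csv")

    def test_synthetic_plate_round_trip(self, tmp_path):
        conds = [dict(m1=0.5, n1=10.0, m2=0.2, n2=500.0, k=1.2, t05=6.0,
                      tau_conc=10.0)]
        plate_df, meta_df, _ = synth.gen_sigmoid_plate(
            conds, noise_sd=5.0, n_replicates=3, seed=11, out_dir=tmp_path)
        curves = load_plate(tmp_path / "plate.csv", tmp_path / "meta.csv")
        assert len(curves) == 3
        for i, c in enumerate(curves):
            np.testing.assert_array_equal(c.times,
                                          plate_df["time_h"].to_numpy())
            np.testing.assert_allclose(
                c.fluorescence, plate_df[f"W{i + 1:03d}"].to_numpy(),
                rtol=0, atol=1e-12)


# ---------------------------------------------------------------------------
# averaging / subtraction / normalization
# ---------------------------------------------------------------------------

class TestAverage:
    def test_mean_of_identical_is_identity(self):
        t = np.arange(5.0)
        a = TimeCourse(t, [1, 2, 3, 4, 5], 10.0, replicate_id="a")
        b = TimeCourse(t, [1, 2, 3, 4, 5], 10.0, replicate_id="b")
        avg = average_replicates([a, b])
        np.testing.assert_array_equal(avg.mean_fluorescence,
                                      [1, 2, 3, 4, 5])
        assert avg.n_replicates == 2

    def test_mean_of_constants(self):
        t = np.arange(4.0)
        a = TimeCourse(t, [0, 0, 0, 0], 10.0, replicate_id="a")
        b = TimeCourse(t, [2, 2, 2, 2], 10.0, replicate_id="b")
        np.testing.assert_array_equal(
            average_replicates([a, b]).mean_fluorescence, [1, 1, 1, 1])

    def test_grid_mismatch(self):
        a = TimeCourse(np.arange(4.0), np.zeros(4), 10.0)
        b = TimeCourse(np.arange(4.0) + 0.5, np.zeros(4), 10.0)
        with pytest.raises(ValueError, match="grid"):
            average_replicates([a, b])

    def test_mixed_conditions(self):
        t = np.arange(4.0)
        a = TimeCourse(t, np.zeros(4), 10.0)
        b = TimeCourse(t, np.zeros(4), 20.0)
        with pytest.raises(ValueError, match="mixed"):
            average_replicates([a, b])

    def test_monte_carlo_mean_within_three_sigma(self):
        # 12 noisy replicates of a known sigmoid; pointwise mean must sit
        # within 3*sigma/sqrt(12) of truth (fixed seed)
        rng = np.random.default_rng(150)
        t = np.arange(0, 97) / 4.0
        truth = sigmoid(t, 0, 0, 0, 1, 1.0, 12.0)
        sigma = 0.05
        reps = [TimeCourse(t, truth + sigma * rng.standard_normal(t.size),
                           10.0, replicate_id=f"r{i}") for i in range(12)]
        avg = average_replicates(reps)
        bound = 3.0 * sigma / math.sqrt(12)
        assert np.all(np.abs(avg.mean_fluorescence - truth) < bound)


class TestSubtractControl:
    def test_zero_control_identity(self):
        t = np.arange(5.0)
        avg = make_curve(t, np.arange(5.0))
        zero = make_curve(t, np.zeros(5))
        np.testing.assert_array_equal(
            subtract_control(avg, zero).mean_fluorescence, avg.mean_fluorescence)

    def test_self_subtraction_zero(self):
        avg = make_curve(np.arange(5.0), np.arange(5.0) ** 2)
        out = subtract_control(avg, avg)
        assert np.all(out.mean_fluorescence == 0)
        assert out.control_subtracted

    def test_constructed_decomposition(self):
        t = np.linspace(0, 10, 30)
        signal = sigmoid(t, 0, 0, 0, 100.0, 2.0, 5.0)
        baseline = 3.0 * t + 7.0
        total = make_curve(t, signal + baseline)
        ctrl = make_curve(t, baseline)
        np.testing.assert_allclose(
            subtract_control(total, ctrl).mean_fluorescence, signal,
            rtol=0, atol=1e-12)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            subtract_control(make_curve(np.arange(5.0), np.zeros(5)),
                             make_curve(np.arange(5.0) + 1, np.zeros(5)))


class TestNormalize:
    def test_simple(self):
        out = normalize_curve(make_curve(np.arange(3.0), [1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.mean_fluorescence, [0, 0.5, 1])
        assert out.normalized and out.norm_reference == (1.0, 3.0)

    def test_flat_curve_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_curve(make_curve(np.arange(4.0), np.ones(4)))

    def test_suppressed_plateau_against_reference(self):
        t = np.linspace(0, 30, 100)
        ref = make_curve(t, sigmoid(t, 0, 0, 0, 1000.0, 2.0, 5.0))
        inhibited = make_curve(t, sigmoid(t, 0, 0, 0, 300.0, 1.0, 15.0))
        out = normalize_curve(inhibited, reference=ref)
        assert out.mean_fluorescence[-1] == pytest.approx(0.3, abs=1e-3)

    @given(a=st.floats(0.1, 100.0), b=st.floats(-50.0, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        t = np.linspace(0, 10, 20)
        y = sigmoid(t, 0.1, 1.0, 0.0, 9.0, 2.0, 5.0)
        base = normalize_curve(make_curve(t, y))
        scaled = normalize_curve(make_curve(t, a * y + b))
        np.testing.assert_allclose(scaled.mean_fluorescence,
                                   base.mean_fluorescence, atol=1e-9)


# ---------------------------------------------------------------------------
# sigmoid evaluation and fitting
# ---------------------------------------------------------------------------

class TestEvalSigmoid:
    def test_midpoint(self):
        p = dict(m1=0, n1=0, m2=0, n2=1, k=3.3, t05=7.7)
        assert eval_sigmoid(p, 7.7) == pytest.approx(0.5)

    def test_pre_baseline_limit(self):
        p = dict(m1=2.0, n1=5.0, m2=0, n2=100.0, k=50.0, t05=10.0)
        t = 1.0
        assert eval_sigmoid(p, t) == pytest.approx(2.0 * t + 5.0, rel=1e-9)

    def test_hand_evaluated_point(self):
        # direct arithmetic oracle: value at t=0 is 1/(1 + e^(1.79*4.41))
        p = dict(m1=0, n1=0, m2=0, n2=1, k=1.79, t05=4.41)
        expected = 1.0 / (1.0 + math.exp(1.79 * 4.41))
        assert eval_sigmoid(p, 0.0) == pytest.approx(expected, rel=1e-12)

    def test_overflow_guard(self):
        p = dict(m1=0, n1=0, m2=0, n2=1, k=1e6, t05=5.0)
        assert eval_sigmoid(p, 0.0) == 0.0
        assert eval_sigmoid(p, 10.0) == 1.0

    @given(m1=st.floats(-5, 5), n1=st.floats(-10, 10), m2=st.floats(-5, 5),
           n2=st.floats(-10, 10), k=st.floats(0.01, 50),
           t05=st.floats(1, 20))
    @settings(max_examples=50, deadline=None)
    def test_midpoint_is_baseline_mean(self, m1, n1, m2, n2, k, t05):
        val = eval_sigmoid(dict(m1=m1, n1=n1, m2=m2, n2=n2, k=k, t05=t05),
                           t05)
        mean = 0.5 * ((m1 * t05 + n1) + (m2 * t05 + n2))
        assert val == pytest.approx(mean, rel=1e-9, abs=1e-9)


class TestFitSigmoid:
    def test_insufficient_points(self):
        with pytest.raises(ValueError):
            fit_sigmoid(make_curve(np.arange(5.0), np.arange(5.0)))

    @pytest.mark.parametrize("params", [
        dict(m1=0.0, n1=0.0, m2=0.0, n2=1.0, k=1.79, t05=4.41),
        dict(m1=3.0, n1=50.0, m2=1.0, n2=900.0, k=1.5, t05=8.0),
        dict(m1=-0.5, n1=20.0, m2=0.1, n2=300.0, k=0.9, t05=14.0),
    ])
    def test_noiseless_recovery(self, params):
        t = np.arange(0, 24 * 12 + 1) / 12.0
        fit = fit_sigmoid(make_curve(t, eval_sigmoid(params, t)))
        assert fit.converged
        for name, truth in params.items():
            assert getattr(fit, name) == pytest.approx(truth, rel=1e-3,
                                                       abs=1e-6)

    def test_matches_brute_force_grid(self):
        # grid-search oracle over (t05, k) at 0.01 resolution, baselines
        # fixed at truth
        truth = dict(m1=0.0, n1=0.0, m2=0.0, n2=1.0, k=1.37, t05=6.83)
        t = np.arange(0, 24 * 12 + 1) / 12.0
        y = eval_sigmoid(truth, t)
        t05_grid = np.arange(6.50, 7.20, 0.01)
        k_grid = np.arange(1.00, 1.80, 0.01)
        sse = np.array([[np.sum((sigmoid(t, 0, 0, 0, 1, k, t05) - y) ** 2)
                         for k in k_grid] for t05 in t05_grid])
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        fit = fit_sigmoid(make_curve(t, y))
        assert abs(fit.t05 - t05_grid[i]) <= 0.01
        assert abs(fit.k - k_grid[j]) <= 0.01

    def test_noisy_t05_coverage(self):
        # recovered t05 within 3 reported SEs of truth in >= 95% of 200
        # noisy repetitions (fixed seed)
        rng = np.random.default_rng(2024)
        t = np.arange(0, 97) / 4.0
        truth = sigmoid(t, 0, 0, 0, 1, 1.5, 10.0)
        hits = 0
        for _ in range(200):
            y = truth + 0.02 * rng.standard_normal(t.size)
            fit = fit_sigmoid(make_curve(t, y))
            if fit.converged and abs(fit.t05 - 10.0) <= 3 * fit.se["t05"]:
                hits += 1
        assert hits >= 190

    def test_sharp_transition_recovery(self):
        # <0.1% recovery requires k * (t_max - t_min) >= 10
        t = np.linspace(0, 24, 200)
        params = dict(m1=0.2, n1=1.0, m2=0.0, n2=50.0, k=0.5, t05=12.0)
        fit = fit_sigmoid(make_curve(t, eval_sigmoid(params, t)))
        for name, truth in params.items():
            assert getattr(fit, name) == pytest.approx(truth, rel=1e-3)


# ---------------------------------------------------------------------------
# half-time comparison and scaling
# ---------------------------------------------------------------------------

class TestCompareHalftimes:
    def test_identical(self):
        f = SigmoidFit(t05=4.0, se={"t05": 0.1})
        assert compare_halftimes(f, f) == (0.0, 1.0)

    def test_paper_scale_z(self):
        a = SigmoidFit(t05=4.41, se={"t05": 0.02})
        b = SigmoidFit(t05=11.22, se={"t05": 0.05})
        z, p = compare_halftimes(a, b)
        assert z > 25
        assert p < 1e-100

    def test_normal_quantile_oracle(self):
        # se_a=1, se_b->0, separation 1.96 -> p ~ 0.05
        from scipy.stats import norm
        a = SigmoidFit(t05=0.0, se={"t05": 1.0})
        b = SigmoidFit(t05=1.96, se={"t05": 0.0})
        z, p = compare_halftimes(a, b)
        assert z == pytest.approx(1.96)
        assert p == pytest.approx(2 * norm.sf(1.96), rel=1e-9)
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_zero_se_error(self):
        a = SigmoidFit(t05=1.0, se={"t05": 0.0})
        b = SigmoidFit(t05=2.0, se={"t05": 0.0})
        with pytest.raises(ValueError):
            compare_halftimes(a, b)

    def test_unconverged_error(self):
        a = SigmoidFit(t05=1.0, se={"t05": 0.1}, converged=False)
        with pytest.raises(ValueError):
            compare_halftimes(a, a)

    @given(delta=st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_linearity(self, delta):
        a = SigmoidFit(t05=5.0, se={"t05": 0.3})
        b = SigmoidFit(t05=5.0 + delta, se={"t05": 0.4})
        z_ab, _ = compare_halftimes(a, b)
        z_ba, _ = compare_halftimes(b, a)
        assert z_ab == z_ba
        z2, _ = compare_halftimes(
            a, SigmoidFit(t05=5.0 + 2 * delta, se={"t05": 0.4}))
        assert z2 == pytest.approx(2 * z_ab, rel=1e-9)


class TestHalftimeScaling:
    @staticmethod
    def _fits(concs, t05s):
        return [(c, SigmoidFit(t05=t, se={"t05": 0.01}))
                for c, t in zip(concs, t05s)]

    def test_exact_power_law(self):
        concs = np.array([2.5, 5.0, 10.0, 20.0])
        sc = halftime_scaling(self._fits(concs, 30.0 * concs ** -0.5))
        assert sc.slope == pytest.approx(-0.5, abs=1e-12)
        assert sc.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_concentration_independent(self):
        concs = np.array([2.5, 5.0, 10.0, 20.0])
        sc = halftime_scaling(self._fits(concs, np.full(4, 7.0)))
        assert sc.slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError):
            halftime_scaling(self._fits([1.0, 2.0], [1.0, 2.0]))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            halftime_scaling(self._fits([1.0, 2.0, 4.0], [1.0, -2.0, 3.0]))
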
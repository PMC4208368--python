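"""Signal primitives, posturography metrics and gait parameter extraction."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from fallrisk.features import (
    ExtractionConfig,
    butterworth_filter,
    compute_mvic,
    cop_metrics,
    detect_gait_events,
    gait_summary,
    preprocess_cop,
    stride_parameters,
    summary_stats,
    trim_signal,
)
from fallrisk.synthetic import generate_gait_trial, generate_torque_trial
from fallrisk.trial import RawTrial

from conftest import make_params


class TestButterworth:
    def test_constant_signal_passes_unchanged(self):
        x = np.full(500, 3.7)
        np.testing.assert_allclose(butterworth_filter(x, 4, 25, 100), x, atol=1e-9)

    def test_zero_phase_gain_at_cutoff_is_half(self):
        # |H|^2 at the -3 dB point: forward-backward 4th order -> 0.5
        rate, f = 1000.0, 25.0
        t = np.arange(20000) / rate
        x = np.sin(2 * np.pi * f * t)
        y = butterworth_filter(x, 4, f, rate)
        mid = slice(5000, 15000)  # avoid edge transients
        gain = y[mid].std() / x[mid].std()
        assert gain == pytest.approx(0.5, abs=0.01)

    def test_passband_phase_shift_below_one_sample(self):
        rate, f = 1000.0, 2.5  # cutoff/10
        t = np.arange(20000) / rate
        x = np.sin(2 * np.pi * f * t)
        y = butterworth_filter(x, 4, 25, rate)
        mid = slice(5000, 15000)
        lags = np.arange(-5, 6)
        xc = [np.dot(x[mid], np.roll(y, k)[mid]) for k in lags]
        assert abs(lags[int(np.argmax(xc))]) <= 1

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            butterworth_filter(np.zeros(100), 4, 50, 100)


def _flat_trial(duration, rate=100.0):
    n = int(duration * rate)
    return RawTrial(
        trial_id="t", subject_id="s", modality="torque", condition="KE:c15",
        rate=rate, channels={"torque": np.arange(n, dtype=float)},
    )


class TestTrim:
    def test_torque_window_leaves_six_seconds(self):
        out = trim_signal(_flat_trial(15), 7, 2)
        assert out.duration == pytest.approx(6.0)
        assert out.channels["torque"][0] == 700  # first retained sample at 7 s

    def test_sway_window_leaves_26_seconds(self):
        out = trim_signal(_flat_trial(30), 2, 2)
        assert out.duration == pytest.approx(26.0)

    def test_nothing_left_is_an_error(self):
        with pytest.raises(ValueError, match="too short"):
            trim_signal(_flat_trial(8), 7, 2)


class TestSummaryStats:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ([5.0, 5.0, 5.0], (5.0, 0.0, 0.0)),
            ([1.0, 2.0, 3.0], (2.0, 1.0, 0.5)),
            ([8.0, 12.0], (10.0, np.sqrt(8.0), np.sqrt(8.0) / 10)),
        ],
    )
    def test_hand_computed_values(self, series, expected):
        mean, sd, cv = summary_stats(np.array(series))
        assert (mean, sd, cv) == pytest.approx(expected)

    def test_zero_mean_flags_cv_undefined(self):
        out = summary_stats(np.array([-1.0, 1.0]))
        assert np.isnan(out.cv)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            summary_stats(np.array([1.0]))


class TestMvic:
    def test_best_of_three_peaks(self, quiet_params):
        trials = []
        for rep, peak in enumerate((100.0, 110.0, 105.0)):
            p = make_params(mvic={"KE": peak, "PF": 60.0},
                            tremor_cv={"KE": 0.0, "PF": 0.0})
            trials.append(generate_torque_trial(p, "KE", "mvic", seed=rep, rep=rep))
        assert compute_mvic(trials) == pytest.approx(110.0, rel=1e-3)

    def test_single_trial_returns_its_peak(self, quiet_params):
        t = generate_torque_trial(quiet_params, "PF", "mvic", seed=0)
        assert compute_mvic([t]) == pytest.approx(60.0, rel=1e-3)

    def test_no_trials_rejected(self):
        with pytest.raises(ValueError):
            compute_mvic([])


def _circle_trial(r=0.01, omega=2 * np.pi * 0.5, rate=120.0, k_turns=5):
    t = np.arange(int(k_turns * 2 * np.pi / omega * rate)) / rate
    return RawTrial(
        trial_id="c", subject_id="s", modality="cop", condition="QEO", rate=rate,
        channels={"AP": r * np.cos(omega * t), "ML": r * np.sin(omega * t)},
    )


class TestCopMetrics:
    def test_circular_path_analytic_values(self):
        r, omega = 0.01, 2 * np.pi * 0.4
        m = cop_metrics(_circle_trial(r=r, omega=omega))
        assert m["DIST"] == pytest.approx(r, rel=1e-4)
        assert m["RMS"] == pytest.approx(r, rel=1e-4)
        assert m["VEL"] == pytest.approx(r * omega, rel=1e-3)
        assert m["FREQ"] == pytest.approx(omega / (2 * np.pi), rel=1e-3)
        # swept area per second: half r^2 omega
        assert m["AREA"] == pytest.approx(0.5 * r**2 * omega, rel=1e-3)

    def test_constant_trace_zeroes_and_undefined_frequencies(self):
        n = 240
        trial = RawTrial(
            trial_id="z", subject_id="s", modality="cop", condition="QEC",
            rate=120.0, channels={"AP": np.full(n, 0.3), "ML": np.full(n, -0.1)},
        )
        m = cop_metrics(trial)
        for key in ("DIST", "RMS", "VEL", "AREA", "EA"):
            assert m[key] == pytest.approx(0.0, abs=1e-15)
        assert np.isnan(m["FREQ"]) and np.isnan(m["FREQ-AP"])

    def test_translation_invariance(self, rng):
        base = _circle_trial()
        shifted = base.copy_with(
            {"AP": base.channels["AP"] + 0.35, "ML": base.channels["ML"] - 1.2}
        )
        m0, m1 = cop_metrics(base), cop_metrics(shifted)
        for key in m0:
            assert m1[key] == pytest.approx(m0[key], rel=1e-9)

    def test_ellipse_area_matches_covariance_eigendecomposition(self, rng):
        # independent oracle: area of the 95% ellipse from the eigenvalues of
        # the 2x2 covariance matrix
        n = 2000
        x = rng.multivariate_normal([0, 0], [[2.0, 0.7], [0.7, 0.5]], size=n) * 1e-3
        trial = RawTrial(
            trial_id="rw", subject_id="s", modality="cop", condition="QEO",
            rate=120.0, channels={"AP": x[:, 0], "ML": x[:, 1]},
        )
        m = cop_metrics(trial)
        lam = np.linalg.eigvalsh(np.cov(x[:, 0], x[:, 1], ddof=1))
        expected = 2 * np.pi * spstats.f.ppf(0.95, 2, n - 2) * np.sqrt(lam[0] * lam[1])
        assert m["EA"] == pytest.approx(expected, rel=1e-9)

    def test_oracle_recomputation_on_random_traces(self, rng):
        # straightforward re-implementation of every metric, 10 random trials
        for _ in range(10):
            n = int(rng.integers(200, 600))
            ap = np.cumsum(rng.normal(size=n)) * 1e-4
            ml = np.cumsum(rng.normal(size=n)) * 1e-4
            rate = 120.0
            trial = RawTrial(
                trial_id="o", subject_id="s", modality="cop", condition="QEO",
                rate=rate, channels={"AP": ap, "ML": ml},
            )
            m = cop_metrics(trial)
            a, b = ap - ap.mean(), ml - ml.mean()
            T = (n - 1) / rate
            rd = np.sqrt(a**2 + b**2)
            assert m["DIST"] == pytest.approx(rd.mean(), rel=1e-9)
            assert m["RMS-ML"] == pytest.approx(np.sqrt((b**2).mean()), rel=1e-9)
            path = np.sum(np.sqrt(np.diff(a) ** 2 + np.diff(b) ** 2))
            assert m["VEL"] == pytest.approx(path / T, rel=1e-9)
            assert m["FREQ-AP"] == pytest.approx(
                (np.abs(np.diff(a)).sum() / T) / (4 * np.abs(a).mean()), rel=1e-9
            )
            area = 0.5 * np.abs(a[:-1] * b[1:] - a[1:] * b[:-1]).sum() / T
            assert m["AREA"] == pytest.approx(area, rel=1e-9)


class TestGaitEvents:
    def test_noise_free_recovery_within_one_sample(self, quiet_params):
        trial, truth = generate_gait_trial(quiet_params, 0, seed=3)
        events = detect_gait_events(trial)
        for side in ("L", "R"):
            det = events.feet[side].hs_t
            planted = np.array(truth["hs_t"][side])
            assert len(det) == len(planted)
            assert np.max(np.abs(det - planted)) <= 1.0 / trial.rate + 1e-9
            det_to = events.feet[side].to_t
            planted_to = np.array(truth["to_t"][side])
            # the detector also sees the lead-in toe-off before the first strike
            assert np.max(np.abs(det_to[-len(planted_to):] - planted_to)) <= 1.0 / trial.rate + 1e-9

    def test_noisy_recovery_within_one_sample(self):
        p = make_params(
            stride_time_sd={"L": 0.03, "R": 0.03}, stride_length_sd=0.02,
            stance_frac_sd=0.002, phase_sd=0.003, maxfc_sd=0.005,
            minfc_sd=0.002, marker_noise_sd=0.0005,
        )
        trial, truth = generate_gait_trial(p, 0, seed=11)
        events = detect_gait_events(trial)
        for side in ("L", "R"):
            det = events.feet[side].hs_t
            planted = np.array(truth["hs_t"][side])
            assert len(det) == len(planted)
            assert np.max(np.abs(det - planted)) <= 1.0 / trial.rate + 1e-9

    def test_exactly_periodic_strikes_when_noise_free(self, quiet_params):
        trial, truth = generate_gait_trial(quiet_params, 0, seed=0)
        for side in ("L", "R"):
            dt = np.diff(truth["hs_t"][side])
            np.testing.assert_allclose(dt, quiet_params.stride_time, atol=1e-12)
            dx = np.diff(truth["hs_x"][side])
            np.testing.assert_allclose(dx, quiet_params.stride_length, atol=1e-12)

    def test_standing_still_trial_discarded(self):
        n = 800
        channels = {
            f"{side}_{role}_{ax}": np.full(n, 0.1)
            for side in ("L", "R")
            for role in ("heel", "met1", "met5", "met23")
            for ax in ("x", "y", "z")
        }
        trial = RawTrial(
            trial_id="still", subject_id="s", modality="gait_markers",
            condition="walk00", rate=100.0, channels=channels,
        )
        with pytest.warns(UserWarning, match="discarded"):
            assert detect_gait_events(trial) is None


class TestStrideParameters:
    def test_planted_geometry_recovered(self, quiet_params):
        trial, truth = generate_gait_trial(quiet_params, 0, seed=5)
        events = detect_gait_events(trial)
        table = stride_parameters(events, trial)
        strides = table.strides
        for side in ("L", "R"):
            sub = strides[strides["foot"] == side]
            np.testing.assert_allclose(
                sub["stride_time"], quiet_params.stride_time, atol=0.011
            )
            np.testing.assert_allclose(
                sub["stride_length"], quiet_params.stride_length, atol=1e-3
            )
            # planted swing apex within filter tolerance
            np.testing.assert_allclose(sub["maxfc"], 0.12, atol=2e-3)
            np.testing.assert_allclose(sub["minfc"], 0.025, atol=2e-3)
            # stride = stance + swing by construction
            np.testing.assert_allclose(
                sub["stride_time"], sub["stance_time"] + sub["swing_time"], atol=1e-12
            )
        assert table.cadence == pytest.approx(120.0 / quiet_params.stride_time, rel=0.01)
        np.testing.assert_allclose(
            table.steps["step_length"], quiet_params.stride_length / 2, atol=1e-3
        )
        np.testing.assert_allclose(
            table.steps["step_width"], quiet_params.step_width, atol=1e-3
        )

    def test_first_and_last_strides_trimmed(self, quiet_params):
        trial, truth = generate_gait_trial(quiet_params, 0, seed=5)
        events = detect_gait_events(trial)
        trimmed = stride_parameters(events, trial, trim=True)
        raw = stride_parameters(events, trial, trim=False)
        for side in ("L", "R"):
            n_raw = (raw.strides["foot"] == side).sum()
            n_trim = (trimmed.strides["foot"] == side).sum()
            assert n_trim == n_raw - 2

    def test_cadence_from_mean_stride_time(self):
        # mean stride time 1.2 s -> 100 steps/min
        p = make_params(stride_time=1.2)
        trial, _ = generate_gait_trial(p, 0, seed=1)
        table = stride_parameters(detect_gait_events(trial), trial)
        assert table.cadence == pytest.approx(100.0, rel=0.01)


class TestGaitSummary:
    def _tables(self, params, n_walks=6, seed0=0):
        tables = []
        for w in range(n_walks):
            trial, _ = generate_gait_trial(params, w, seed=seed0 + w)
            tables.append(stride_parameters(detect_gait_events(trial), trial))
        return tables

    def test_zero_cycle_noise_gives_zero_variability(self, quiet_params):
        out = gait_summary(self._tables(quiet_params))
        for m, v in out.items():
            if m.startswith("GA:SD") or m.startswith("GA:CV"):
                # residual variability is sampling quantization only
                assert abs(v) < 0.02, m
        assert out["GA:Mn-Str-Len-L"] == pytest.approx(1.2, abs=1e-3)

    def test_cv_identity_holds_per_subject(self):
        p = make_params(stride_time_sd={"L": 0.03, "R": 0.02},
                        stride_length_sd=0.02, marker_noise_sd=0.0003)
        out = gait_summary(self._tables(p))
        for name in ("Str-T-L", "Str-Len-R", "Sw-T-L"):
            assert out[f"GA:CV-{name}"] == pytest.approx(
                out[f"GA:SD-{name}"] / out[f"GA:Mn-{name}"], rel=1e-9
            )

    def test_planted_stride_time_sd_recovered(self):
        # sampling-theory check: SD-Str-T estimates sigma within 2 sigma/sqrt(2n)
        sigma = 0.04
        p = make_params(stride_time_sd={"L": sigma, "R": sigma})
        vals = []
        for rep in range(8):
            out = gait_summary(self._tables(p, seed0=100 * rep))
            vals.append(out["GA:SD-Str-T-L"])
        n = 30  # pooled retained strides per foot
        assert np.mean(vals) == pytest.approx(sigma, abs=2 * sigma / np.sqrt(2 * n))

    def test_too_few_strides_sets_measures_missing(self, quiet_params):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tables = self._tables(quiet_params, n_walks=1)
            tables[0].strides = tables[0].strides.iloc[:3]
            assert gait_summary(tables) == {}


class TestAssembly:
    def test_subject_without_sway_trials_gets_missing_qs_columns(self, tiny_spec):
        from fallrisk.features import assemble_feature_table, extract_subject
        from fallrisk.synthetic import iter_cohort

        rec, _ = next(iter_cohort(tiny_spec))
        trials = [t for t in rec.trials if t.modality != "cop"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vals = extract_subject(trials)
        table = assemble_feature_table({rec.params.subject_id: vals})
        qs = [c for c in table.columns if c.startswith("QS:")]
        ga = [c for c in table.columns if c.startswith("GA:")]
        assert table[qs].isna().all().all()
        assert table[ga].notna().all().all()

    def test_registry_override_restricts_columns(self):
        from fallrisk.features import assemble_feature_table
        from fallrisk.registry import default_registry

        gait_only = [m for m in default_registry() if m.domain == "GA"]
        table = assemble_feature_table({"S001": {"GA:Mn-CAD": 100.0}}, gait_only)
        assert table.shape == (1, 44)
        assert all(c.startswith("GA:") for c in table.columns)

    def test_duplicate_subject_rejected(self):
        from fallrisk.features import assemble_feature_table

        class TwoKeys(dict):  # a mapping yielding a repeated subject id
            def __iter__(self):
                return iter(["S1", "S1"])

        with pytest.raises(ValueError, match="duplicate"):
            assemble_feature_table(TwoKeys(S1={}))


class TestPipelineInvariances:
    def test_marker_translation_changes_nothing(self, quiet_params):
        trial, _ = generate_gait_trial(quiet_params, 0, seed=9)
        shifted = trial.copy_with(
            {k: v + (3.0 if k.endswith("_x") else 0.0) for k, v in trial.channels.items()}
        )
        t0 = stride_parameters(detect_gait_events(trial), trial)
        t1 = stride_parameters(detect_gait_events(shifted), shifted)
        pd.testing.assert_frame_equal(t0.strides, t1.strides, atol=1e-9)

    def test_half_speed_doubles_times_keeps_lengths_and_cv(self):
        p = make_params(stride_time_sd={"L": 0.02, "R": 0.02},
                        marker_noise_sd=0.0)
        cfg = ExtractionConfig(min_strides_per_foot=3)
        fast_tables, slow_tables = [], []
        for w in range(4):
            trial, _ = generate_gait_trial(p, w, seed=21 + w, rate=200.0)
            slowed = RawTrial(
                trial_id=trial.trial_id, subject_id=trial.subject_id,
                modality=trial.modality, condition=trial.condition,
                rate=trial.rate / 2,  # same samples played at half speed
                channels=trial.channels, units=trial.units,
            )
            fast_tables.append(stride_parameters(detect_gait_events(trial, cfg), trial, cfg))
            slow_tables.append(stride_parameters(detect_gait_events(slowed, cfg), slowed, cfg))
        fast = gait_summary(fast_tables, cfg)
        slow = gait_summary(slow_tables, cfg)
        # event indices shift by at most ~1 sample (the low-pass cutoff is
        # fixed in absolute Hz), so the doubling is exact to quantization
        assert slow["GA:Mn-Str-T-L"] == pytest.approx(2 * fast["GA:Mn-Str-T-L"], rel=2e-3)
        assert slow["GA:SD-Str-T-R"] == pytest.approx(2 * fast["GA:SD-Str-T-R"], rel=0.1)
        assert slow["GA:Mn-Str-Len-L"] == pytest.approx(fast["GA:Mn-Str-Len-L"], rel=1e-3)
        assert slow["GA:CV-Str-T-L"] == pytest.approx(fast["GA:CV-Str-T-L"], rel=0.1)
        assert slow["GA:Mn-CAD"] == pytest.approx(fast["GA:Mn-CAD"] / 2, rel=2e-3)
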
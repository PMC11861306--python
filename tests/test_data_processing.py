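"""Torque-processing pipeline: normalization, scale fitting, rates, regression."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from fourccr import (
    fatigue_rates,
    load_torque_csv,
    normalize_phase,
    process_dataset,
    process_session,
    representative_scale,
    subject_curve,
    velocity_regression,
)
from fourccr.data_processing import (
    fatigue_rate_frame,
    fatigue_rate_table,
    majority_subset_size,
    strength_frame,
)
from fourccr.synthetic_data import generate_session


class TestNormalizePhase:
    def test_divides_by_phase_maximum(self):
        out = normalize_phase([40, 50, 45, 35, 30, 25])
        assert np.allclose(out, [0.8, 1.0, 0.9, 0.7, 0.6, 0.5])

    def test_constant_input_maps_to_ones(self):
        assert np.allclose(normalize_phase([7, 7, 7]), 1.0)

    def test_exactly_one_maximum_unless_tied(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = rng.uniform(10, 80, size=6)
            out = normalize_phase(t)
            assert (out == 1.0).sum() == 1
            assert np.all((out > 0) & (out <= 1))

    def test_rejects_sensor_artifacts(self):
        with pytest.raises(ValueError):
            normalize_phase([40, -5, 30, 20, 10, 5])
        with pytest.raises(ValueError):
            normalize_phase([40])


class TestSubjectCurve:
    def test_idempotent_on_identical_sets(self):
        s = [0.8, 1.0, 0.9]
        assert np.allclose(subject_curve([s] * 5), s)

    def test_arithmetic_mean_across_phases(self):
        sets = [[1, 0.5], [1, 0.7], [1, 0.6], [1, 0.6], [1, 0.6]]
        assert np.allclose(subject_curve(sets), [1, 0.6])

    def test_rejects_mismatched_stop_sets(self):
        with pytest.raises(ValueError):
            subject_curve([[1, 0.5], [1, 0.7, 0.6], [1, 0.6], [1, 0.6], [1, 0.6]])
        with pytest.raises(ValueError):
            subject_curve([[1, 0.5]] * 4)


class TestRepresentativeScale:
    def test_noiseless_proportionality_recovers_exact_scale(self):
        curve = np.array([0.5, 0.8, 1.0, 0.9, 0.7, 0.55])
        s, _, rss = representative_scale(curve, 55.0 * curve)
        assert s == pytest.approx(55.0, abs=1e-12)
        assert rss == pytest.approx(0.0, abs=1e-18)

    def test_exact_ties_broken_by_lowest_lexicographic_subset(self):
        # powers of two make every subset's residual exactly 0.0
        curve = np.array([1.0, 0.5, 0.25, 0.5, 1.0])
        s, subset, rss = representative_scale(curve, 8.0 * curve)
        assert s == 8.0 and rss == 0.0
        assert subset == (0, 1, 2)

    def test_majority_subset_sizes(self):
        assert majority_subset_size(6) == 4
        assert majority_subset_size(5) == 3

    def test_candidate_count_matches_combinatorics(self):
        # n = 6 stops -> C(6, 4) = 15 candidate subsets; verify the chosen
        # subset is the brute-force least-squares winner
        rng = np.random.default_rng(3)
        curve = rng.uniform(0.5, 1.0, size=6)
        raw = 40 * curve + rng.normal(0, 2.0, size=6)
        s, subset, rss = representative_scale(curve, raw)
        cands = list(combinations(range(6), 4))
        assert len(cands) == 15

        def fit(sub):
            c, y = curve[list(sub)], raw[list(sub)]
            sc = (y @ c) / (c @ c)
            r = y - sc * c
            return float(r @ r), sc

        best = min(cands, key=lambda sub: fit(sub)[0])
        assert subset == best
        assert s == pytest.approx(fit(best)[1])
        assert rss == pytest.approx(fit(best)[0])

    def test_true_scale_recovered_despite_corrupted_minority(self):
        # 5 stops: majority subset is 3; corrupt floor(5/2) = 2 stops and an
        # uncorrupted subset still exists and wins with zero residual
        curve = np.array([0.6, 0.85, 1.0, 0.9, 0.7])
        raw = 70.0 * curve
        raw[1] *= 1.8
        raw[3] *= 0.4
        s, subset, rss = representative_scale(curve, raw)
        assert s == pytest.approx(70.0, abs=1e-9)
        assert subset == (0, 2, 4)

    def test_deterministic_on_repeated_runs(self):
        rng = np.random.default_rng(7)
        curve = rng.uniform(0.4, 1.0, size=6)
        raw = 30 * curve + rng.normal(0, 1, size=6)
        results = {representative_scale(curve, raw) for _ in range(5)}
        assert len(results) == 1

    def test_rejects_mismatched_or_tiny_inputs(self):
        with pytest.raises(ValueError):
            representative_scale([1.0, 0.5], [10.0, 5.0])
        with pytest.raises(ValueError):
            representative_scale([1.0, 0.5, 0.4], [10.0, 5.0])


class TestFatigueRates:
    def test_declines_in_percent_mvc_per_minute(self):
        rates = fatigue_rates([1.0, 0.9, 0.85, 0.82, 0.80])
        assert np.allclose(rates, [10, 5, 3, 2])

    def test_constant_strength_gives_zero_rates(self):
        assert np.allclose(fatigue_rates([55.0] * 5), 0.0)

    def test_normalized_by_first_phase_scale(self):
        # same relative declines, different absolute torques -> same rates
        a = fatigue_rates([100, 90, 85, 82, 80])
        b = fatigue_rates([200, 180, 170, 164, 160])
        assert np.allclose(a, b)

    def test_negative_declines_preserved(self):
        rates = fatigue_rates([1.0, 1.05, 0.9, 0.9, 0.85])
        assert rates[0] == pytest.approx(-5.0)


class TestVelocityRegression:
    def test_perfect_line_recovered(self):
        v = np.array([20, 30, 45, 60, 75], dtype=float)
        fit = velocity_regression(v, 0.001 * v + 0.02)
        assert fit["slope"] == pytest.approx(0.001)
        assert fit["p_value"] < 1e-10
        assert fit["ci_high"] - fit["ci_low"] < 1e-9

    def test_flat_rates_give_zero_slope(self):
        fit = velocity_regression([30, 60, 90, 120], [2.0, 2.0, 2.0, 2.0])
        assert fit["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        v = np.repeat([20.0, 30.0, 45.0, 60.0, 75.0], 4)
        y = 0.05 * v + rng.normal(0, 0.5, size=v.size)
        fit = velocity_regression(v, y)
        X = np.column_stack([np.ones_like(v), v])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit["slope"] == pytest.approx(beta[1], abs=1e-12)
        assert fit["intercept"] == pytest.approx(beta[0], abs=1e-12)

    def test_needs_three_distinct_velocities(self):
        with pytest.raises(ValueError):
            velocity_regression([30, 30, 60, 60], [1, 2, 3, 4])


@pytest.fixture(scope="module")
def noiseless_session(study_specs):
    spec = study_specs["knee_extensors"]
    df, traj, truth = generate_session(spec, 90.0)
    return df, traj, truth


class TestSessionPipeline:
    def test_scale_invariance_of_rates(self, noiseless_session):
        df, _, _ = noiseless_session
        scaled = df.copy()
        scaled["peak_torque_Nm"] *= 3.7
        s1 = process_session(df)
        s2 = process_session(scaled)
        assert np.allclose(s2.scales, 3.7 * s1.scales)
        assert np.allclose(fatigue_rates(s1.scales), fatigue_rates(s2.scales))

    def test_noiseless_closure_against_model_capacity(self, noiseless_session):
        df, _, truth = noiseless_session
        series = process_session(df)
        caps = np.array(truth["phase_capacities"])
        assert np.abs(series.normalized - caps).max() <= 1e-6
        rates = fatigue_rates(series.scales)
        assert np.allclose(rates, 100 * (caps[:-1] - caps[1:]), atol=1e-6)

    def test_dataset_split_and_summary_tables(self, study_specs):
        frames = []
        for v in (60.0, 120.0):
            df, _, _ = generate_session(study_specs["knee_flexors"], v)
            frames.append(df)
        data = pd.concat(frames, ignore_index=True)
        series = process_dataset(data)
        assert len(series) == 2
        rates = fatigue_rate_frame(series)
        assert set(rates["iteration"]) == {"ISOK1", "ISOK2", "ISOK3", "ISOK4"}
        table = fatigue_rate_table(rates)
        assert len(table) == 8  # 1 group x 2 velocities x 4 iterations
        assert (table["n"] == 1).all()
        strengths = strength_frame(series)
        assert len(strengths) == 10

    def test_csv_schema_violations_cite_the_row(self, tmp_path, study_specs):
        df, _, _ = generate_session(study_specs["hip_flexors"], 45.0)
        df.loc[3, "peak_torque_Nm"] = -2.0
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="row 3"):
            load_torque_csv(path)
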
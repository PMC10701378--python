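"""Kalman predictive gate: textbook-recursion oracle, worked examples, properties."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from hotwalk import (StateSpaceConfig, ValidationError,
                     detect_outliers, generate_trajectory, kalman_predictive,
                     summarize_outliers)
from hotwalk.outliers import OutlierResult, _runs_from_flags

from conftest import make_traj, random_walk

CHI2_95 = sps.chi2.ppf(0.95, 2)


def matrix_filter_oracle(traj, cfg):
    """Independent full 4x4 textbook predict/update recursion.

    Returns per-sample predictive means, 2x2 predictive covariances and the
    95%-ellipse membership flags.
    """
    dt_seq = np.diff(traj.t)
    H = np.array([[1.0, 0, 0, 0], [0, 0, 1.0, 0]])
    R = cfg.r * np.eye(2)
    x = np.array([traj.xy[0, 0], 0.0, traj.xy[0, 1], 0.0])
    P = cfg.init_cov_scale * np.eye(4)
    thresh = sps.chi2.ppf(cfg.gate_level, 2)
    n = len(traj)
    means = np.full((n, 2), np.nan)
    covs = np.full((n, 2, 2), np.nan)
    flags = np.zeros(n, dtype=bool)
    for k in range(1, n):
        dt = dt_seq[k - 1]
        F = np.eye(4)
        F[0, 1] = F[2, 3] = dt
        qblock = cfg.q * np.array([[dt ** 3 / 3, dt ** 2 / 2],
                                   [dt ** 2 / 2, dt]])
        Q = np.zeros((4, 4))
        Q[:2, :2] = qblock
        Q[2:, 2:] = qblock
        x = F @ x
        P = F @ P @ F.T + Q
        S = H @ P @ H.T + R
        z = traj.xy[k]
        innov = z - H @ x
        means[k] = H @ x
        covs[k] = S
        flags[k] = innov @ np.linalg.solve(S, innov) > thresh
        K = P @ H.T @ np.linalg.inv(S)
        x = x + K @ innov
        P = (np.eye(4) - K @ H) @ P
    return means, covs, flags


def cv_trajectory(n=120, v=(0.4, -0.2), rate=13.0):
    t = np.arange(n) / rate
    xy = np.column_stack([1.0 + v[0] * t, 3.0 + v[1] * t])
    return make_traj(xy, t=t)


class TestPredictive:
    def test_matches_textbook_recursion_on_hand_series(self):
        xy = [(0.0, 0.0), (0.1, 0.05), (0.18, 0.12), (0.31, 0.14), (0.4, 0.2)]
        tr = make_traj(xy, rate=13.0)
        cfg = StateSpaceConfig(q=0.3, r=2e-3, init_cov_scale=10.0)
        means, covs = kalman_predictive(tr, cfg)
        o_means, o_covs, _ = matrix_filter_oracle(tr, cfg)
        assert np.allclose(means[1:], o_means[1:], atol=1e-10)
        assert np.allclose(covs[1:], o_covs[1:], atol=1e-10)
        assert np.all(np.isnan(means[0]))

    def test_noise_free_cv_predictions_converge_to_observations(self):
        tr = cv_trajectory(200)
        cfg = StateSpaceConfig(q=0.8, r=1e-12)
        means, _ = kalman_predictive(tr, cfg)
        err = np.hypot(*(tr.xy[50:] - means[50:]).T)
        assert err.max() < 1e-6

    def test_stationary_input_converges_to_position(self):
        tr = make_traj([(2.0, 1.0)] * 100, rate=13.0)
        means, _ = kalman_predictive(tr)
        assert np.allclose(means[-1], [2.0, 1.0], atol=1e-6)

    def test_predictive_covariances_positive_definite(self):
        tr = random_walk(150, seed=4)
        _, covs = kalman_predictive(tr)
        assert np.all(covs[1:, 0, 0] > 0)
        assert np.all(np.linalg.eigvalsh(covs[1:]) > 0)


class TestGate:
    def test_noise_free_cv_has_no_outliers(self):
        assert detect_outliers(cv_trajectory()).n_outliers == 0

    def test_single_displaced_sample_flagged_exactly(self):
        """A 1 m jump in an otherwise perfect constant-velocity walk is the
        only gated sample when the filter barely trusts its model (tiny q)."""
        tr = cv_trajectory(150)
        xy = tr.xy.copy()
        k_disp = 80
        xy[k_disp] += (0.7, -0.7)
        bumped = make_traj(xy, t=tr.t)
        cfg = StateSpaceConfig(q=1e-6, r=1e-2)
        res = detect_outliers(bumped, cfg)
        assert list(np.nonzero(res.flags)[0]) == [k_disp]
        assert res.runs == [(k_disp, k_disp)]
        # cross-check the Mahalanobis exceedance directly
        means, covs = kalman_predictive(bumped, cfg)
        innov = bumped.xy[k_disp] - means[k_disp]
        m2 = innov @ np.linalg.solve(covs[k_disp], innov)
        assert m2 > CHI2_95

    def test_gate_level_approaching_one_empties_the_gate(self):
        tr = random_walk(200, seed=12, step=0.05)
        counts = [detect_outliers(tr, StateSpaceConfig(gate_level=g)).n_outliers
                  for g in (0.95, 1 - 1e-12)]
        assert counts[0] >= counts[1] and counts[1] == 0

    def test_gate_level_monotone(self):
        tr = random_walk(300, seed=2, step=0.1)
        counts = [detect_outliers(tr, StateSpaceConfig(gate_level=g)).n_outliers
                  for g in (0.5, 0.9, 0.95, 0.99)]
        assert counts == sorted(counts, reverse=True)

    def test_measurement_noise_monotone(self):
        tr = random_walk(300, seed=2, step=0.1)
        counts = [detect_outliers(tr, StateSpaceConfig(r=r)).n_outliers
                  for r in (1e-5, 1e-4, 1e-3, 1e-2)]
        assert counts == sorted(counts, reverse=True)

    def test_flags_equal_ellipse_membership_oracle(self, phenotypes):
        """Gate decisions must equal explicit 95% predictive-ellipse tests."""
        inputs = [random_walk(200, seed=s, step=0.06) for s in (1, 2)]
        sim = generate_trajectory(phenotypes["AD"], seed=3, group="AD")
        inputs.append(make_traj(sim.xy[:200], t=sim.t[:200]))
        for tr in inputs:
            cfg = StateSpaceConfig()
            _, _, oracle_flags = matrix_filter_oracle(tr, cfg)
            res = detect_outliers(tr, cfg)
            assert np.array_equal(res.flags, oracle_flags)

    def test_config_validation(self):
        for kwargs in ({"q": 0}, {"r": -1}, {"gate_level": 1.0},
                       {"gate_on": "posterior"}):
            with pytest.raises(ValidationError):
                StateSpaceConfig(**kwargs)

    def test_smoothed_gate_runs(self):
        tr = random_walk(150, seed=8, step=0.05)
        res = detect_outliers(tr, StateSpaceConfig(gate_on="smoothed"))
        assert len(res.flags) == len(tr) and not res.flags[0]


class TestRuns:
    def test_runs_match_groupby_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            flags = rng.random(80) < 0.3
            expect = []
            pos = 0
            for val, grp in itertools.groupby(flags):
                ln = len(list(grp))
                if val:
                    expect.append((pos, pos + ln - 1))
                pos += ln
            assert _runs_from_flags(flags) == expect

    def test_run_lengths_sum_to_flag_count(self):
        tr = random_walk(400, seed=5, step=0.12)
        res = detect_outliers(tr, StateSpaceConfig(gate_level=0.6))
        assert sum(b - a + 1 for a, b in res.runs) == res.n_outliers
        for (a1, b1), (a2, b2) in zip(res.runs, res.runs[1:]):
            assert b1 + 1 < a2 or (b1 < a2)  # disjoint and maximal

    def test_summarize_examples(self):
        empty = OutlierResult(np.zeros(10, bool), [], [])
        assert summarize_outliers(empty) == (0, 0.0)
        two = OutlierResult(
            np.array([False, True, True, False, True, True, True, False]),
            [(1, 2), (4, 6)], [0.4, 0.6])
        n, mean_run = summarize_outliers(two)
        assert n == 5 and mean_run == pytest.approx(0.5)
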
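import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dagoat.model import (
    DaGOAT,
    ModelConfig,
    _theta_bins,
    best_cutoff,
    fit_bin_probs,
    fit_thresholds,
    smooth_probs,
    theta,
    window_labels,
)
from dagoat.model import DynamicFeatureParams, LOW, MID, HIGH
from conftest import make_cohort


def brute_force_cutoff(values, labels):
    """Exhaustive MI maximization via sklearn, smallest candidate on ties."""
    from sklearn.metrics import mutual_info_score

    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if y.min() == y.max() or np.unique(v).size < 2:
        return np.nan
    sv = np.unique(v)
    best, best_mi = np.nan, -1.0
    for c in (sv[:-1] + sv[1:]) / 2:
        mi = mutual_info_score(y, (v > c).astype(int))
        if mi > best_mi + 1e-12:
            best, best_mi = c, mi
    return best


class TestWindowLabels:
    def _cohort(self, onset):
        vals = np.zeros((1, 1, 40))
        return make_cohort(vals, np.ones_like(vals), [onset])

    @pytest.mark.parametrize(
        "onset, t, in_risk, y",
        [
            (10, 10, False, False),  # onset on t: already excluded
            (11, 10, True, True),    # boundary t+1
            (25, 10, True, False),   # t+delta+1 just outside
            (24, 10, True, True),    # t+delta inside
            (None, 10, True, False),
        ],
    )
    def test_boundaries(self, onset, t, in_risk, y):
        at_risk, lab = window_labels(self._cohort(onset), t, delta=14)
        assert at_risk[0] == in_risk
        assert lab[0] == y

    def test_left_observation(self):
        cohort = make_cohort(np.zeros((1, 1, 40)), np.ones((1, 1, 40)),
                             [None], last_observed=[15])
        at_risk, _ = window_labels(cohort, 20, delta=14)
        assert not at_risk[0]


class TestBestCutoff:
    def test_perfect_separation(self):
        v = np.array([1, 2, 3, 4.0])
        y = np.array([0, 0, 1, 1])
        assert best_cutoff(v, y) == pytest.approx(2.5)

    def test_degenerate(self):
        assert np.isnan(best_cutoff([3, 3, 3], [0, 1, 0]))
        assert np.isnan(best_cutoff([1, 2, 3], [1, 1, 1]))

    def test_matches_exhaustive_search(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 31))
            v = rng.normal(size=n)
            y = rng.integers(0, 2, n)
            got = best_cutoff(v, y)
            want = brute_force_cutoff(v, y)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want)

    def test_tied_maxima_reach_the_same_information(self, rng):
        # rounded values provoke exact MI ties; the achieved maximum must
        # agree with the exhaustive search even if the argmax differs
        from sklearn.metrics import mutual_info_score

        for _ in range(100):
            n = int(rng.integers(4, 31))
            v = np.round(rng.normal(size=n), 1)
            y = rng.integers(0, 2, n)
            got, want = best_cutoff(v, y), brute_force_cutoff(v, y)
            if np.isnan(want):
                assert np.isnan(got)
                continue
            mi = lambda c: mutual_info_score(y, (v > c).astype(int))
            assert mi(got) == pytest.approx(mi(want), abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_property_random_instances(self, seed):
        r = np.random.default_rng(seed)
        v = r.normal(size=int(r.integers(2, 25)))
        y = r.integers(0, 2, v.size)
        got, want = best_cutoff(v, y), brute_force_cutoff(v, y)
        assert (np.isnan(got) and np.isnan(want)) or got == pytest.approx(want)


class TestFitThresholds:
    def test_constant(self):
        l, u = fit_thresholds([5.0] * 30)
        assert l == u == 5.0

    def test_linear_interpolation_convention(self):
        l, u = fit_thresholds([1, 2, 3, 4, np.nan])
        assert (l, u) == pytest.approx((1.75, 3.25))

    def test_all_undefined(self):
        l, u = fit_thresholds([np.nan, np.nan])
        assert np.isnan(l) and np.isnan(u)


class TestFitBinProbs:
    def test_all_below(self):
        # 3 positives observed on day 1, all below l
        values = np.array([[0.1], [0.2], [0.3], [9.0]])
        mask = np.ones_like(values, dtype=bool)
        at_risk = np.ones_like(values, dtype=bool)
        y = np.array([[True], [True], [True], [False]])
        probs = fit_bin_probs(values, mask, at_risk, y, l=1.0, u=5.0)
        assert probs[0, 0] == 1.0  # rho1_low
        assert probs[1, 0] == 0.0  # rho1_high
        assert probs[2, 0] == 0.0  # rho0_low (9 > u)
        assert probs[3, 0] == 1.0

    def test_empty_class_undefined(self):
        values = np.array([[0.1], [0.2]])
        mask = np.ones_like(values, dtype=bool)
        at_risk = mask.copy()
        y = np.zeros_like(mask)
        probs = fit_bin_probs(values, mask, at_risk, y, 1.0, 5.0)
        assert np.isnan(probs[0, 0]) and np.isnan(probs[1, 0])
        assert np.isfinite(probs[2, 0])

    def test_counting_oracle(self, rng):
        n, H = 30, 6
        values = rng.normal(size=(n, H))
        mask = rng.random((n, H)) < 0.7
        at_risk = rng.random((n, H)) < 0.9
        y = (rng.random((n, H)) < 0.3) & at_risk
        l, u = -0.5, 0.5
        probs = fit_bin_probs(values, mask, at_risk, y, l, u)
        for d in range(H):
            for cls, rows in ((1, (0, 1)), (0, (2, 3))):
                in_cls = y[:, d] if cls == 1 else (at_risk[:, d] & ~y[:, d])
                obs = mask[:, d] & at_risk[:, d] & in_cls
                if obs.sum() == 0:
                    assert np.isnan(probs[rows[0], d])
                    continue
                assert probs[rows[0], d] == pytest.approx(
                    (values[obs, d] < l).mean())
                assert probs[rows[1], d] == pytest.approx(
                    (values[obs, d] > u).mean())


class TestSmoothProbs:
    def test_constant_preserved(self):
        out = smooth_probs(np.full(50, 0.4))
        np.testing.assert_allclose(out, 0.4)

    def test_extrapolates_to_full_horizon(self, rng):
        raw = np.full(100, np.nan)
        raw[9:90] = 0.3 + 0.1 * np.sin(np.arange(81) / 10) + rng.normal(0, 0.01, 81)
        out = smooth_probs(raw)
        assert np.isfinite(out).all()
        assert out.shape == (100,)

    def test_variation_reduction_on_noisy_sinusoid(self, rng):
        days = np.arange(100)
        raw = 0.5 + 0.2 * np.sin(days / 8) + rng.normal(0, 0.15, 100)
        out = smooth_probs(raw)
        tv = lambda a: np.abs(np.diff(a)).sum()
        assert tv(out) <= tv(raw)

    def test_sparse_fallback_constant_mean(self):
        raw = np.full(30, np.nan)
        raw[[3, 10, 20]] = [0.2, 0.4, 0.6]
        out = smooth_probs(raw)
        np.testing.assert_allclose(out, 0.4)

    def test_empty_all_nan(self):
        assert np.isnan(smooth_probs(np.full(20, np.nan))).all()


class TestTheta:
    def _params(self, probs):
        return DynamicFeatureParams(
            l=0.0, u=1.0, per_day_cutoffs=np.zeros(1),
            raw_probs=probs, smooth_probs=probs,
        )

    def test_identical_distributions_zero(self):
        probs = np.array([[0.3], [0.2], [0.3], [0.2]])
        p = self._params(probs)
        for x in (-1.0, 0.5, 2.0):
            assert theta(x, 1, p, gamma=0.1) == 0.0

    def test_direct_arithmetic(self):
        probs = np.array([[0.5], [0.1], [0.15], [0.1]])
        p = self._params(probs)
        assert theta(-1.0, 1, p, gamma=0.1) == pytest.approx(np.log(0.6 / 0.25))

    def test_clamp_spline_undershoot(self):
        probs = np.array([[-0.02], [0.1], [0.3], [0.1]])
        p = self._params(probs)
        assert theta(-1.0, 1, p, gamma=0.1) == pytest.approx(np.log(0.1 / 0.4))

    @given(st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_antisymmetry_under_class_swap(self, seed):
        r = np.random.default_rng(seed)
        p1l, p1h, p0l, p0h = r.uniform(-0.1, 1.0, 4)
        g = float(r.uniform(0.01, 1.0))
        forward = _theta_bins(p1l, p1h, p0l, p0h, g)
        swapped = _theta_bins(p0l, p0h, p1l, p1h, g)
        np.testing.assert_allclose(forward, -swapped, atol=1e-12)

    def test_undefined_raw_gives_zero_without_smoothing(self):
        probs = np.array([[np.nan], [0.3], [0.2], [0.1]])
        p = self._params(probs)
        assert theta(-1.0, 1, p, gamma=0.1, smoothing=False) == 0.0
        assert theta(2.0, 1, p, gamma=0.1, smoothing=False) == pytest.approx(
            np.log(0.4 / 0.2))


def _toy_cohort(rng, n=40, p=3, H=30, seed_peri=True):
    mask = rng.random((n, p, H)) < 0.6
    values = np.where(mask, rng.normal(size=(n, p, H)), 0.0)
    onsets = [int(rng.integers(5, H)) if rng.random() < 0.3 else None for _ in range(n)]
    peri = {"g": [["a", "b"][int(rng.integers(2))] for _ in range(n)]} if seed_peri else None
    return make_cohort(values, mask, onsets, peri=peri)


class TestFit:
    def test_refit_deterministic(self, rng):
        cohort = _toy_cohort(rng)
        m1 = DaGOAT(horizon=30).fit(cohort)
        m2 = DaGOAT(horizon=30).fit(cohort)
        np.testing.assert_array_equal(m1.theta_table_, m2.theta_table_)
        assert m1.to_json() == m2.to_json()

    def test_all_missing_feature_uninformative(self, rng):
        cohort = _toy_cohort(rng)
        cohort.panel.mask[:, 1, :] = False
        m = DaGOAT(horizon=30).fit(cohort)
        assert not m.features_["f1"].informative
        np.testing.assert_array_equal(m.theta_table_[1], 0.0)
        # other features unaffected by the dead one
        reduced = cohort.select_features(["f0", "f2"])
        m2 = DaGOAT(horizon=30).fit(reduced)
        np.testing.assert_allclose(m.theta_table_[[0, 2]], m2.theta_table_)

    def test_zero_events_rejected(self, rng):
        cohort = _toy_cohort(rng)
        cohort.outcomes["onset_day"] = None
        with pytest.raises(ValueError):
            DaGOAT(horizon=30).fit(cohort)


class TestScore:
    def test_all_missing_scores_to_prior(self, rng):
        cohort = _toy_cohort(rng)
        m = DaGOAT(horizon=30).fit(cohort)
        blank = cohort.subset_patients(range(cohort.n_patients))
        blank.panel.mask[:] = False
        prior = m._prior(blank)
        np.testing.assert_allclose(m.predict_score(blank, 20), prior)

    def test_window_truncated_at_day_one(self, rng):
        cohort = _toy_cohort(rng)
        m = DaGOAT(horizon=30).fit(cohort)
        # at t=1 only day 1 contributes: blanking days 2.. changes nothing
        other = cohort.subset_patients(range(cohort.n_patients))
        other.panel.mask[:, :, 1:] = False
        np.testing.assert_allclose(
            m.predict_score(cohort, 1), m.predict_score(other, 1))

    def test_manual_summation(self):
        r = np.random.default_rng(5)
        cohort = _toy_cohort(r, n=20, p=2, H=10)
        m = DaGOAT(delta=3, horizon=10).fit(cohort)
        t = 7
        got = m.predict_score(cohort, t)
        prior = m._prior(cohort)
        for i in range(cohort.n_patients):
            total = prior[i]
            for k, name in enumerate(m.feature_names_):
                for tau in (5, 6, 7):
                    if cohort.panel.mask[i, k, tau - 1]:
                        total += theta(cohort.panel.values[i, k, tau - 1], tau,
                                       m.features_[name], m.gamma, m.smoothing)
            assert got[i] == pytest.approx(total)

    def test_trajectories_match_per_day_scores(self, rng):
        cohort = _toy_cohort(rng)
        m = DaGOAT(horizon=30).fit(cohort)
        traj = m.predict_trajectories(cohort)
        for t in (1, 5, 17, 30):
            np.testing.assert_allclose(traj.scores[:, t - 1],
                                       m.predict_score(cohort, t))

    def test_valid_flags_follow_risk_set(self, rng):
        cohort = _toy_cohort(rng, n=10)
        cohort.outcomes.iloc[0, 0] = 20  # onset day 20
        m = DaGOAT(horizon=30).fit(cohort)
        traj = m.predict_trajectories(cohort)
        assert not traj.valid[0, 19:].any()
        assert traj.valid[0, :19].all()

    def test_translation_covariance(self):
        r = np.random.default_rng(9)
        n, p, H, s = 30, 2, 20, 4
        mask = r.random((n, p, H)) < 0.7
        values = np.where(mask, r.normal(size=(n, p, H)), 0.0)
        onsets = [int(r.integers(4, H)) if r.random() < 0.4 else None for _ in range(n)]
        base = make_cohort(values, mask, onsets)
        sh_vals = np.zeros((n, p, H + s))
        sh_mask = np.zeros((n, p, H + s), dtype=bool)
        sh_vals[:, :, s:], sh_mask[:, :, s:] = values, mask
        shifted = make_cohort(sh_vals, sh_mask,
                              [None if o is None else o + s for o in onsets],
                              last_observed=[H + s] * n)
        m0 = DaGOAT(delta=5, smoothing=False, horizon=H).fit(base)
        m1 = DaGOAT(delta=5, smoothing=False, horizon=H + s).fit(shifted)
        t0 = m0.predict_trajectories(base).scores
        t1 = m1.predict_trajectories(shifted).scores
        np.testing.assert_allclose(t1[:, s:], t0, atol=1e-10)

    def test_prior_dominance_large_gamma(self, rng):
        cohort = _toy_cohort(rng)
        m = DaGOAT(gamma=1e9, smoothing=False, horizon=30).fit(cohort)
        prior = m._prior(cohort)
        np.testing.assert_allclose(m.predict_score(cohort, 20), prior, atol=1e-6)

    def test_feature_mismatch_rejected(self, rng):
        cohort = _toy_cohort(rng)
        m = DaGOAT(horizon=30).fit(cohort)
        with pytest.raises(ValueError):
            m.predict_score(cohort.select_features(["f1", "f0", "f2"]), 5)


def test_json_round_trip_bit_exact(rng):
    cohort = _toy_cohort(rng)
    m = DaGOAT(horizon=30).fit(cohort)
    m2 = DaGOAT.from_json(m.to_json())
    np.testing.assert_array_equal(m2.theta_table_, m.theta_table_)
    np.testing.assert_array_equal(
        m2.predict_trajectories(cohort).scores,
        m.predict_trajectories(cohort).scores,
    )


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(delta=0)
    with pytest.raises(ValueError):
        ModelConfig(gamma=-0.1)
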
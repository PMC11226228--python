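"""Selection, contrast and latency statistics: formula oracles, permutation
behaviour, and jackknife properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import riftpipe as rp
from riftpipe.events import EpochSet
from riftpipe.spectral import analytic_recordings
from riftpipe.tagstats import (
    coherence_bias,
    equalize_trials,
    half_max_latency,
    jackknife_latency_difference,
    mean_coherence_in_min_fixation_window,
    min_fixation_window,
    paired_condition_test,
    permutation_select_sensors,
    z_coherence_diff,
)


class TestCoherenceBias:
    @pytest.mark.parametrize("n,expected", [(2, 0.5), (51, 0.01), (11, 0.05)])
    def test_values(self, n, expected):
        assert coherence_bias(n) == pytest.approx(expected, abs=1e-15)

    def test_monotone_to_zero(self):
        ns = np.arange(2, 200)
        vals = np.array([coherence_bias(n) for n in ns])
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] < 0.003

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            coherence_bias(1)


class TestZCoherenceDiff:
    def test_symmetric_cancellation(self):
        assert z_coherence_diff(0.4, 30, 0.4, 30) == pytest.approx(0.0, abs=1e-15)

    def test_formula_oracle(self):
        # value frozen from an independent direct evaluation of the formula
        assert z_coherence_diff(0.3, 50, 0.1, 50) == pytest.approx(
            1.4642897953042526, abs=1e-12
        )

    def test_monotone_in_coh1(self):
        vals = [z_coherence_diff(c, 40, 0.2, 40) for c in np.linspace(0.0, 0.9, 30)]
        assert np.all(np.diff(vals) > 0)

    @given(
        c1=st.floats(0.0, 0.95), c2=st.floats(0.0, 0.95),
        n1=st.integers(2, 500), n2=st.integers(2, 500),
    )
    def test_antisymmetry(self, c1, c2, n1, n2):
        assert z_coherence_diff(c1, n1, c2, n2) == pytest.approx(
            -z_coherence_diff(c2, n2, c1, n1), abs=1e-10
        )

    def test_coherence_one_rejected(self):
        with pytest.raises(ValueError, match="clip"):
            z_coherence_diff(1.0, 10, 0.5, 10)


def _analytic_epochs(n_epochs, n_channels, n_samples, rng, locked_channels=(),
                     amp=1.0, label="x"):
    """Complex analytic epochs: unit-magnitude random phases per trial; the
    listed channels are phase-locked to the photodiode with the given amp."""
    phases = rng.uniform(0, 2 * np.pi, size=(n_epochs, n_channels, 1))
    sensor = np.exp(1j * phases) * np.ones((n_epochs, n_channels, n_samples))
    noise = 0.7 * (
        rng.standard_normal(sensor.shape) + 1j * rng.standard_normal(sensor.shape)
    )
    sensor = sensor + noise
    photo = np.exp(1j * rng.uniform(0, 2 * np.pi, size=(n_epochs, 1)))
    photo = photo * np.ones((n_epochs, n_samples))
    for ch in locked_channels:
        sensor[:, ch, :] = amp * photo + 0.3 * noise[:, ch, :]
    meta = pd.DataFrame(
        {"subject_id": 0, "trial_id": np.arange(n_epochs),
         "condition": "congruent", "duration_ms": 200.0}
    )
    return EpochSet(label=label, window_s=(-0.5, 0.5), sample_rate_hz=1000.0,
                    sensor=sensor, photodiode=photo, meta=meta)


class TestPermutationSelection:
    def test_strong_tagging_selects_exactly_tagged_channels(self):
        rng = np.random.default_rng(5)
        pre = _analytic_epochs(40, 5, 200, rng, locked_channels=(1, 3))
        base = _analytic_epochs(40, 5, 200, rng)
        sel = permutation_select_sensors(
            pre, base, n_perm=200, alpha=0.01, seed=0, precomputed_analytic=True
        )
        assert set(sel.selected_channels) == {1, 3}

    def test_same_seed_identical(self, small_dataset, small_events):
        recs = analytic_recordings(small_dataset.recordings[0])
        sub = small_events[small_events.subject_id == 0]
        pre = rp.extract_epochs(recs, sub, -1)
        base = rp.extract_baseline_epochs(recs)
        a = permutation_select_sensors(pre, base, n_perm=120, seed=42,
                                       precomputed_analytic=True)
        b = permutation_select_sensors(pre, base, n_perm=120, seed=42,
                                       precomputed_analytic=True)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_pvalues_never_zero_and_selection_rule(self):
        rng = np.random.default_rng(6)
        pre = _analytic_epochs(20, 4, 100, rng, locked_channels=(0,))
        base = _analytic_epochs(20, 4, 100, rng)
        sel = permutation_select_sensors(pre, base, n_perm=150, seed=1,
                                         precomputed_analytic=True)
        assert (sel.table["p_perm"] > 0).all()
        assert (sel.table["selected"] == (sel.table["p_perm"] < sel.alpha)).all()

    def test_small_nperm_warns(self):
        rng = np.random.default_rng(7)
        pre = _analytic_epochs(10, 2, 50, rng)
        base = _analytic_epochs(10, 2, 50, rng)
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_select_sensors(pre, base, n_perm=50, seed=1,
                                       precomputed_analytic=True)

    def test_empty_candidate_set_rejected(self):
        rng = np.random.default_rng(8)
        pre = _analytic_epochs(10, 2, 50, rng)
        base = _analytic_epochs(10, 2, 50, rng)
        with pytest.raises(ValueError, match="candidate"):
            permutation_select_sensors(pre, base, candidate_channels=[],
                                       n_perm=100, seed=1,
                                       precomputed_analytic=True)

    def test_null_pvalues_roughly_uniform(self):
        """Under exchangeable no-signal inputs, permutation p-values spread
        over (0, 1] instead of clumping."""
        rng = np.random.default_rng(9)
        ps = []
        for r in range(12):
            pre = _analytic_epochs(15, 4, 60, rng)
            base = _analytic_epochs(15, 4, 60, rng)
            sel = permutation_select_sensors(pre, base, n_perm=200, seed=r,
                                             precomputed_analytic=True)
            ps.extend(sel.table["p_perm"].tolist())
        ps = np.asarray(ps)
        assert 0.3 < np.mean(ps) < 0.7
        assert (ps <= 0.25).mean() < 0.5


class TestEqualizeTrials:
    def test_counts_equalized(self):
        rng = np.random.default_rng(10)
        a = _analytic_epochs(40, 2, 30, rng)
        b = _analytic_epochs(36, 2, 30, rng)
        a2, b2 = equalize_trials(a, b, seed=0)
        assert len(a2) == len(b2) == 36

    def test_equal_counts_identity(self):
        rng = np.random.default_rng(11)
        a = _analytic_epochs(10, 2, 30, rng)
        b = _analytic_epochs(10, 2, 30, rng)
        a2, b2 = equalize_trials(a, b, seed=0)
        assert a2 is a and b2 is b

    def test_outputs_are_subsets(self):
        rng = np.random.default_rng(12)
        a = _analytic_epochs(25, 2, 30, rng)
        b = _analytic_epochs(12, 2, 30, rng)
        a2, _ = equalize_trials(a, b, seed=3)
        ids_a = set(a.meta["trial_id"])
        assert set(a2.meta["trial_id"]) <= ids_a


class TestMinFixationWindow:
    def test_window_from_pooled_durations(self):
        assert min_fixation_window(np.array([120.0, 97.0, 150.0])) == (0.0, 0.097)

    def test_constant_curve_returns_constant(self):
        times = np.arange(0, 1001) / 1000.0 - 0.5
        curve = np.full(1001, 0.42)
        out = mean_coherence_in_min_fixation_window(
            {"congruent": curve, "incongruent": curve},
            times,
            {"congruent": np.array([120.0]), "incongruent": np.array([97.0])},
        )
        assert out["congruent"] == pytest.approx(0.42)

    def test_window_excludes_post_fixation_samples(self):
        times = np.arange(0, 1001) / 1000.0 - 0.5
        curve = np.where(times <= 0.097, 0.5, 99.0)  # poison after min duration
        out = mean_coherence_in_min_fixation_window(
            {"congruent": curve},
            times,
            {"congruent": np.array([120.0]), "incongruent": np.array([97.0])},
        )
        assert out["congruent"] == pytest.approx(0.5)

    def test_too_short_window_rejected(self):
        times = np.arange(0, 101) / 100.0
        with pytest.raises(ValueError):
            mean_coherence_in_min_fixation_window(
                {"congruent": np.ones(101)}, times,
                {"congruent": np.array([0.5])},
            )


class TestPairedConditionTest:
    def test_identical_pairs(self):
        t, p, d = paired_condition_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_constant_nonzero_difference_flagged(self):
        t, p, d = paired_condition_test([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_null_calibration(self):
        """Random paired data under the null rejects at ~5%."""
        rng = np.random.default_rng(13)
        rejections = 0
        reps = 4000
        for _ in range(reps):
            a = rng.standard_normal(10)
            b = rng.standard_normal(10)
            _, p, _ = paired_condition_test(a, b)
            rejections += p < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)


class TestHalfMaxLatency:
    def test_step_at_100ms(self):
        times = np.arange(0, 500) / 1000.0
        curve = (times >= 0.1).astype(float)
        assert half_max_latency(times, curve) * 1000 == pytest.approx(100.0)

    def test_linear_ramp_midpoint(self):
        times = np.arange(0, 500) / 1000.0
        curve = np.clip(times / 0.1, 0, 1)
        assert half_max_latency(times, curve) * 1000 == pytest.approx(50.0)

    @given(st.floats(1e-3, 1e3))
    def test_scale_invariance(self, scale):
        times = np.arange(0, 400) / 1000.0
        curve = np.clip((times - 0.05) / 0.2, 0, 1) ** 2
        base = half_max_latency(times, curve)
        assert half_max_latency(times, scale * curve) == pytest.approx(
            base, abs=1e-12
        )

    def test_earliest_crossing_wins_on_ties(self):
        times = np.arange(0, 300) / 1000.0
        curve = np.zeros(300)
        curve[100:] = 1.0  # long flat region at the half-max-exceeding level
        assert half_max_latency(times, curve) == pytest.approx(0.1)

    def test_constant_curve_rejected(self):
        times = np.arange(0, 300) / 1000.0
        with pytest.raises(ValueError, match="constant"):
            half_max_latency(times, np.ones(300))


class TestJackknifeLatency:
    def _curves(self, latencies_ms, times):
        """Per-subject sigmoid curves with given half-max latencies."""
        return np.stack(
            [1 / (1 + np.exp(-(times - lat / 1000.0) / 0.01)) for lat in latencies_ms]
        )

    def test_sd_formula_oracle(self):
        """S_D matches an independent direct evaluation on curves whose
        leave-one-out differences are hand-computable."""
        times = np.arange(-150, 451) / 1000.0
        cong = self._curves([80.0, 90.0, 100.0, 110.0], times)
        incong = self._curves([105.0, 115.0, 125.0, 135.0], times)
        est = jackknife_latency_difference(
            {"congruent": cong, "incongruent": incong}, times,
            search_window=(-0.15, 0.45),
        )
        # independent direct implementation of the jackknife
        def lat(curve):
            mask = (times >= -0.15) & (times <= 0.45)
            t, c = times[mask], curve[mask]
            lev = c.min() + (c.max() - c.min()) / 2
            return t[np.flatnonzero(c >= lev)[0]] * 1000.0

        n = 4
        d = np.array(
            [
                lat(np.delete(incong, i, axis=0).mean(axis=0))
                - lat(np.delete(cong, i, axis=0).mean(axis=0))
                for i in range(n)
            ]
        )
        sd = np.sqrt((n - 1) / n * np.sum((d - d.mean()) ** 2))
        assert est.jackknife_sd == pytest.approx(sd, abs=1e-12)
        assert est.difference_ms == pytest.approx(
            lat(incong.mean(axis=0)) - lat(cong.mean(axis=0)), abs=1e-9
        )

    def test_identical_loo_differences_give_zero_sd(self):
        times = np.arange(-150, 451) / 1000.0
        cong = self._curves([100.0] * 3, times)
        incong = self._curves([120.0] * 3, times)
        est = jackknife_latency_difference(
            {"congruent": cong, "incongruent": incong}, times,
            search_window=(-0.15, 0.45),
        )
        assert est.jackknife_sd == pytest.approx(0.0, abs=1e-9)
        assert est.difference_ms == pytest.approx(20.0, abs=0.5)

    def test_three_subject_hand_case(self):
        """Logistic curves make leave-one-out latencies hand-computable: the
        mean of two identical sigmoids shifted to l1, l2 crosses half-max at
        (l1+l2)/2 exactly.  With congruent latencies {80.3, 100.3, 120.3} ms
        and incongruent {95.3, 125.3, 140.3} ms the LOO midpoints are
        {132.8, 117.8, 110.3} vs {110.3, 100.3, 90.3} ms; the first 1 ms grid
        samples at half-max are {133, 118, 111} vs {111, 101, 91}, so the LOO
        differences are {22, 17, 20} ms and
        S_D = sqrt(2/3 * sum((D - 59/3)^2)) = sqrt(76/9) ms."""
        times = np.arange(-150, 451) / 1000.0
        cong = self._curves([80.3, 100.3, 120.3], times)
        incong = self._curves([95.3, 125.3, 140.3], times)
        est = jackknife_latency_difference(
            {"congruent": cong, "incongruent": incong}, times,
            search_window=(-0.15, 0.45),
        )
        np.testing.assert_allclose(
            np.sort(est.leave_one_out_differences_ms), [17.0, 20.0, 22.0],
            atol=1e-9,
        )
        assert est.jackknife_sd == pytest.approx(np.sqrt(76.0 / 9.0), abs=1e-9)

    def test_undefined_latency_names_subsample(self):
        times = np.arange(0, 300) / 1000.0
        flat = np.ones((3, 300))
        with pytest.raises(ValueError, match="congruent"):
            jackknife_latency_difference(
                {"congruent": flat, "incongruent": flat}, times,
                search_window=(0.0, 0.29),
            )

    def test_too_few_subjects(self):
        times = np.arange(0, 300) / 1000.0
        c = self._curves([100.0, 110.0], times)
        with pytest.raises(ValueError, match="3 subjects"):
            jackknife_latency_difference(
                {"congruent": c, "incongruent": c}, times,
            )
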
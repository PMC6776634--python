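"""Firing rates, correlation structure, clustering and window alignment."""

import numpy as np
import pandas as pd
import pytest

from retinamech import spikes as sp
from retinamech import synth
from retinamech.errors import (
    AlignmentError,
    InsufficientDataError,
    TriggerConsistencyError,
)


def make_set(spike_lists, duration=100.0):
    units = [
        sp.Unit(i, 10, 10, np.asarray(t, float)) for i, t in enumerate(spike_lists)
    ]
    return sp.SpikeTrainSet(units=units, recording_duration_s=duration)


class TestFilterAndRates:
    def test_rate_filter_boundary_inclusive(self):
        sts = make_set([np.linspace(1, 99, 9), np.linspace(1, 99, 10)])
        kept = sp.filter_units(sts, 0.1)
        assert kept.unit_ids == [1]

    def test_empty_filter_warns(self):
        sts = make_set([[1.0]])
        with pytest.warns(UserWarning):
            sp.filter_units(sts, 5.0)

    def test_window_count_to_rate(self):
        # 20 spikes inside one 2 s window -> 10 Hz
        sts = make_set([np.linspace(0.05, 1.95, 20)], duration=2.0)
        frm = sp.compute_firing_rate(sts, (0.0, 2.0), window_s=2.0, step_s=0.01)
        assert frm.rates.shape == (1, 1)
        assert frm.rates[0, 0] == pytest.approx(10.0)

    def test_empty_unit_gives_zero_row(self):
        sts = make_set([[], np.linspace(1, 9, 30)], duration=10.0)
        frm = sp.compute_firing_rate(sts, (0.0, 10.0))
        assert np.all(frm.rates[0] == 0.0)

    def test_window_longer_than_interval_rejected(self):
        sts = make_set([[1.0]])
        with pytest.raises(InsufficientDataError):
            sp.compute_firing_rate(sts, (0.0, 1.0), window_s=2.0)

    def test_nonoverlapping_tiling_conserves_counts(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0, 100, 500))
        sts = make_set([spikes])
        frm = sp.compute_firing_rate(sts, (0.0, 100.0), window_s=2.0, step_s=2.0)
        counts = frm.rates[0] * 2.0
        lo, hi = frm.bin_centers_s[0] - 1.0, frm.bin_centers_s[-1] + 1.0
        expected = np.count_nonzero((spikes >= lo) & (spikes < hi))
        assert counts.sum() == pytest.approx(expected)

    def test_poisson_rate_within_3_se(self):
        cfg = synth.RetinaConfig.background_only(1, basal_rate_hz=5.0, seed=2)
        sts = synth.simulate_spike_trains(cfg, [], [], 120.0, seed=5)
        frm = sp.compute_firing_rate(sts, (0.0, 120.0))
        assert abs(frm.rates.mean() - 5.0) <= 3 * np.sqrt(5.0 / 120.0)


class TestZScore:
    def test_rows_standardized(self):
        rng = np.random.default_rng(1)
        sts = make_set([np.sort(rng.uniform(0, 100, 300)) for _ in range(4)])
        z = sp.zscore_rates(sp.compute_firing_rate(sts, (0.0, 100.0)))
        assert np.allclose(z.rates.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(z.rates.std(axis=1), 1.0, atol=1e-9)

    def test_population_sd_convention(self):
        frm = sp.FiringRateMatrix([0], np.array([0.0, 1.0]), np.array([[0.0, 2.0]]), 2.0, 1.0)
        z = sp.zscore_rates(frm)
        assert np.allclose(z.rates, [[-1.0, 1.0]])

    def test_constant_row_flagged_not_nan(self):
        frm = sp.FiringRateMatrix(
            [0, 1], np.array([0.0, 1.0]), np.array([[3.0, 3.0], [0.0, 2.0]]), 2.0, 1.0
        )
        z = sp.zscore_rates(frm)
        assert z.constant_mask.tolist() == [True, False]
        assert np.all(np.isfinite(z.rates))


class TestCorrelation:
    def _frm(self, rows):
        rows = np.asarray(rows, float)
        return sp.FiringRateMatrix(
            list(range(len(rows))), np.arange(rows.shape[1], dtype=float), rows, 2.0, 1.0
        )

    def test_self_and_negation(self):
        base = np.sin(np.linspace(0, 10, 200))
        corr = sp.correlation_matrix(self._frm([base, -base, base + 1]))
        assert corr.loc[0, 0] == pytest.approx(1.0)
        assert corr.loc[0, 1] == pytest.approx(-1.0)
        assert corr.loc[0, 2] == pytest.approx(1.0)

    def test_symmetric_positive_semidefinite(self):
        rng = np.random.default_rng(3)
        corr = sp.correlation_matrix(self._frm(rng.normal(size=(12, 400))))
        a = corr.to_numpy()
        assert np.allclose(a, a.T)
        assert np.linalg.eigvalsh(a).min() > -1e-8

    def test_constant_units_excluded(self):
        rows = [np.ones(100), np.sin(np.arange(100.0)), np.cos(np.arange(100.0))]
        corr = sp.correlation_matrix(self._frm(rows))
        assert list(corr.index) == [1, 2]

    def test_too_few_usable_units_rejected(self):
        with pytest.raises(InsufficientDataError):
            sp.correlation_matrix(self._frm([np.ones(50), np.ones(50)]))


class TestClustering:
    def _corr_from_signals(self, signals, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        n = len(signals[0])
        rows = np.vstack(
            [s + rng.normal(0, noise, n) for s in signals]
        )
        frm = sp.FiringRateMatrix(
            list(range(len(rows))), np.arange(n, dtype=float), rows, 2.0, 1.0
        )
        return sp.correlation_matrix(frm)

    def test_anticorrelated_groups_merge(self):
        """|rho| similarity intentionally groups correlated with anti-correlated."""
        rng = np.random.default_rng(0)
        s1 = rng.normal(size=3000)
        s2 = rng.normal(size=3000)
        signals = [s1] * 3 + [-s1] * 3 + [s2] * 3 + [-s2] * 3
        corr = self._corr_from_signals(signals)
        cl = sp.cluster_units(corr, k_range=(2, 5))
        labels = np.asarray(cl.labels)
        assert len(set(labels[:6])) == 1  # s1 and -s1 together
        assert len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_four_orthogonal_planted_clusters_recovered(self):
        rng = np.random.default_rng(1)
        base = [rng.normal(size=3000) for _ in range(4)]
        signals = [b for b in base for _ in range(8)]
        corr = self._corr_from_signals(signals, seed=2)
        cl = sp.cluster_units(corr, k_range=(4, 60))
        assert cl.k_selected == 4
        truth = np.repeat(np.arange(4), 8)
        # exact recovery up to relabeling
        mapping = {}
        for t, l in zip(truth, cl.labels):
            mapping.setdefault(t, l)
            assert mapping[t] == l
        assert len(set(mapping.values())) == 4

    def test_input_order_invariance(self):
        rng = np.random.default_rng(4)
        base = [rng.normal(size=2000) for _ in range(3)]
        signals = [b for b in base for _ in range(6)]
        corr = self._corr_from_signals(signals, seed=5)
        cl1 = sp.cluster_units(corr, k_range=(2, 10))
        perm = rng.permutation(len(corr))
        corr_p = corr.iloc[perm, perm]
        cl2 = sp.cluster_units(corr_p, k_range=(2, 10))
        lab1 = dict(zip(cl1.unit_ids, cl1.labels))
        lab2 = dict(zip(cl2.unit_ids, cl2.labels))
        pairs1 = {(a, b): lab1[a] == lab1[b] for a in lab1 for b in lab1}
        pairs2 = {(a, b): lab2[a] == lab2[b] for a in lab2 for b in lab2}
        assert pairs1 == pairs2

    def test_identical_signals_fall_back_to_single_cluster(self):
        corr = pd.DataFrame(np.ones((6, 6)), index=range(6), columns=range(6))
        with pytest.warns(UserWarning):
            cl = sp.cluster_units(corr, k_range=(4, 60))
        assert cl.k_selected == 1
        assert len(set(cl.labels)) == 1


class TestReorderAndTimecourse:
    def test_reorder_preserves_entry_multiset(self):
        rng = np.random.default_rng(7)
        base = [rng.normal(size=2000) for _ in range(2)]
        signals = [b for b in base for _ in range(5)]
        rows = np.vstack([s + rng.normal(0, 0.1, 2000) for s in signals])
        frm = sp.FiringRateMatrix(list(range(10)), np.arange(2000.0), rows, 2.0, 1.0)
        corr = sp.correlation_matrix(frm)
        cl = sp.cluster_units(corr, k_range=(2, 5))
        reordered, summary = sp.reorder_basal(corr, cl, corr)
        assert sorted(np.round(reordered.to_numpy().ravel(), 12)) == sorted(
            np.round(corr.to_numpy().ravel(), 12)
        )
        assert summary["basal"] == summary["indentation"]

    def test_unit_mismatch_rejected(self):
        corr = pd.DataFrame(np.eye(3), index=[0, 1, 2], columns=[0, 1, 2])
        cl = sp.ClusterAssignment([0, 1], np.array([1, 2]), 2, {2: 0.5})
        with pytest.raises(AlignmentError):
            sp.reorder_basal(corr, cl)

    def test_singleton_clusters_excluded_from_within_summary(self):
        corr = pd.DataFrame(np.eye(3), index=[0, 1, 2], columns=[0, 1, 2])
        cl = sp.ClusterAssignment([0, 1, 2], np.array([1, 2, 3]), 3, {3: 0.1})
        res = sp.within_between_abs_corr(corr, cl)
        assert np.isnan(res["within"])
        assert res["between"] == pytest.approx(0.0)

    def test_single_member_cluster_sem_flagged(self):
        rng = np.random.default_rng(8)
        rows = rng.normal(size=(3, 500))
        frm = sp.FiringRateMatrix([0, 1, 2], np.arange(500.0), rows, 2.0, 1.0)
        cl = sp.ClusterAssignment([0, 1, 2], np.array([1, 1, 2]), 2, {2: 0.2})
        tc = sp.cluster_timecourse(frm, cl)
        assert tc[2]["flagged_single"]
        assert np.all(tc[2]["sem"] == 0.0)

    def test_responsive_clusters_flag_planted_not_background(self):
        cfg = synth.RetinaConfig.four_cluster_preset(seed=3, n_background=60, cluster_size=10)
        sts = synth.simulate_spike_trains(cfg, [synth.StimEvent(130.0, 190.0)], [], 210.0, seed=4)
        frm_b = sp.compute_firing_rate(sts, (10.0, 130.0))
        frm_i = sp.compute_firing_rate(sts, (130.0, 200.0))
        planted = {m for pc in cfg.planted_clusters for m in pc.members}
        labels = np.array(
            [i // 10 + 1 if u in planted else 5 + i % 6 for i, u in enumerate(sts.unit_ids)]
        )
        cl = sp.ClusterAssignment(sts.unit_ids, labels, len(set(labels)), {})
        resp = sp.responsive_clusters(frm_b, frm_i, cl)
        assert {1, 2, 3, 4} <= set(resp)  # every planted assembly flagged
        assert not any(l >= 5 for l in resp)  # background groups stay quiet

    def test_onset_cluster_mean_peaks_after_onset(self):
        cfg = synth.RetinaConfig.four_cluster_preset(seed=0, n_background=20, cluster_size=10)
        sts = synth.simulate_spike_trains(cfg, [synth.StimEvent(130.0, 190.0)], [], 210.0, seed=1)
        frm = sp.compute_firing_rate(sts, (130.0, 200.0))
        members = list(cfg.planted_clusters[0].members)
        cl = sp.ClusterAssignment(
            sts.unit_ids,
            np.array([1 if u in members else 2 for u in sts.unit_ids]),
            2,
            {2: 0.5},
        )
        tc = sp.cluster_timecourse(frm, cl)
        peak_time = frm.bin_centers_s[np.argmax(tc[1]["mean"])]
        assert 130.0 < peak_time < 145.0


class TestAlignment:
    def test_basal_and_indentation_windows(self):
        sts = make_set([np.linspace(1, 599, 100)], duration=600.0)
        _, windows = sp.align_stimulation_window(sts, [(200.0, 260.0)])
        assert windows[0]["basal"] == (80.0, 200.0)
        assert windows[0]["indentation"] == (200.0, 260.0)

    def test_inverted_trigger_rejected(self):
        sts = make_set([[1.0]], duration=100.0)
        with pytest.raises(TriggerConsistencyError):
            sp.align_stimulation_window(sts, [(50.0, 40.0)])

    def test_early_onset_truncates_basal_with_warning(self):
        sts = make_set([[1.0]], duration=300.0)
        with pytest.warns(UserWarning):
            _, windows = sp.align_stimulation_window(sts, [(60.0, 90.0)])
        assert windows[0]["basal"] == (0.0, 60.0)

    def test_out_of_range_trigger_rejected(self):
        sts = make_set([[1.0]], duration=100.0)
        with pytest.raises(TriggerConsistencyError):
            sp.align_stimulation_window(sts, [(50.0, 150.0)])
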
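"""Peri-event binning, smoothing, z-scoring, condition averages, exclusion."""

import numpy as np
import pandas as pd
import pytest

from ddstates.spikes import (
    AlignedTensor,
    SpikeTable,
    ZScoreNeurons,
    align_and_bin,
    bin_count,
    condition_averages,
    retained_neurons,
    retention_bookkeeping,
    smooth,
    zscore_rates,
)


def make_table(times_by_neuron, session_id="s"):
    rows = [(nid, t) for nid, times in times_by_neuron.items() for t in times]
    df = pd.DataFrame(rows, columns=["neuron_id", "time_s"])
    return SpikeTable(session_id=session_id, spikes=df)


@pytest.mark.parametrize(
    "window,width,expected",
    [
        ((-15.0, 15.0), 0.2, 151),
        ((-19.0, 1.0), 0.2, 101),
        ((0.0, 1.0), 1.0, 2),  # endpoints inclusive
    ],
)
def test_bin_count_convention(window, width, expected):
    assert bin_count(window, width) == expected


def test_bin_count_rejects_bad_inputs():
    with pytest.raises(ValueError):
        bin_count((0.0, 1.0), 0.0)
    with pytest.raises(ValueError):
        bin_count((1.0, 0.0), 0.2)


class TestAlignAndBin:
    def test_single_spike_lands_in_center_bin(self):
        table = make_table({0: [100.0]})
        tensor = align_and_bin(table, [100.0], window=(-1.0, 1.0), bin_width=0.2)
        assert tensor.rates.shape == (1, 11, 1)
        counts = tensor.rates[0, :, 0] * 0.2
        assert counts[5] == pytest.approx(1.0)
        assert counts.sum() == pytest.approx(1.0)

    def test_empty_train_all_zero(self):
        table = make_table({0: [0.5], 1: [1e6]})  # neuron 1 far outside window
        tensor = align_and_bin(table, [0.5], window=(-1.0, 1.0), bin_width=0.2)
        assert np.all(tensor.rates[1] == 0)

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(0)
        lam, T = 20.0, 400.0
        times = np.sort(rng.uniform(0, T, size=rng.poisson(lam * T)))
        table = make_table({0: times})
        tensor = align_and_bin(table, [T / 2], window=(-100.0, 100.0), bin_width=0.2)
        assert tensor.rates.mean() == pytest.approx(lam, rel=0.05)

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            align_and_bin(make_table({0: [1.0]}), [])

    def test_truncated_trials_flagged(self):
        table = make_table({0: [5.0]})
        tensor = align_and_bin(table, [5.0, 395.0], window=(-10.0, 10.0),
                               bin_width=0.2, recording_span=(0.0, 400.0))
        assert tensor.truncated.tolist() == [True, True]

    def test_binning_is_linear_in_spike_trains(self):
        """Merging two spike trains adds their binned (and smoothed) rates."""
        rng = np.random.default_rng(1)
        a = np.sort(rng.uniform(0, 40, 200))
        b = np.sort(rng.uniform(0, 40, 150))
        ta = align_and_bin(make_table({0: a}), [20.0], window=(-19.0, 1.0), bin_width=0.2)
        tb = align_and_bin(make_table({0: b}), [20.0], window=(-19.0, 1.0), bin_width=0.2)
        tab = align_and_bin(make_table({0: np.sort(np.concatenate([a, b]))}), [20.0],
                            window=(-19.0, 1.0), bin_width=0.2)
        np.testing.assert_allclose(tab.rates, ta.rates + tb.rates, atol=1e-9)
        np.testing.assert_allclose(
            smooth(tab).rates, smooth(ta).rates + smooth(tb).rates, atol=1e-9
        )


class TestSmooth:
    def _impulse(self, n_bins=101, at=50):
        rates = np.zeros((1, n_bins, 1))
        rates[0, at, 0] = 1.0
        return AlignedTensor(rates=rates, window=(-19.0, 1.0), bin_width_s=0.2,
                             neuron_ids=[0])

    def test_moving_average_impulse_response(self):
        out = smooth(self._impulse(), method="moving_average")
        resp = out.rates[0, :, 0]
        assert resp[48:53] == pytest.approx(np.full(5, 0.2))
        assert resp.sum() == pytest.approx(1.0)

    def test_constant_series_unchanged(self):
        rates = np.full((2, 101, 3), 7.5)
        tensor = AlignedTensor(rates=rates, window=(-19.0, 1.0), bin_width_s=0.2,
                               neuron_ids=[0, 1])
        for method in ("moving_average", "gaussian"):
            np.testing.assert_allclose(smooth(tensor, method=method).rates, rates)

    def test_matches_direct_convolution_oracle(self):
        rng = np.random.default_rng(7)
        series = rng.uniform(size=101)
        rates = series[None, :, None].copy()
        tensor = AlignedTensor(rates=rates, window=(-19.0, 1.0), bin_width_s=0.2,
                               neuron_ids=[0])
        out = smooth(tensor, method="moving_average").rates[0, :, 0]
        padded = np.concatenate([series[:2][::-1], series, series[-2:][::-1]])
        oracle = np.convolve(padded, np.full(5, 0.2), mode="valid")
        np.testing.assert_allclose(out, oracle, atol=1e-12)

    def test_kernel_longer_than_series_errors(self):
        rates = np.zeros((1, 3, 1))
        tensor = AlignedTensor(rates=rates, window=(0.0, 0.4), bin_width_s=0.2,
                               neuron_ids=[0])
        with pytest.raises(ValueError):
            smooth(tensor, method="moving_average", ma_bins=5)


class TestZScore:
    def test_closed_form_three_values(self):
        X = np.array([[1.0], [2.0], [3.0]])
        Z, dropped = zscore_rates(X)
        np.testing.assert_allclose(Z[:, 0], [-1.2247448, 0.0, 1.2247448], atol=1e-6)
        assert dropped == []

    def test_post_transform_moments(self):
        rng = np.random.default_rng(2)
        X = rng.normal(5, 3, size=(808, 20))
        Z, _ = zscore_rates(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)

    def test_constant_neuron_dropped(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        Z, dropped = zscore_rates(X)
        assert Z.shape == (10, 1)
        assert dropped == [0]

    def test_tensor_zscore_per_neuron_over_bins_and_trials(self):
        rng = np.random.default_rng(3)
        rates = rng.gamma(2, 2, size=(4, 101, 5))
        rates[2] = 3.0  # constant neuron
        tensor = AlignedTensor(rates=rates, window=(-19.0, 1.0), bin_width_s=0.2,
                               neuron_ids=list("abcd"))
        out, dropped = zscore_rates(tensor)
        assert dropped == ["c"]
        flat = out.rates.reshape(3, -1)
        np.testing.assert_allclose(flat.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(flat.std(axis=1), 1.0, atol=1e-12)

    def test_sklearn_transformer_roundtrip(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 6))
        zs = ZScoreNeurons().fit(X)
        assert zs.get_params() == {"ddof": 0}
        np.testing.assert_allclose(zs.transform(X).mean(axis=0), 0.0, atol=1e-12)


class TestConditionAverages:
    def _tensor(self, rates):
        n, b, t = rates.shape
        return AlignedTensor(rates=rates, window=(-15.0, 15.0), bin_width_s=0.2,
                             neuron_ids=list(range(n)))

    def test_identical_conditions_nothing_significant(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(30, 151, 1))
        rates = np.concatenate([base + 0.01 * rng.normal(size=(30, 151, 4))], axis=2)
        labels = ["IM-low", "IM-low", "IM-high", "IM-high"]
        res = condition_averages(self._tensor(rates), labels, contrasts=[("IM-low", "IM-high")])
        assert not res.tests[("IM-low", "IM-high")].significant.any()

    def test_injected_offset_bins_flagged(self):
        """An offset planted in bins 80-100 of one condition is exactly the
        significant set at large neuron count."""
        rng = np.random.default_rng(6)
        n_neurons = 120
        rates = rng.normal(0, 0.2, size=(n_neurons, 151, 6))
        labels = np.array(["IM-low"] * 3 + ["IM-high"] * 3)
        rates[:, 80:101, labels == "IM-high"] += 2.0
        res = condition_averages(self._tensor(rates), labels,
                                 contrasts=[("IM-low", "IM-high")])
        sig = res.tests[("IM-low", "IM-high")].significant
        assert sig[80:101].all()
        # FDR controls the false-discovery *rate*: tolerate at most a couple
        # of spurious flags among the 130 null bins
        false_flags = sig[:80].sum() + sig[101:].sum()
        assert false_flags <= 2

    def test_by_adjusted_at_least_raw(self):
        rng = np.random.default_rng(8)
        rates = rng.normal(size=(25, 151, 4))
        labels = ["DEL-low", "DEL-low", "DEL-high", "DEL-high"]
        res = condition_averages(self._tensor(rates), labels,
                                 contrasts=[("DEL-low", "DEL-high")])
        t = res.tests[("DEL-low", "DEL-high")]
        assert np.all(t.p_adjusted >= t.p_raw - 1e-12)

    def test_empty_condition_errors(self):
        rng = np.random.default_rng(9)
        rates = rng.normal(size=(5, 151, 3))
        with pytest.raises(ValueError):
            condition_averages(self._tensor(rates), ["IM-low", "IM-low", "IM-high"])


class TestNeuronExclusion:
    def test_silent_in_one_type_excluded(self):
        table = make_table({
            "active": [9.0, 19.0, 29.0, 39.0],
            "partial": [9.0, 19.0, 29.0],  # silent around the 4th event
        })
        events = {"A-T3": [10.0], "A-T4": [20.0], "B-T3": [30.0], "B-T4": [40.0]}
        kept = retained_neurons(table, events, window=(-5.0, 1.0))
        assert kept == ["active"]

    def test_fires_once_anywhere_in_type_suffices(self):
        table = make_table({"n": [9.0, 19.0]})
        events = {"A-T3": [10.0, 100.0], "A-T4": [20.0]}
        kept = retained_neurons(table, events, window=(-5.0, 1.0))
        assert kept == ["n"]

    def test_retention_bookkeeping(self):
        assert retention_bookkeeping(2120, 1539) == 581
        assert retention_bookkeeping(2078, 912) == 1166
        with pytest.raises(ValueError):
            retention_bookkeeping(10, 11)
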
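"""Trigger-pulse construction, lag estimation, and event mapping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import collocerp as c
from collocerp.events import validate_events


def make_events(onsets, duration=0.2, **cols):
    df = pd.DataFrame(
        {
            "token": [f"w{i}" for i in range(len(onsets))],
            "onset_s": onsets,
            "offset_s": [o + duration for o in onsets],
        }
    )
    for k, v in cols.items():
        df[k] = v
    return df


def brute_force_lag(x, y):
    """Independent oracle: scan every integer lag, maximize correlation."""
    x = x - x.mean()
    y = y - y.mean()
    best_lag, best_r = 0, -np.inf
    for lag in range(-(len(x) - 1), len(y)):
        lo, hi = max(0, lag), min(len(y), len(x) + lag)
        if hi - lo < 2:
            continue
        seg_y = y[lo:hi]
        seg_x = x[lo - lag : hi - lag]
        r = float(np.dot(seg_x, seg_y))
        if r > best_r or (r == best_r and abs(lag) < abs(best_lag)):
            best_r, best_lag = r, lag
    return best_lag


class TestTriggerTrace:
    def test_single_pulse_position_and_width(self):
        trace = c.make_trigger_trace(make_events([1.0]), fs=250, pulse_ms=10)
        assert trace.samples[250] == 1.0 and trace.samples[251] == 1.0
        assert trace.samples.sum() == 2  # round(2.5) samples wide

    def test_empty_event_list_gives_all_zero_trace(self):
        trace = c.make_trigger_trace(make_events([]), fs=250, duration_s=2.0)
        assert trace.samples.shape == (500,)
        assert not trace.samples.any()

    def test_close_events_merge_with_warning(self):
        with pytest.warns(UserWarning, match="merge"):
            trace = c.make_trigger_trace(
                make_events([1.0, 1.004], duration=0.003), fs=250, pulse_ms=10
            )
        assert trace.samples.sum() == 3  # overlapping pulses fuse

    def test_event_beyond_duration_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            c.make_trigger_trace(make_events([5.0]), fs=250, duration_s=2.0)

    def test_unsorted_or_overlapping_events_rejected(self):
        with pytest.raises(ValueError):
            validate_events(make_events([2.0, 1.0]))
        with pytest.raises(ValueError):
            validate_events(make_events([1.0, 1.1], duration=0.5))


class TestEstimateLag:
    def _shift(self, x, s):
        y = np.zeros_like(x)
        if s >= 0:
            y[s:] = x[: len(x) - s]
        else:
            y[:s] = x[-s:]
        return y

    def test_identity_gives_zero_lag_and_unit_peak(self):
        tr = c.make_trigger_trace(make_events([0.5, 1.3, 2.1]), fs=250)
        res = c.estimate_lag(tr, tr)
        assert res.lag_samples == 0
        assert res.peak_correlation == pytest.approx(1.0, abs=1e-9)

    def test_pure_shift_recovered_exactly(self):
        tr = c.make_trigger_trace(
            make_events([0.5, 1.3, 2.1, 3.7]), fs=250, duration_s=10.0
        )
        shifted = c.TriggerTrace(self._shift(tr.samples, 250), tr.fs)
        res = c.estimate_lag(tr, shifted)
        assert res.lag_samples == 250
        assert res.lag_s == pytest.approx(1.0)
        assert res.peak_correlation == pytest.approx(1.0, abs=0.01)

    def test_noisy_shift_matches_brute_force_oracle(self, rng):
        tr = c.make_trigger_trace(
            make_events(sorted(rng.uniform(0.5, 9.0, size=12)), duration=0.05), fs=250
        )
        sig = self._shift(tr.samples, 250)
        noisy = sig + rng.normal(0, np.sqrt(sig.var() / 10), size=sig.size)
        res = c.estimate_lag(tr, c.TriggerTrace(noisy, tr.fs))
        assert res.lag_samples == 250
        assert res.lag_samples == brute_force_lag(tr.samples, noisy)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        shift=st.integers(-1250, 1250),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_round_trip_recovers_any_integer_shift(self, shift, seed):
        rng = np.random.default_rng(seed)
        onsets = np.sort(rng.uniform(0.0, 20.0, size=rng.integers(3, 30)))
        onsets = onsets[np.diff(onsets, prepend=-1.0) > 0.1]
        if len(onsets) < 2:
            onsets = np.array([0.5, 1.0])
        tr = c.make_trigger_trace(make_events(list(onsets), duration=0.04), fs=250)
        n = len(tr.samples) + abs(shift)
        rec = np.zeros(n)
        if shift >= 0:
            rec[shift : shift + len(tr.samples)] = tr.samples
        else:
            rec[: len(tr.samples) + shift] = tr.samples[-shift:]
        res = c.estimate_lag(tr, c.TriggerTrace(rec, tr.fs))
        assert res.lag_samples == shift

    def test_antisymmetric_in_argument_order(self):
        tr = c.make_trigger_trace(make_events([0.5, 1.1, 2.9]), fs=250)
        shifted = c.TriggerTrace(self._shift(tr.samples, 37), tr.fs)
        assert c.estimate_lag(tr, shifted).lag_samples == -(
            c.estimate_lag(shifted, tr).lag_samples
        )

    def test_degenerate_inputs_rejected(self):
        tr = c.make_trigger_trace(make_events([0.5]), fs=250)
        flat = c.TriggerTrace(np.ones(100), 250.0)
        with pytest.raises(ValueError, match="constant"):
            c.estimate_lag(tr, flat)
        other_fs = c.TriggerTrace(tr.samples.copy(), 500.0)
        with pytest.raises(ValueError, match="mismatch"):
            c.estimate_lag(tr, other_fs)


class TestEventsToSamples:
    def _labeled(self, onsets, conditions, duration=0.2):
        return make_events(
            onsets,
            duration=duration,
            is_critical=[cond is not None for cond in conditions],
            condition=conditions,
        )

    def test_sample_arithmetic(self):
        ev = self._labeled([2.0], ["collocation"])
        sync = c.SyncResult(lag_samples=5, lag_s=0.02, peak_correlation=1.0)
        out, dropped = c.events_to_samples(ev, sync, fs=250)
        assert out == [(505, "collocation")]
        assert dropped == 0

    def test_zero_lag_zero_onset_maps_to_zero(self):
        ev = self._labeled([0.0], ["collocation"])
        sync = c.SyncResult(0, 0.0, 1.0)
        out, _ = c.events_to_samples(ev, sync, fs=250)
        assert out[0][0] == 0

    def test_event_past_recording_end_dropped_and_counted(self):
        ev = self._labeled([1.0, 50.0], ["collocation", "non_collocation"])
        sync = c.SyncResult(0, 0.0, 1.0)
        out, dropped = c.events_to_samples(ev, sync, fs=250, n_samples=1000)
        assert len(out) == 1 and dropped == 1

    def test_non_critical_events_excluded_by_default(self):
        ev = self._labeled([1.0, 2.0, 3.0], ["collocation", None, "non_collocation"])
        sync = c.SyncResult(0, 0.0, 1.0)
        out, _ = c.events_to_samples(ev, sync, fs=250)
        assert [cond for _, cond in out] == ["collocation", "non_collocation"]

    def test_order_preserving_and_injective(self, rng):
        onsets = np.sort(rng.uniform(0, 30, size=40))
        onsets = onsets[np.diff(onsets, prepend=-1.0) > 0.05]
        ev = self._labeled(list(onsets), ["collocation"] * len(onsets),
                           duration=0.04)
        sync = c.SyncResult(17, 17 / 250, 1.0)
        out, _ = c.events_to_samples(ev, sync, fs=250)
        idx = [i for i, _ in out]
        assert idx == sorted(idx)
        assert len(set(idx)) == len(idx)


class TestReaders:
    def test_tsv_round_trip(self, tmp_path):
        ev = make_events([0.5, 1.2], is_critical=[True, False],
                         condition=["collocation", None])
        p = tmp_path / "events.tsv"
        c.write_events_tsv(ev, p)
        back = c.read_events_tsv(p)
        assert list(back["token"]) == list(ev["token"])
        assert np.allclose(back["onset_s"], ev["onset_s"])
        assert list(back["is_critical"]) == [True, False]

    def test_textgrid_word_tier_parsed_and_silences_skipped(self, tmp_path):
        tg = tmp_path / "sample.TextGrid"
        tg.write_text(
            'File type = "ooTextFile"\n'
            'Object class = "TextGrid"\n'
            "xmin = 0\nxmax = 2.5\ntiers? <exists>\nsize = 1\nitem []:\n"
            "    item [1]:\n"
            '        class = "IntervalTier"\n'
            '        name = "words"\n'
            "        xmin = 0\nxmax = 2.5\nintervals: size = 3\n"
            "        intervals [1]:\n"
            "            xmin = 0\n            xmax = 0.4\n"
            '            text = ""\n'
            "        intervals [2]:\n"
            "            xmin = 0.4\n            xmax = 1.1\n"
            '            text = "guten"\n'
            "        intervals [3]:\n"
            "            xmin = 1.1\n            xmax = 1.9\n"
            '            text = "Morgen"\n',
            encoding="utf-8",
        )
        df = c.read_textgrid_events(tg)
        assert list(df["token"]) == ["guten", "Morgen"]
        assert df["onset_s"].tolist() == [0.4, 1.1]
        with pytest.raises(ValueError, match="interval tier"):
            c.read_textgrid_events(tg, tier="phones")
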
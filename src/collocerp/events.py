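"""Word-event handling and stimulus/EEG synchronization.

Forced alignment of the audio-book transcript yields word-boundary time
tags.  The stimulation setup converts word onsets into rectangular trigger
pulses fed into an auxiliary channel of the EEG amplifier; the lag between
the stimulus clock and the recording clock is recovered by locating the
peak of the normalized cross-correlation between the original pulse train
and its recorded copy.  Word onsets are then mapped to EEG sample indices.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["token", "onset_s", "offset_s", "is_critical", "condition"]


@dataclass(frozen=True)
class TriggerTrace:
    """A pulse train sampled at ``fs`` Hz."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.samples) < 1:
            raise ValueError("trigger trace is empty")


@dataclass(frozen=True)
class SyncResult:
    """Estimated recording lag relative to the stimulus clock."""

    lag_samples: int
    lag_s: float
    peak_correlation: float


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check ordering/overlap invariants of an event table; returns it."""
    missing = {"token", "onset_s", "offset_s"} - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    if (events["offset_s"] <= events["onset_s"]).any():
        raise ValueError("event offsets must exceed onsets")
    onsets = events["onset_s"].to_numpy()
    if (np.diff(onsets) < 0).any():
        raise ValueError("events must be sorted by onset")
    if (events["onset_s"].to_numpy()[1:] < events["offset_s"].to_numpy()[:-1]).any():
        raise ValueError("events overlap within the stream")
    return events


def make_trigger_trace(
    events: pd.DataFrame,
    fs: float,
    pulse_ms: float = 10.0,
    duration_s: float | None = None,
) -> TriggerTrace:
    """Rectangular unit pulses of width ``pulse_ms`` at each word onset.

    ``duration_s`` defaults to the last word offset plus one pulse width.
    Events starting beyond the requested duration are an error; pulses of
    adjacent words may merge when inter-word gaps are shorter than the
    pulse (a warning, common in fluent speech).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    pulse_n = max(1, int(round(pulse_ms / 1000.0 * fs)))
    if len(events) == 0:
        n = max(1, int(round((duration_s or 1.0) * fs)))
        return TriggerTrace(np.zeros(n), fs)
    validate_events(events)
    onsets = events["onset_s"].to_numpy(dtype=float)
    if duration_s is None:
        duration_s = float(events["offset_s"].max()) + pulse_ms / 1000.0
    n = int(round(duration_s * fs))
    late = onsets[onsets * fs > n - 1]
    if late.size:
        raise ValueError(
            f"{late.size} event(s) beyond trace duration {duration_s:.3f} s: "
            f"onsets {late[:5].tolist()}"
        )
    trace = np.zeros(n)
    starts = np.round(onsets * fs).astype(int)
    if (np.diff(starts) < pulse_n).any():
        warnings.warn("adjacent trigger pulses merge (inter-word gap < pulse width)",
                      stacklevel=2)
    for s in starts:
        trace[s : s + pulse_n] = 1.0
    return TriggerTrace(trace, float(fs))


def estimate_lag(original: TriggerTrace, recorded: TriggerTrace) -> SyncResult:
    """Lag of the recorded pulse train relative to the original.

    The lag is the argmax of the full normalized cross-correlation;
    positive lag means the recorded copy is delayed.  Ties are broken
    toward the smallest absolute lag.
    """
    if original.fs != recorded.fs:
        raise ValueError(f"fs mismatch: {original.fs} vs {recorded.fs}")
    x = np.asarray(original.samples, dtype=float)
    y = np.asarray(recorded.samples, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant trigger trace: lag is undefined")
    x = x - x.mean()
    y = y - y.mean()
    corr = signal.correlate(y, x, mode="full", method="fft")
    lags = signal.correlation_lags(len(y), len(x), mode="full")
    norm = np.sqrt(np.sum(x**2) * np.sum(y**2))
    corr = corr / norm
    best = corr.max()
    # snap float ties (within 1e-12 of the max) toward the smallest |lag|
    tied = np.flatnonzero(corr >= best - 1e-12)
    lag = int(lags[tied[np.argmin(np.abs(lags[tied]))]])
    return SyncResult(
        lag_samples=lag,
        lag_s=lag / original.fs,
        peak_correlation=float(best),
    )


def events_to_samples(
    events: pd.DataFrame,
    sync: SyncResult,
    fs: float,
    n_samples: int | None = None,
    critical_only: bool = True,
) -> tuple[list[tuple[int, str]], int]:
    """Map word onsets to EEG sample indices.

    ``sample = round(onset_s * fs) + lag_samples``.  By default only
    critical words carrying a condition label are emitted.  Events mapping
    outside ``[0, n_samples)`` are dropped with a logged warning; the drop
    count is returned alongside.
    """
    validate_events(events)
    sub = events
    if critical_only:
        if "is_critical" not in events.columns or "condition" not in events.columns:
            raise ValueError("event table lacks is_critical/condition columns")
        sub = events[events["is_critical"].astype(bool) & events["condition"].notna()]
    out: list[tuple[int, str]] = []
    dropped = 0
    for row in sub.itertuples():
        idx = int(round(row.onset_s * fs)) + sync.lag_samples
        if idx < 0 or (n_samples is not None and idx >= n_samples):
            dropped += 1
            logger.warning("event %r at %.3f s maps outside the recording", row.token,
                           row.onset_s)
            continue
        cond = getattr(row, "condition", None)
        out.append((idx, None if cond is None or pd.isna(cond) else str(cond)))
    return out, dropped


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_events_tsv(path) -> pd.DataFrame:
    """Read an event table (token, onset_s, offset_s[, is_critical, condition])."""
    df = pd.read_csv(path, sep="\t")
    if "is_critical" not in df.columns:
        df["is_critical"] = False
    if "condition" not in df.columns:
        df["condition"] = pd.NA
    return validate_events(df)


def write_events_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


_TG_NUM = re.compile(r"(?:xmin|xmax|number)\s*=\s*([0-9.eE+-]+)")
_TG_TEXT = re.compile(r'(?:text|mark)\s*=\s*"((?:[^"]|"")*)"')


def read_textgrid_events(path, tier: str | None = None) -> pd.DataFrame:
    """Parse word events from a Praat TextGrid (long format, interval tiers).

    ``tier`` selects the interval tier by name; by default the first
    interval tier is used.  Intervals with empty labels (silences) are
    skipped.
    """
    with open(path, encoding="utf-8") as fh:
        content = fh.read()
    # split into tier blocks
    blocks = re.split(r"item\s*\[\d+\]\s*:", content)[1:]
    chosen = None
    for block in blocks:
        if '"IntervalTier"' not in block:
            continue
        m = re.search(r'name\s*=\s*"((?:[^"]|"")*)"', block)
        name = m.group(1) if m else ""
        if tier is None or name == tier:
            chosen = block
            break
    if chosen is None:
        raise ValueError(
            f"no interval tier{'' if tier is None else f' named {tier!r}'} in {path}"
        )
    rows = []
    for ib in re.split(r"intervals\s*\[\d+\]\s*:", chosen)[1:]:
        nums = _TG_NUM.findall(ib)
        texts = _TG_TEXT.findall(ib)
        if len(nums) < 2 or not texts:
            continue
        label = texts[0].replace('""', '"').strip()
        if not label:
            continue
        rows.append((label, float(nums[0]), float(nums[1])))
    df = pd.DataFrame(rows, columns=["token", "onset_s", "offset_s"])
    df["is_critical"] = False
    df["condition"] = pd.NA
    return validate_events(df)
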
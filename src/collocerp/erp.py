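"""Evoked responses, grand averages, and ROI mean amplitudes.

Per-participant evoked responses are within-condition trial means; grand
averages weight each participant equally.  The quantity of interest is the
mean amplitude over four scalp regions of interest (left/right x
anterior/posterior) in the 300-500 ms post-onset window where the N400 is
expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import EpochSet

#: N400 analysis window in seconds (inclusive at both endpoints at sample
#: resolution).
DEFAULT_WINDOW = (0.3, 0.5)


@dataclass(frozen=True)
class RoiSet:
    """Four named electrode groups (10-10 montage labels)."""

    groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "LA": ("FC1", "FC3", "FC5", "F1", "F3", "F5", "F7", "AF3", "AF7"),
            "RA": ("FC2", "FC4", "FC6", "F2", "F4", "F6", "F8", "AF4", "AF8"),
            "LP": ("CP1", "CP3", "CP5", "P1", "P3", "P5", "P7"),
            "RP": ("CP2", "CP4", "CP6", "P2", "P4", "P6", "P8"),
        }
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, chans in self.groups.items():
            overlap = seen & set(chans)
            if overlap:
                raise ValueError(f"ROI {name} overlaps others on {sorted(overlap)}")
            seen |= set(chans)

    @property
    def names(self) -> list[str]:
        return list(self.groups)

    @property
    def all_channels(self) -> list[str]:
        return [c for chans in self.groups.values() for c in chans]

    def indices(self, channel_names: list[str]) -> dict[str, np.ndarray]:
        """Row indices of each ROI's channels; errors name missing channels."""
        pos = {c: i for i, c in enumerate(channel_names)}
        out = {}
        for name, chans in self.groups.items():
            missing = [c for c in chans if c not in pos]
            if missing:
                raise ValueError(f"ROI {name}: channel(s) {missing} not in montage")
            out[name] = np.array([pos[c] for c in chans])
        return out


DEFAULT_ROIS = RoiSet()


@dataclass
class Evoked:
    """Within-condition trial mean for one participant."""

    condition: str
    participant: str
    data: np.ndarray  # channels x time, microvolts
    n_trials: int
    fs: float
    channel_names: list[str]
    tmin_s: float

    @property
    def times(self) -> np.ndarray:
        return self.tmin_s + np.arange(self.data.shape[1]) / self.fs


@dataclass
class GrandAverage:
    """Unweighted mean of per-participant evokeds for one condition."""

    condition: str
    data: np.ndarray
    n_participants: int
    fs: float
    channel_names: list[str]
    tmin_s: float

    @property
    def times(self) -> np.ndarray:
        return self.tmin_s + np.arange(self.data.shape[1]) / self.fs


def evoked_average(epochs: EpochSet) -> list[Evoked]:
    """One evoked per condition present, as the arithmetic mean over trials."""
    conditions = [c for c in pd.unique(epochs.conditions) if c is not None]
    if not conditions:
        raise ValueError("epoch set has no labeled conditions")
    out = []
    for cond in conditions:
        mask = epochs.conditions == cond
        if not mask.any():
            raise ValueError(f"condition {cond!r} has no trials")
        out.append(
            Evoked(
                condition=str(cond),
                participant=epochs.participant,
                data=epochs.epochs[mask].mean(axis=0),
                n_trials=int(mask.sum()),
                fs=epochs.fs,
                channel_names=list(epochs.channel_names),
                tmin_s=epochs.tmin_s,
            )
        )
    return out


def grand_average(evokeds: list[Evoked]) -> GrandAverage:
    """Mean over participants; every participant counts once."""
    if not evokeds:
        raise ValueError("no evokeds given")
    first = evokeds[0]
    for ev in evokeds[1:]:
        if ev.condition != first.condition:
            raise ValueError(
                f"mixed conditions: {ev.condition!r} vs {first.condition!r}"
            )
        if ev.channel_names != first.channel_names or ev.data.shape != first.data.shape:
            raise ValueError("evokeds disagree on montage or time axis")
    stack = np.stack([ev.data for ev in evokeds])
    return GrandAverage(
        condition=first.condition,
        data=stack.mean(axis=0),
        n_participants=len(evokeds),
        fs=first.fs,
        channel_names=first.channel_names,
        tmin_s=first.tmin_s,
    )


def _window_slice(tmin_s: float, fs: float, window: tuple[float, float]) -> slice:
    lo = int(round((window[0] - tmin_s) * fs))
    hi = int(round((window[1] - tmin_s) * fs))
    return slice(lo, hi + 1)  # inclusive endpoints


def roi_mean_amplitude(
    source: Evoked | GrandAverage | EpochSet,
    rois: RoiSet = DEFAULT_ROIS,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Mean amplitude over ROI channels then window samples.

    For an :class:`EpochSet` one row per trial x ROI is produced (columns
    ``unit`` = trial index, ``condition``, ``roi``, ``amplitude_uv``); for
    an evoked or grand average, one row per ROI.
    """
    n_t = (source.epochs if isinstance(source, EpochSet) else source.data).shape[-1]
    tmin = source.tmin_s
    fs = source.fs
    t_end = tmin + (n_t - 1) / fs
    if window[0] < tmin - 1e-9 or window[1] > t_end + 1e-9:
        raise ValueError(f"window {window} outside epoch range [{tmin}, {t_end}]")
    idx = rois.indices(source.channel_names)
    sl = _window_slice(tmin, fs, window)

    rows = []
    if isinstance(source, EpochSet):
        for roi, chans in idx.items():
            vals = source.epochs[:, chans, sl].mean(axis=(1, 2))
            for i, (v, cond) in enumerate(zip(vals, source.conditions)):
                rows.append(
                    (f"{source.participant}/{i}", str(cond), roi, float(v))
                )
    else:
        cond = source.condition
        unit = getattr(source, "participant", "grand_average")
        for roi, chans in idx.items():
            rows.append((unit, cond, roi, float(source.data[chans, sl].mean())))
    return pd.DataFrame(rows, columns=["unit", "condition", "roi", "amplitude_uv"])


def amplitude_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot an amplitude table to ROI x condition cell means."""
    return table.pivot_table(
        index="roi", columns="condition", values="amplitude_uv", aggfunc="mean"
    )


def export_roi_waveforms(
    gas: list[GrandAverage], rois: RoiSet = DEFAULT_ROIS
) -> pd.DataFrame:
    """ROI-averaged time series per condition as a long-format table."""
    rows = []
    for ga in gas:
        idx = rois.indices(ga.channel_names)
        times = ga.times
        for roi, chans in idx.items():
            series = ga.data[chans].mean(axis=0)
            for t, v in zip(times, series):
                rows.append((ga.condition, roi, float(t), float(v)))
    return pd.DataFrame(rows, columns=["condition", "roi", "time_s", "amplitude_uv"])
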
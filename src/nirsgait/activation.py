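"""Epoch segmentation, block averaging, and baseline-corrected activation.

Activation for a condition is the mean HbO2 over the task extraction window
(3-60 s after walk onset, intersected with the condition's analysis window)
minus the mean over the 5 s immediately preceding walk onset. Walk onsets are
the block boundaries (60 s and 150 s); the published analysis windows
(62.5-120 s, 152.5-210 s) are treated as pre-trimmed ranges, giving
extraction windows [63, 120) and [153, 210) seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CONDITIONS,
    N_CHANNELS,
    HbSeries,
    Montage,
    Paradigm,
    ValidationError,
    window_slice,
)

__all__ = ["Epoch", "EpochSet", "segment_epochs", "block_average", "activation_value", "roi_aggregate"]


@dataclass(frozen=True)
class Epoch:
    condition: str
    window_s: tuple[float, float]
    task: slice
    baseline: slice | None
    baseline_s: tuple[float, float] | None


@dataclass(frozen=True)
class EpochSet:
    fs: float
    epochs: dict[str, Epoch]

    def __getitem__(self, condition: str) -> Epoch:
        return self.epochs[condition]


def segment_epochs(hb: HbSeries, paradigm: Paradigm | None = None) -> EpochSet:
    """Condition windows with their baseline intervals, as sample slices.

    For the walking conditions, baseline = [onset - 5 s, onset) and the task
    range = [onset + 3 s, window end), both half-open with sample index
    floor(t * fs). The rest condition has no baseline (it *is* the baseline
    state). Raises when the recording does not cover a required window.
    """
    paradigm = paradigm or hb.paradigm
    fs = hb.fs
    missing = [c for c in CONDITIONS if c not in paradigm.analysis_windows]
    if missing:
        raise ValidationError(f"paradigm lacks analysis windows for: {', '.join(missing)}")
    dur = hb.n_samples / fs
    epochs: dict[str, Epoch] = {}
    too_short = []
    for cond in CONDITIONS:
        start, end = paradigm.analysis_windows[cond]
        if end > dur + 1e-9:
            too_short.append(f"{cond} [{start}, {end})")
            continue
        if cond == "rest":
            epochs[cond] = Epoch(cond, (start, end), window_slice((start, end), fs), None, None)
        else:
            onset = paradigm.walk_onset(cond)
            t0, _ = paradigm.task_extract_window
            ext = (max(start, onset + t0), end)
            base = (onset - paradigm.baseline_window_s, onset)
            epochs[cond] = Epoch(cond, ext, window_slice(ext, fs), window_slice(base, fs), base)
    if too_short:
        raise ValidationError(f"recording of {dur:.1f} s does not cover windows: {', '.join(too_short)}")
    return EpochSet(fs=fs, epochs=epochs)


def block_average(trials: list[np.ndarray]) -> np.ndarray:
    """Sample-wise mean across same-condition trials (identity for one trial)."""
    if len(trials) == 0:
        raise ValidationError("block_average requires at least one trial")
    lengths = {t.shape[-1] for t in trials}
    if len(lengths) > 1:
        raise ValidationError(f"trial lengths differ: {sorted(lengths)}")
    return np.mean(trials, axis=0)


def activation_value(hb: HbSeries, epoch: Epoch) -> np.ndarray:
    """Per-channel activation: mean(task window) - mean(baseline window), HbO2.

    QC-excluded channels propagate as NaN. A rest epoch (no baseline) returns
    the plain window mean.
    """
    x = hb.hbo
    task = x[:, epoch.task]
    if task.shape[1] == 0:
        raise ValidationError(f"empty task window for condition {epoch.condition!r}")
    task_mean = task.mean(axis=1)
    if epoch.baseline is None:
        return task_mean
    base = x[:, epoch.baseline]
    if base.shape[1] == 0:
        raise ValidationError(f"empty baseline window for condition {epoch.condition!r}")
    return task_mean - base.mean(axis=1)


def roi_aggregate(channel_values: np.ndarray, montage: Montage) -> dict[str, float]:
    """Unweighted mean over each ROI's retained (finite) member channels.

    Channels outside every ROI are ignored; a ROI whose members are all
    missing yields NaN with a warning.
    """
    channel_values = np.asarray(channel_values, dtype=float)
    if channel_values.shape != (N_CHANNELS,):
        raise ValidationError(f"expected one value per channel, got shape {channel_values.shape}")
    out: dict[str, float] = {}
    for roi in montage.roi_map:
        vals = channel_values[montage.roi_indices(roi)]
        if np.all(np.isnan(vals)):
            warnings.warn(f"ROI {roi}: no retained channels, value is missing", stacklevel=2)
            out[roi] = np.nan
        else:
            out[roi] = float(np.nanmean(vals))
    return out


def activation_table(hb: HbSeries, montage: Montage, paradigm: Paradigm | None = None) -> pd.DataFrame:
    """Long table of channel- and ROI-level activation for one subject."""
    epochs = segment_epochs(hb, paradigm)
    rows = []
    for cond, ep in epochs.epochs.items():
        ch_vals = activation_value(hb, ep)
        for c in range(N_CHANNELS):
            rows.append(
                dict(subject_id=hb.subject_id, group=hb.group, condition=cond,
                     level="channel", label=str(c + 1), value=ch_vals[c])
            )
        for roi, v in roi_aggregate(ch_vals, montage).items():
            rows.append(
                dict(subject_id=hb.subject_id, group=hb.group, condition=cond,
                     level="roi", label=roi, value=v)
            )
    return pd.DataFrame(rows)
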
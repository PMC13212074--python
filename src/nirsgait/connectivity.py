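"""Channel-wise Pearson functional connectivity and ROI-level aggregation.

Connectivity is computed per condition on the same HbO2 extraction windows as
activation ([63, 120) s for the freeze-induction walk, [153, 210) s for normal
walking, [0, 60) s rest). Values are raw Pearson r (no Fisher transform by
default, negative correlations retained), matching how group means are
reported in the field's tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import N_CHANNELS, HbSeries, Montage, ValidationError
from .activation import segment_epochs

__all__ = ["FCMatrix", "fc_matrix", "roi_pair_fc", "channel_pair_table", "KEY_CHANNEL_PAIRS", "subject_fc"]

#: The ten key channel pairs the study tracked across cueing conditions.
KEY_CHANNEL_PAIRS: tuple[tuple[int, int], ...] = (
    (1, 27), (1, 31), (3, 35), (4, 43), (5, 42),
    (11, 27), (16, 27), (17, 41), (23, 27), (31, 35),
)

MIN_WINDOW_SAMPLES = 30


@dataclass
class FCMatrix:
    subject_id: str
    group: str
    condition: str
    matrix: np.ndarray  # (48, 48) Pearson r, NaN rows/cols for missing channels
    valid: np.ndarray  # (48,) channel usable in this window

    def r(self, ch_a: int, ch_b: int) -> float:
        """Pearson r between two 1-based channel ids."""
        return float(self.matrix[ch_a - 1, ch_b - 1])


def fc_matrix(hb: HbSeries, condition: str, fisher: bool = False) -> FCMatrix:
    """Pairwise Pearson correlation over a condition's extraction window.

    QC-excluded and zero-variance channels propagate as NaN rows/columns
    (with a warning for zero variance). ``fisher=True`` returns arctanh(r).
    """
    ep = segment_epochs(hb)[condition]
    x = hb.hbo[:, ep.task]
    if x.shape[1] < MIN_WINDOW_SAMPLES:
        raise ValidationError(
            f"window for {condition!r} has {x.shape[1]} samples; need >= {MIN_WINDOW_SAMPLES}"
        )
    valid = hb.qc_mask.copy()
    sd = np.nanstd(x, axis=1)
    zero_var = valid & (sd == 0)
    if zero_var.any():
        warnings.warn(
            f"zero-variance channels in {condition!r} window: {list(np.flatnonzero(zero_var) + 1)}",
            stacklevel=2,
        )
        valid &= ~zero_var
    m = np.full((N_CHANNELS, N_CHANNELS), np.nan)
    idx = np.flatnonzero(valid)
    if idx.size >= 2:
        sub = np.corrcoef(x[idx])
        m[np.ix_(idx, idx)] = sub
    elif idx.size == 1:
        m[idx[0], idx[0]] = 1.0
    if fisher:
        with np.errstate(divide="ignore"):
            m = np.arctanh(np.clip(m, -1.0, 1.0))
    return FCMatrix(hb.subject_id, hb.group, condition, m, valid)


def roi_pair_fc(fc: FCMatrix, montage: Montage) -> dict[str, float]:
    """Inter- and intra-ROI connectivity from a channel FC matrix.

    Inter pair "A-B": mean r over all (i in A, j in B). Intra "A-A": mean
    over unordered distinct channel pairs within A (diagonal excluded).
    NaN channels are skipped; a cell with no usable pair is NaN.
    """
    rois = list(montage.roi_map)
    out: dict[str, float] = {}
    for a, b in combinations(rois, 2):
        block = fc.matrix[np.ix_(montage.roi_indices(a), montage.roi_indices(b))]
        out[f"{a}-{b}"] = float(np.nanmean(block)) if np.any(np.isfinite(block)) else np.nan
    for a in rois:
        ia = montage.roi_indices(a)
        block = fc.matrix[np.ix_(ia, ia)]
        iu = np.triu_indices(len(ia), k=1)
        vals = block[iu]
        out[f"{a}-{a}"] = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else np.nan
    return out


def channel_pair_table(
    fc_list: list[FCMatrix],
    pairs: tuple[tuple[int, int], ...] = KEY_CHANNEL_PAIRS,
    montage: Montage | None = None,
) -> pd.DataFrame:
    """Long table of named channel-pair correlations, one row per
    subject x condition x pair, ready for repeated-measures testing."""
    for a, b in pairs:
        if not (1 <= a <= N_CHANNELS and 1 <= b <= N_CHANNELS):
            raise ValidationError(f"unknown channel id in pair ({a}, {b})")
    rows = []
    for fc in fc_list:
        for a, b in pairs:
            roi_label = ""
            if montage is not None:
                roi_label = f"{montage.roi_of(a)}-{montage.roi_of(b)}"
            rows.append(
                dict(
                    subject_id=fc.subject_id, group=fc.group, condition=fc.condition,
                    pair=f"{a}-{b}", roi_pair=roi_label, r=fc.r(a, b),
                )
            )
    return pd.DataFrame(rows, columns=["subject_id", "group", "condition", "pair", "roi_pair", "r"])


def subject_fc(hb: HbSeries, montage: Montage, conditions: tuple[str, ...] = ("freeze_walk", "normal_walk")) -> pd.DataFrame:
    """ROI-level connectivity rows for one subject across conditions."""
    rows = []
    for cond in conditions:
        fc = fc_matrix(hb, cond)
        for label, v in roi_pair_fc(fc, montage).items():
            rows.append(
                dict(subject_id=hb.subject_id, group=hb.group, condition=cond, label=label, value=v)
            )
    return pd.DataFrame(rows)
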
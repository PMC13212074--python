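"""Raw intensity -> clean hemoglobin series.

Stages, in the order applied by :func:`preprocess_recording`:

1. channel quality control (coefficient of variation of raw intensity,
   exclude when CV > 14% at either wavelength),
2. conversion to optical density (OD) changes,
3. motion-artifact detection (moving-window range vs. 6x channel SD or a
   0.5-OD amplitude ceiling) and cubic-smoothing-spline correction, both in
   the OD domain,
4. modified Beer-Lambert inversion to HbO2/HHb concentration changes
   (umol/L; DPF 6.0, 3 cm separation),
5. zero-phase Butterworth bandpass, 0.01-0.2 Hz.

The molar extinction table is shared with the forward model in
:mod:`nirsgait.simulate`, so forward/inverse round trips are exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import butter, sosfiltfilt

from .core import N_CHANNELS, HbSeries, RawIntensityRecording, ValidationError

__all__ = [
    "EXTINCTION_CM_PER_M",
    "MBLLParams",
    "MotionParams",
    "FilterParams",
    "QCReport",
    "channel_qc",
    "intensity_to_od",
    "mbll",
    "mbll_forward",
    "detect_motion_artifacts",
    "spline_correct",
    "bandpass",
    "preprocess_recording",
]

#: Molar extinction coefficients, cm^-1 (mol/L)^-1, keyed by wavelength (nm):
#: (epsilon_HbO2, epsilon_HHb). Standard literature compilation values,
#: pinned so the simulator's forward model and this inverter agree exactly.
EXTINCTION_CM_PER_M: dict[float, tuple[float, float]] = {
    730.0: (390.0, 1102.2),
    850.0: (1058.0, 691.32),
}


@dataclass(frozen=True)
class MBLLParams:
    """Modified Beer-Lambert parameters. DPF and separation follow the study."""

    dpf: float = 6.0
    separation_cm: float = 3.0
    wavelengths: tuple[float, float] = (730.0, 850.0)
    extinction: dict[float, tuple[float, float]] = field(default_factory=lambda: dict(EXTINCTION_CM_PER_M))

    def matrix(self) -> np.ndarray:
        """2x2 matrix mapping (dHbO2, dHHb) in umol/L to dOD per wavelength."""
        try:
            eps = np.array([self.extinction[w] for w in self.wavelengths])
        except KeyError as exc:
            raise ValidationError(f"no extinction coefficients for wavelength {exc}") from exc
        a = eps * self.separation_cm * self.dpf * 1e-6  # per umol/L
        if np.linalg.cond(a) > 1e3:
            raise ValidationError("extinction matrix is ill-conditioned; check wavelengths/coefficients")
        return a


@dataclass(frozen=True)
class MotionParams:
    stdev_thresh: float = 6.0  # multiples of channel-global OD SD
    amp_thresh: float = 0.5  # OD units, peak-to-peak within the window
    t_motion: float = 0.5  # s, sliding detection window
    t_mask: float = 1.0  # s, dilation of flagged instants

    def __post_init__(self) -> None:
        if min(self.stdev_thresh, self.amp_thresh, self.t_motion, self.t_mask) <= 0:
            raise ValidationError("all motion parameters must be positive")


@dataclass(frozen=True)
class FilterParams:
    band: tuple[float, float] = (0.01, 0.2)  # Hz
    order: int = 3
    zero_phase: bool = True

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValidationError("filter band must satisfy 0 < low < high")


@dataclass
class QCReport:
    """Per channel x wavelength CV (%) and the resulting retention mask."""

    cv_percent: np.ndarray  # (48, 2)
    retained: np.ndarray  # (48,)
    threshold: float
    reasons: dict[int, str] = field(default_factory=dict)  # 1-based channel id -> reason

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "channel": np.arange(1, N_CHANNELS + 1),
                "cv_wl1_percent": self.cv_percent[:, 0],
                "cv_wl2_percent": self.cv_percent[:, 1],
                "retained": self.retained,
                "reason": [self.reasons.get(c, "") for c in range(1, N_CHANNELS + 1)],
            }
        )


def cv_percent(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Coefficient of variation, percent: 100 * sample SD / mean."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 100.0 * x.std(axis=axis, ddof=1) / x.mean(axis=axis)


def channel_qc(rec: RawIntensityRecording, threshold: float = 14.0) -> QCReport:
    """Coefficient-of-variation channel QC on raw intensity.

    CV = 100 * sample SD / mean per channel and wavelength over the whole
    recording; a channel is retained iff CV <= threshold at *both*
    wavelengths (the exclusion rule is strictly CV > threshold). Channels
    with a non-positive mean have undefined CV and are excluded.
    """
    mean = rec.data.mean(axis=2)
    cv = cv_percent(rec.data, axis=2)
    reasons: dict[int, str] = {}
    retained = np.ones(N_CHANNELS, dtype=bool)
    for c in range(N_CHANNELS):
        if not np.all(np.isfinite(cv[c])) or np.any(mean[c] <= 0):
            retained[c] = False
            reasons[c + 1] = "undefined CV (non-positive mean intensity)"
        elif np.max(cv[c]) > threshold:
            retained[c] = False
            reasons[c + 1] = f"CV {np.max(cv[c]):.2f}% > {threshold}%"
    return QCReport(cv_percent=cv, retained=retained, threshold=threshold, reasons=reasons)


def intensity_to_od(data: np.ndarray) -> np.ndarray:
    """Optical-density change: dOD(t) = -log10(I(t) / mean(I)), per series."""
    data = np.asarray(data, dtype=float)
    if np.any(data <= 0) or not np.all(np.isfinite(data)):
        raise ValidationError("intensities must be finite and > 0 for OD conversion")
    ref = data.mean(axis=-1, keepdims=True)
    return -np.log10(data / ref)


def mbll(od: np.ndarray, params: MBLLParams | None = None) -> np.ndarray:
    """Invert the modified Beer-Lambert law.

    ``od`` has shape (..., 2 wavelengths, T); returns concentration changes
    (..., 2 chromophores (HbO2, HHb), T) in umol/L.
    """
    params = params or MBLLParams()
    a_inv = np.linalg.inv(params.matrix())
    return np.einsum("cw,...wt->...ct", a_inv, np.asarray(od, dtype=float))


def mbll_forward(conc_um: np.ndarray, params: MBLLParams | None = None) -> np.ndarray:
    """Forward Beer-Lambert map: concentrations (umol/L) -> dOD. Shared with the simulator."""
    params = params or MBLLParams()
    return np.einsum("wc,...ct->...wt", params.matrix(), np.asarray(conc_um, dtype=float))


def detect_motion_artifacts(
    od: np.ndarray, params: MotionParams | None = None, fs: float = 11.0
) -> np.ndarray:
    """Flag motion-contaminated samples in OD series.

    Within each sliding window of ``t_motion`` seconds a sample is flagged
    when the window's signal range exceeds ``stdev_thresh`` times the
    channel-global SD, or ``amp_thresh`` OD outright; flags are dilated by
    +-``t_mask`` seconds. Input shape (..., T); wavelength axes (if present)
    are OR-reduced so the mask is per channel: output shape (n_channels, T)
    for (n_channels, 2, T) input, else input shape.
    """
    params = params or MotionParams()
    od = np.asarray(od, dtype=float)
    w = max(2, int(round(params.t_motion * fs)))
    rng_ = maximum_filter1d(od, w, axis=-1, mode="nearest") - minimum_filter1d(od, w, axis=-1, mode="nearest")
    sd = od.std(axis=-1, keepdims=True)
    flagged = (rng_ > params.stdev_thresh * sd) | (rng_ > params.amp_thresh)
    if flagged.ndim == 3:
        flagged = flagged.any(axis=1)
    pad = int(round(params.t_mask * fs))
    if pad > 0 and flagged.any():
        # dilation by +-pad samples == running maximum over a (2 pad + 1) window
        flagged = maximum_filter1d(flagged.astype(np.uint8), 2 * pad + 1, axis=-1).astype(bool)
    return flagged


def _segments(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Alternating (start, stop, is_artifact) runs covering [0, len)."""
    edges = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    bounds = np.concatenate(([0], edges, [mask.size]))
    return [(int(a), int(b), bool(mask[a])) for a, b in zip(bounds[:-1], bounds[1:])]


def _smoothing_spline_fit(t: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Natural cubic smoothing spline fitted values at the data points.

    Solves min ||y - f||^2 + lam * integral f''^2 (the Reinsch formulation,
    f = (I + lam K)^-1 y with K = D^T W^-1 D) by a dense solve — equivalent to
    ``scipy.interpolate.make_smoothing_spline`` but far cheaper on the short
    artifact segments this is applied to. Falls back to scipy for long runs.
    """
    n = len(t)
    if n > 400:
        return make_smoothing_spline(t, y, lam=lam)(t)
    h = np.diff(t)
    # second-divided-difference matrix D ((n-2) x n) and Gram matrix W
    d = np.zeros((n - 2, n))
    rows = np.arange(n - 2)
    d[rows, rows] = 1.0 / h[:-1]
    d[rows, rows + 1] = -(1.0 / h[:-1] + 1.0 / h[1:])
    d[rows, rows + 2] = 1.0 / h[1:]
    w = np.diag((h[:-1] + h[1:]) / 3.0)
    off = h[1:-1] / 6.0
    w[rows[:-1], rows[:-1] + 1] = off
    w[rows[:-1] + 1, rows[:-1]] = off
    k = d.T @ np.linalg.solve(w, d)
    return np.linalg.solve(np.eye(n) + lam * k, y)


def spline_correct(
    od: np.ndarray,
    artifact_mask: np.ndarray,
    fs: float = 11.0,
    smoothing: float = 0.99,
) -> np.ndarray:
    """Cubic-smoothing-spline motion correction in the OD domain.

    Each flagged segment is fit with a cubic smoothing spline (penalty
    ``lam = (1 - smoothing) / smoothing``), the fit subtracted, and the
    segment re-levelled to the mean of the preceding clean segment (the
    following one when the artifact starts the recording). Segments after an
    artifact are shifted to restore continuity at the boundary, so sustained
    baseline steps are removed, not just masked. Unflagged data within a
    segment is otherwise unchanged.
    """
    od = np.asarray(od, dtype=float)
    artifact_mask = np.asarray(artifact_mask, dtype=bool)
    if artifact_mask.shape[-1] != od.shape[-1]:
        raise ValidationError("artifact mask length does not match the series")
    if not artifact_mask.any():
        return od.copy()
    # penalty scale chosen so the default smoothing (0.99) is near-interpolating
    # on artifact segments: the fit tracks even sub-sample discontinuities to
    # measurement-noise level, which is what subtracting the artifact shape needs
    lam = (1.0 - smoothing) / smoothing * 0.01
    w_edge = max(1, int(round(1.0 * fs)))  # boundary-mean window for continuity

    def correct_1d(y: np.ndarray, mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            return y
        if mask.all():
            return y - y.mean()
        out = np.empty_like(y)
        segs = _segments(mask)
        prev_clean_mean: float | None = None
        # level each artifact segment against its preceding clean segment;
        # shift every subsequent segment to keep the series continuous
        offset = 0.0
        for k, (a, b, is_art) in enumerate(segs):
            seg = y[a:b]
            if not is_art:
                if k > 0 and segs[k - 1][2]:
                    # continuity with the corrected artifact segment
                    prev_tail = out[max(0, a - w_edge) : a]
                    offset = prev_tail.mean() - seg[: min(len(seg), w_edge)].mean()
                out[a:b] = seg + offset
                prev_clean_mean = out[a:b].mean()
            else:
                # sample-index abscissa: with lam = (1-p)/p ~ 0.01 the spline
                # tracks the artifact waveform closely (near-interpolating),
                # so subtraction leaves only measurement-scale residuals
                t = np.arange(a, b, dtype=float)
                if len(seg) >= 4:
                    fit = _smoothing_spline_fit(t, seg, lam)
                else:
                    fit = np.full(len(seg), seg.mean())
                resid = seg - fit
                if prev_clean_mean is None:
                    # artifact at the recording start: level against the following clean segment
                    nxt = next((s for s in segs[k + 1 :] if not s[2]), None)
                    level = y[nxt[0] : nxt[1]].mean() if nxt else seg.mean()
                else:
                    level = prev_clean_mean
                out[a:b] = resid + level
        return out

    flat = od.reshape(-1, od.shape[-1]).copy()
    if artifact_mask.ndim == od.ndim:
        mflat = artifact_mask.reshape(-1, od.shape[-1])
    else:
        # per-channel mask applied to every wavelength of that channel
        reps = flat.shape[0] // artifact_mask.shape[0]
        mflat = np.repeat(artifact_mask, reps, axis=0)
    for i in np.flatnonzero(mflat.any(axis=1)):
        flat[i] = correct_1d(flat[i], mflat[i])
    return flat.reshape(od.shape)


def _sos(params: FilterParams, fs: float) -> np.ndarray:
    low, high = params.band
    if high >= fs / 2:
        raise ValidationError(f"upper cutoff {high} Hz must be below Nyquist ({fs / 2} Hz)")
    return butter(params.order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(data: np.ndarray, params: FilterParams | None = None, fs: float = 11.0) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth bandpass along the last axis."""
    params = params or FilterParams()
    data = np.asarray(data, dtype=float)
    sos = _sos(params, fs)
    min_len = 3 * 2 * (2 * params.order + 1)  # forward-backward startup margin
    if data.shape[-1] < min_len:
        raise ValidationError(
            f"series of {data.shape[-1]} samples is shorter than 3x the filter startup "
            f"length ({min_len}); pad or extend the recording"
        )
    if not params.zero_phase:
        from scipy.signal import sosfilt

        return sosfilt(sos, data, axis=-1)
    return sosfiltfilt(sos, data, axis=-1)


def preprocess_recording(
    rec: RawIntensityRecording,
    qc_threshold: float = 14.0,
    mbll_params: MBLLParams | None = None,
    motion_params: MotionParams | None = None,
    filter_params: FilterParams | None = None,
    motion_correction: bool = True,
    filtering: bool = True,
) -> tuple[HbSeries, QCReport]:
    """Full preprocessing chain: QC -> OD -> motion handling -> MBLL -> bandpass."""
    mbll_params = mbll_params or MBLLParams(wavelengths=rec.wavelengths)
    qc = channel_qc(rec, threshold=qc_threshold)
    od = intensity_to_od(rec.data)
    if motion_correction:
        mask = detect_motion_artifacts(od, motion_params, fs=rec.fs)
        od = spline_correct(od, mask, fs=rec.fs)
    else:
        mask = np.zeros((N_CHANNELS, rec.n_samples), dtype=bool)
    conc = mbll(od, mbll_params)
    if filtering:
        conc = bandpass(conc, filter_params, fs=rec.fs)
    if not qc.retained.all():
        excluded = [c + 1 for c in range(N_CHANNELS) if not qc.retained[c]]
        warnings.warn(f"QC excluded channels {excluded}", stacklevel=2)
    return (
        HbSeries(
            data=conc,
            fs=rec.fs,
            qc_mask=qc.retained,
            artifact_mask=mask,
            subject_id=rec.subject_id,
            group=rec.group,
            paradigm=rec.paradigm,
        ),
        qc,
    )
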
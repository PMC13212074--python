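"""Readers and writers: SNIRF (HDF5) and long-format CSV recordings, result tables.

The SNIRF layout written here is the minimal continuous-wave subset:
``/nirs/data1/dataTimeSeries`` (T x 96, channel-major then wavelength),
one ``measurementList`` group per column, probe wavelengths/positions,
and one ``stim`` group per paradigm block. The paradigm's analysis windows
are carried in a metaDataTags entry so recordings round-trip exactly.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    N_CHANNELS,
    Paradigm,
    RawIntensityRecording,
    ValidationError,
    build_default_montage,
    default_paradigm,
)

__all__ = ["read_recording", "write_recording", "write_tables"]

_CSV_COLUMNS = ["time_s", "channel", "wavelength_nm", "intensity"]


def _infer_format(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix == ".snirf":
        return "snirf"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer format from {path}; pass format='snirf' or 'csv'")


def write_recording(rec: RawIntensityRecording, path: str | os.PathLike, format: str | None = None) -> Path:
    """Write a raw recording as SNIRF or long-format CSV; returns the path."""
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "snirf":
        _write_snirf(rec, path)
    elif fmt == "csv":
        _write_csv(rec, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_recording(path: str | os.PathLike, format: str | None = None) -> RawIntensityRecording:
    """Read a SNIRF or long-format CSV recording and validate its invariants."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "snirf":
        return _read_snirf(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# SNIRF
# ---------------------------------------------------------------------------


def _write_snirf(rec: RawIntensityRecording, path: Path) -> None:
    montage = build_default_montage()
    n_t = rec.n_samples
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject_id)
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset("Group", data=rec.group)
        meta.create_dataset("ParadigmJSON", data=rec.paradigm.to_json())
        data1 = nirs.create_group("data1")
        # columns: (channel 1, wl 1), (channel 1, wl 2), (channel 2, wl 1), ...
        ts = rec.data.reshape(2 * N_CHANNELS, n_t).T
        data1.create_dataset("dataTimeSeries", data=ts)
        data1.create_dataset("time", data=np.array([0.0, 1.0 / rec.fs]))
        for col in range(2 * N_CHANNELS):
            ch = montage.channels[col // 2]
            ml = data1.create_group(f"measurementList{col + 1}")
            ml.create_dataset("sourceIndex", data=ch.source_id)
            ml.create_dataset("detectorIndex", data=ch.detector_id)
            ml.create_dataset("wavelengthIndex", data=col % 2 + 1)
            ml.create_dataset("dataType", data=1)
            ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths))
        probe.create_dataset("sourcePos3D", data=np.asarray(montage.source_pos))
        probe.create_dataset("detectorPos3D", data=np.asarray(montage.detector_pos))
        for k, (label, start, end) in enumerate(rec.paradigm.blocks):
            stim = nirs.create_group(f"stim{k + 1}")
            stim.create_dataset("name", data=label)
            stim.create_dataset("data", data=np.array([[start, end - start, 1.0]]))


def _read_str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def _read_snirf(path: Path) -> RawIntensityRecording:
    try:
        with h5py.File(path, "r") as f:
            nirs = f["nirs"]
            meta = nirs["metaDataTags"]
            subject = _read_str(meta["SubjectID"])
            group = _read_str(meta["Group"]) if "Group" in meta else "HC"
            paradigm = (
                Paradigm.from_json(_read_str(meta["ParadigmJSON"]))
                if "ParadigmJSON" in meta
                else default_paradigm()
            )
            data1 = nirs["data1"]
            ts = np.asarray(data1["dataTimeSeries"])
            time = np.asarray(data1["time"])
            wl = tuple(float(w) for w in np.asarray(nirs["probe"]["wavelengths"]))
    except (KeyError, OSError) as exc:
        raise ValidationError(f"malformed SNIRF file {path}: {exc}") from exc
    if ts.ndim != 2 or ts.shape[1] != 2 * N_CHANNELS:
        raise ValidationError(f"malformed SNIRF file {path}: expected {2 * N_CHANNELS} data columns, got {ts.shape}")
    dt = time[1] - time[0] if time.size == 2 else float(np.median(np.diff(time)))
    fs = 1.0 / dt
    data = ts.T.reshape(N_CHANNELS, 2, ts.shape[0])
    return RawIntensityRecording(
        subject_id=subject, group=group, fs=fs, data=data, wavelengths=wl, paradigm=paradigm
    )


# ---------------------------------------------------------------------------
# Long-format CSV
# ---------------------------------------------------------------------------


def _write_csv(rec: RawIntensityRecording, path: Path) -> None:
    n_t = rec.n_samples
    t = rec.times
    header = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "fs": rec.fs,
        "wavelengths": list(rec.wavelengths),
        "paradigm": json.loads(rec.paradigm.to_json()),
    }
    ch = np.repeat(np.arange(1, N_CHANNELS + 1), 2 * n_t)
    wl = np.tile(np.repeat(np.asarray(rec.wavelengths), n_t), N_CHANNELS)
    df = pd.DataFrame(
        {
            "time_s": np.tile(t, 2 * N_CHANNELS),
            "channel": ch,
            "wavelength_nm": wl,
            "intensity": rec.data.reshape(-1),
        }
    )
    with open(path, "w") as fh:
        fh.write("# nirsgait-recording " + json.dumps(header) + "\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def _read_csv(path: Path) -> RawIntensityRecording:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# nirsgait-recording "):
            raise ValidationError(f"malformed CSV {path}: missing recording header line")
        header = json.loads(first[len("# nirsgait-recording ") :])
        df = pd.read_csv(fh)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"malformed CSV {path}: missing columns {missing}")
    bad = df[~(np.isfinite(df["intensity"]) & (df["intensity"] > 0))]
    if len(bad):
        row = bad.iloc[0]
        raise ValidationError(
            f"malformed CSV {path}: non-positive intensity at time {row['time_s']} s, "
            f"channel {int(row['channel'])}, wavelength {row['wavelength_nm']} nm"
        )
    wavelengths = tuple(float(w) for w in header["wavelengths"])
    fs = float(header["fs"])
    times = np.sort(df["time_s"].unique())
    if len(times) > 1:
        fs_data = 1.0 / float(np.median(np.diff(times)))
        if abs(fs_data - fs) / fs > 0.01:
            raise ValidationError(
                f"malformed CSV {path}: header fs={fs} Hz disagrees with data spacing ({fs_data:.3f} Hz)"
            )
    n_t = len(times)
    pivot = df.pivot_table(index=["channel", "wavelength_nm"], columns="time_s", values="intensity", sort=True)
    if pivot.shape != (2 * N_CHANNELS, n_t):
        raise ValidationError(f"malformed CSV {path}: expected a complete 48x2 channel/wavelength grid")
    data = np.empty((N_CHANNELS, 2, n_t))
    for ci in range(N_CHANNELS):
        for wi, w in enumerate(wavelengths):
            data[ci, wi] = pivot.loc[(ci + 1, w)].to_numpy()
    paradigm = Paradigm.from_json(json.dumps(header["paradigm"]))
    return RawIntensityRecording(
        subject_id=header["subject_id"],
        group=header["group"],
        fs=fs,
        data=data,
        wavelengths=wavelengths,
        paradigm=paradigm,
    )


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

TABLE_COLUMNS = [
    "label",
    "group_a",
    "mean_a",
    "sd_a",
    "group_b",
    "mean_b",
    "sd_b",
    "test_name",
    "statistic",
    "df",
    "effect",
    "effect_kind",
    "p",
    "p_adjusted",
]


def write_tables(results: dict[str, pd.DataFrame], out_dir: str | os.PathLike) -> list[Path]:
    """Write one CSV per named result table (header-only when a table is empty).

    Each table mirrors the published layout: one row per ROI, ROI pair, or
    channel pair, with group summary cells, the test statistic, effect size,
    and raw/FDR-adjusted p values.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.items():
        if df is None or len(df) == 0:
            df = pd.DataFrame(columns=TABLE_COLUMNS)
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    return written
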
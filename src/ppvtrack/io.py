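"""Signal ingestion, preprocessing and annotation files.

Supported inputs: plain CSV (``time_s,value`` columns, or a single value
column with the rate given explicitly), and single-segment PhysioNet WFDB
records through a lightweight built-in reader (header parsing plus ``.dat``
formats 16 and 212, covering the MGHDB records).  Preprocessing is
anti-aliased integer-factor decimation (the published protocol downsamples
360 Hz recordings by 9 to 40 Hz) followed by mean-centering: the harmonic
model has no DC state, so the mean must be removed before tracking and is
carried along so envelopes can be re-offset to mm Hg.

Time convention: seconds from record start, sample n at t = n/fs, 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "SignalRecord",
    "AnnotationSet",
    "AnnotationError",
    "ChannelError",
    "read_signal",
    "preprocess",
    "read_annotations",
    "write_csv",
    "read_wfdb",
    "write_wfdb",
]

log = logging.getLogger(__name__)

MAX_GAP_FRACTION = 0.05


class ChannelError(ValueError):
    """Requested channel not present in the record."""


class AnnotationError(ValueError):
    """Malformed annotation file."""


@dataclass
class SignalRecord:
    record_id: str
    sample_rate: float
    samples: np.ndarray
    channel: str = "ABP"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be > 0")
        self.samples = np.asarray(self.samples, float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class AnnotationSet:
    """Beat-wise systolic peaks and diastolic troughs, plus optional
    respiratory-cycle boundary times."""

    peak_times: np.ndarray
    peak_values: np.ndarray
    trough_times: np.ndarray
    trough_values: np.ndarray
    cycle_times: np.ndarray | None = None


def _interpolate_gaps(x: np.ndarray, record_id: str) -> np.ndarray:
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    frac = bad.mean()
    if frac > MAX_GAP_FRACTION:
        raise ValueError(
            f"record {record_id}: {100 * frac:.1f}% non-finite samples "
            f"(limit {100 * MAX_GAP_FRACTION:.0f}%)")
    log.warning("record %s: interpolating %d non-finite samples", record_id, bad.sum())
    idx = np.arange(x.size)
    x = x.copy()
    x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return x


# --------------------------------------------------------------------------
# WFDB (single-segment records; .dat formats 16 and 212)

def _parse_header(hea_path: Path):
    lines = [ln.split("#")[0].strip() for ln in hea_path.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    rec = lines[0].split()
    name = rec[0].split("/")[0]
    n_sig = int(rec[1])
    fs = float(rec[2]) if len(rec) > 2 else 250.0
    n_samp = int(rec[3]) if len(rec) > 3 else 0
    sigs = []
    for ln in lines[1:1 + n_sig]:
        parts = ln.split()
        fname, fmt = parts[0], parts[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline, units = 200.0, 0, "mV"
        if len(parts) > 2:
            g = parts[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, b = g.rstrip(")").split("(")
                baseline = int(b)
            gain = float(g) if float(g) != 0 else 200.0
        desc = " ".join(parts[8:]) if len(parts) > 8 else f"sig{len(sigs)}"
        sigs.append(dict(file=fname, fmt=int(fmt), gain=gain,
                         baseline=baseline, units=units, desc=desc))
    return name, fs, n_samp, sigs


def _read_dat(path: Path, fmt: int, n_sig: int) -> np.ndarray:
    raw = path.read_bytes()
    if fmt == 16:
        data = np.frombuffer(raw, dtype="<i2")
        data = data[: (data.size // n_sig) * n_sig]
        return data.reshape(-1, n_sig)
    if fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: (b.size // 3) * 3].reshape(-1, 3).astype(np.int16)
        first = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
        second = b[:, 2] | ((b[:, 1] & 0xF0) << 4)
        first = np.where(first > 2047, first - 4096, first)
        second = np.where(second > 2047, second - 4096, second)
        data = np.empty(first.size * 2, dtype=np.int16)
        data[0::2], data[1::2] = first, second
        data = data[: (data.size // n_sig) * n_sig]
        return data.reshape(-1, n_sig)
    raise ValueError(f"unsupported WFDB signal format {fmt} (supported: 16, 212)")


def read_wfdb(record_path: str | Path, channel: str | int | None = None) -> SignalRecord:
    """Read one channel of a single-segment WFDB record.

    ``record_path`` is the record name with or without the ``.hea``
    extension.  ``channel`` may be an index, a (case-insensitive substring)
    label, or None to pick the first channel whose description matches an
    arterial-pressure label.
    """
    hea = Path(str(record_path)).with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    name, fs, n_samp, sigs = _parse_header(hea)
    labels = [s["desc"] for s in sigs]
    if channel is None:
        idx = next((i for i, d in enumerate(labels)
                    if "ABP" in d.upper() or "ART" in d.upper() or "BP" in d.upper()), None)
        if idx is None:
            raise ChannelError(f"no ABP-like channel found; available: {labels}")
    elif isinstance(channel, int):
        if not 0 <= channel < len(sigs):
            raise ChannelError(f"channel index {channel} out of range; available: {labels}")
        idx = channel
    else:
        matches = [i for i, d in enumerate(labels) if channel.lower() in d.lower()]
        if not matches:
            raise ChannelError(f"channel {channel!r} not found; available: {labels}")
        idx = matches[0]
    sig = sigs[idx]
    data = _read_dat(hea.parent / sig["file"], sig["fmt"], len(sigs))
    if n_samp:
        data = data[:n_samp]
    x = (data[:, idx].astype(float) - sig["baseline"]) / sig["gain"]
    x = _interpolate_gaps(x, name)
    return SignalRecord(record_id=name, sample_rate=fs, samples=x,
                        channel=labels[idx],
                        provenance={"file": str(hea), "channel_index": idx,
                                    "units": sig["units"]})


def write_wfdb(record_path: str | Path, rec: SignalRecord,
               gain: float = 100.0) -> None:
    """Write a record as WFDB format 16 (one channel).

    Values are quantized to ``round(value * gain)``; a gain of 100 keeps
    0.01 mm Hg resolution within int16 for physiological pressures.
    """
    base = Path(str(record_path))
    name = base.name
    adc = np.round(rec.samples * gain)
    if np.any(np.abs(adc) > 32767):
        raise ValueError("signal exceeds int16 range at this gain")
    (base.parent / f"{name}.hea").write_text(
        f"{name} 1 {rec.sample_rate:g} {rec.samples.size}\n"
        f"{name}.dat 16 {gain:g}(0)/mmHg 16 0 0 0 0 {rec.channel}\n")
    (base.parent / f"{name}.dat").write_bytes(
        adc.astype("<i2").tobytes())


# --------------------------------------------------------------------------
# CSV

def read_csv_signal(path: str | Path, sample_rate: float | None = None,
                    value_column: str | None = None) -> SignalRecord:
    df = pd.read_csv(path)
    cols = list(df.columns)
    if value_column is None:
        value_column = next((c for c in cols if c != "time_s"), None)
        if value_column is None:
            raise ValueError(f"{path}: no value column found (columns: {cols})")
    if "time_s" in cols:
        t = df["time_s"].to_numpy(float)
        dt = np.diff(t)
        if t.size < 2 or np.any(dt <= 0):
            raise ValueError(f"{path}: time_s column must be strictly increasing")
        inferred = 1.0 / np.median(dt)
        if sample_rate is not None and abs(inferred - sample_rate) / sample_rate > 0.01:
            raise ValueError(f"{path}: time column implies {inferred:.3f} Hz, "
                             f"got sample_rate={sample_rate}")
        sample_rate = inferred
    elif sample_rate is None:
        raise ValueError(f"{path}: no time_s column; pass sample_rate explicitly")
    x = _interpolate_gaps(df[value_column].to_numpy(float), Path(path).stem)
    return SignalRecord(record_id=Path(path).stem, sample_rate=float(sample_rate),
                        samples=x, channel=value_column,
                        provenance={"file": str(path)})


def read_signal(path: str | Path, channel: str | int | None = None,
                sample_rate: float | None = None) -> SignalRecord:
    """Read a signal from WFDB (``.hea``/record name) or CSV."""
    p = Path(str(path))
    if p.suffix == ".hea" or p.with_suffix(".hea").exists():
        return read_wfdb(p if p.suffix != ".hea" else p.with_suffix(""), channel)
    if p.suffix in (".csv", ".txt", ""):
        return read_csv_signal(p, sample_rate=sample_rate,
                               value_column=channel if isinstance(channel, str) else None)
    raise ValueError(f"cannot determine format of {path}")


def write_csv(path: str | Path, rec: SignalRecord) -> None:
    pd.DataFrame({"time_s": rec.times, rec.channel: rec.samples}).to_csv(
        path, index=False)


# --------------------------------------------------------------------------
# preprocessing

def preprocess(rec: SignalRecord, target_rate: float = 40.0,
               allow_resample: bool = False) -> SignalRecord:
    """Anti-aliased decimation to ``target_rate``, then mean-centering.

    The source rate must be an integer multiple of the target (e.g. the
    published 360 -> 40 Hz, factor 9) unless ``allow_resample`` permits
    polyphase resampling for other ratios.  The anti-alias filter is a
    zero-phase 8th-order Butterworth low-pass at 0.8x the target Nyquist.
    The removed mean is stored under ``provenance['removed_mean']``.
    """
    x = rec.samples
    fs = rec.sample_rate
    prov = dict(rec.provenance)
    if abs(fs - target_rate) > 1e-9:
        ratio = fs / target_rate
        if abs(ratio - round(ratio)) < 1e-9:
            q = int(round(ratio))
            sos = sps.butter(8, 0.8 * (target_rate / 2), fs=fs, output="sos")
            x = sps.sosfiltfilt(sos, x)[::q]
            prov["decimated_by"] = q
        elif allow_resample:
            from fractions import Fraction
            frac = Fraction(target_rate / fs).limit_denominator(1000)
            x = sps.resample_poly(x, frac.numerator, frac.denominator)
            prov["resampled"] = f"{fs}->{target_rate}"
        else:
            raise ValueError(
                f"source rate {fs} Hz is not an integer multiple of "
                f"{target_rate} Hz; pass allow_resample=True to permit it")
    mean = float(np.mean(x))
    prov["removed_mean"] = prov.get("removed_mean", 0.0) + mean
    return SignalRecord(record_id=rec.record_id, sample_rate=target_rate,
                        samples=x - mean, channel=rec.channel, provenance=prov)


# --------------------------------------------------------------------------
# annotations

def read_annotations(path: str | Path) -> AnnotationSet:
    """Read a beat/cycle annotation CSV with columns type,time_s,value.

    ``type`` is ``peak`` (systolic), ``trough`` (diastolic) or ``cycle``
    (respiratory cycle boundary, value ignored).  Peaks and troughs must
    alternate in time and times must be strictly increasing per type.
    """
    df = pd.read_csv(path)
    need = {"type", "time_s"}
    if not need.issubset(df.columns):
        raise AnnotationError(f"{path}: need columns type,time_s[,value]")
    known = {"peak", "trough", "cycle"}
    bad = set(df["type"]) - known
    if bad:
        raise AnnotationError(f"{path}: unknown annotation types {sorted(bad)}")
    beats = df[df["type"].isin(("peak", "trough"))].reset_index()
    times = beats["time_s"].to_numpy(float)
    if np.any(np.diff(times) <= 0):
        i = int(np.argmax(np.diff(times) <= 0)) + 1
        raise AnnotationError(
            f"{path}: non-increasing beat times at data line {beats['index'][i] + 2}")
    kinds = beats["type"].to_numpy()
    for i in range(1, len(kinds)):
        if kinds[i] == kinds[i - 1]:
            raise AnnotationError(
                f"{path}: two consecutive {kinds[i]}s at data line "
                f"{beats['index'][i] + 2}; peaks and troughs must alternate")
    peaks = beats[kinds == "peak"]
    troughs = beats[kinds == "trough"]
    n = min(len(peaks), len(troughs))
    cyc = df[df["type"] == "cycle"]["time_s"].to_numpy(float)
    return AnnotationSet(
        peak_times=peaks["time_s"].to_numpy(float)[:n],
        peak_values=peaks["value"].to_numpy(float)[:n],
        trough_times=troughs["time_s"].to_numpy(float)[:n],
        trough_values=troughs["value"].to_numpy(float)[:n],
        cycle_times=cyc if cyc.size else None,
    )
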
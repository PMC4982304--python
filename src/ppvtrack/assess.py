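"""Agreement assessment between two PPV measurement series.

The assessment protocol takes five PPV measurements per record, spaced
2 minutes apart, each the average over five complete respiratory cycles,
and summarizes paired automatic/manual (or automatic/ground-truth)
measurements with Bland-Altman statistics: mean difference (bias), standard
deviation of the differences, and limits of agreement bias +- 1.96 sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PPVMeasurement", "AgreementReport", "windowed_measurements",
           "bland_altman", "PairingError"]


class PairingError(ValueError):
    """Automatic and manual measurement lists do not pair one-to-one."""


@dataclass
class PPVMeasurement:
    record_id: str
    window_index: int
    window_start_s: float
    value: float          # mean PPV (%) over five respiratory cycles
    source: str = "auto"  # "auto" | "manual" | "truth"
    valid: bool = True


@dataclass
class AgreementReport:
    differences: np.ndarray   # paired auto - manual (%)
    bias: float
    sd: float                 # sample (n-1) standard deviation
    loa_lower: float          # bias - 1.96 sd
    loa_upper: float          # bias + 1.96 sd
    max_abs_diff: float
    per_record: pd.DataFrame  # mean +- sd per record and source

    def to_dict(self) -> dict:
        return {
            "n_pairs": int(self.differences.size),
            "bias_pct": self.bias,
            "sd_pct": self.sd,
            "loa_lower_pct": self.loa_lower,
            "loa_upper_pct": self.loa_upper,
            "max_abs_diff_pct": self.max_abs_diff,
        }


def windowed_measurements(ppv, cycle_bounds, times=None, record_id: str = "",
                          n_windows: int = 5, spacing_s: float = 120.0,
                          cycles_per_window: int = 5, anchor_s: float = 0.0,
                          source: str = "auto") -> list[PPVMeasurement]:
    """PPV measurements on fixed windows of five respiratory cycles.

    Window w starts at ``anchor_s + w * spacing_s``; its value averages PPV
    over the first ``cycles_per_window`` complete respiratory cycles after
    the start.  ``ppv`` is either a continuous per-sample trace (give
    ``times``) — averaged in time over the covered cycles — or a sequence of
    per-cycle values aligned with consecutive ``cycle_bounds`` intervals —
    averaged over the five cycle values.  ``cycle_bounds`` are the cycle
    boundary times in seconds.  A window without enough complete cycles is
    returned flagged invalid (value NaN).
    """
    bounds = np.asarray(cycle_bounds, float)
    out: list[PPVMeasurement] = []
    per_cycle = times is None
    if per_cycle and len(ppv) != len(bounds) - 1:
        raise ValueError("per-cycle PPV needs len(cycle_bounds) - 1 values")
    for w in range(n_windows):
        start = anchor_s + w * spacing_s
        first = int(np.searchsorted(bounds, start))
        if first + cycles_per_window >= bounds.size:
            out.append(PPVMeasurement(record_id, w + 1, start, float("nan"),
                                      source, valid=False))
            continue
        t0, t1 = bounds[first], bounds[first + cycles_per_window]
        if per_cycle:
            value = float(np.mean(ppv[first:first + cycles_per_window]))
        else:
            t = np.asarray(times, float)
            sel = (t >= t0) & (t < t1)
            value = float(np.mean(np.asarray(ppv, float)[sel]))
        out.append(PPVMeasurement(record_id, w + 1, start, value, source))
    return out


def bland_altman(auto: list[PPVMeasurement],
                 manual: list[PPVMeasurement]) -> AgreementReport:
    """Bland-Altman agreement between paired measurement lists.

    Measurements pair by (record, window index); invalid measurements are
    excluded pairwise.  Raises :class:`PairingError` listing offenders if
    the lists do not match one-to-one.
    """
    a = {(m.record_id, m.window_index): m for m in auto}
    b = {(m.record_id, m.window_index): m for m in manual}
    if set(a) != set(b):
        missing = sorted(set(a) ^ set(b))
        raise PairingError(f"unpaired measurements: {missing}")
    keys = sorted(k for k in a if a[k].valid and b[k].valid)
    if not keys:
        raise PairingError("no valid measurement pairs")
    diffs = np.array([a[k].value - b[k].value for k in keys])
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1)) if diffs.size > 1 else 0.0
    rows = []
    for rec in sorted({k[0] for k in keys}):
        vals_a = [a[k].value for k in keys if k[0] == rec]
        vals_b = [b[k].value for k in keys if k[0] == rec]
        rows.append({
            "record": rec,
            "manual_mean": np.mean(vals_b),
            "manual_sd": np.std(vals_b, ddof=1) if len(vals_b) > 1 else 0.0,
            "auto_mean": np.mean(vals_a),
            "auto_sd": np.std(vals_a, ddof=1) if len(vals_a) > 1 else 0.0,
        })
    return AgreementReport(
        differences=diffs, bias=bias, sd=sd,
        loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd,
        max_abs_diff=float(np.max(np.abs(diffs))),
        per_record=pd.DataFrame(rows),
    )
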
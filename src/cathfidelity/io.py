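"""Waveform CSV dialect.

One sample per row, UTF-8, decimal point, header ``time_s,pressure_mmHg``
for pressure or ``time_s,flow_m3s`` for flow. Sampling must be uniform;
timestamps jittered by more than 1% of the nominal interval are rejected.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .waveforms import FlowWaveform, PressureWaveform

__all__ = ["read_waveform_csv", "write_waveform_csv",
           "read_flow_csv", "write_flow_csv"]

_PRESSURE_HEADER = ["time_s", "pressure_mmHg"]
_FLOW_HEADER = ["time_s", "flow_m3s"]


def _read(path, header, cls):
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: not parseable as CSV ({exc})") from exc
    if list(df.columns) != header:
        raise FormatError(
            f"{path}: malformed header {list(df.columns)}, expected {header}")
    if len(df) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    for col in header:
        bad = np.nonzero(~np.isfinite(df[col].to_numpy(dtype=float)))[0]
        if bad.size:
            raise FormatError(
                f"{path}: non-finite value in column {col!r} at data row {bad[0] + 1}")
    t = df[header[0]].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.nonzero(dt <= 0)[0][0]) + 2
        raise FormatError(f"{path}: non-monotone time at data row {row}")
    dt0 = float(np.median(dt))
    if np.any(np.abs(dt - dt0) > 0.01 * dt0):
        raise FormatError(
            f"{path}: non-uniform sampling (time jitter exceeds 1% of the "
            f"nominal interval {dt0:g} s)")
    return cls(df[header[1]].to_numpy(dtype=float), 1.0 / dt0, float(t[0]))


def _write(w, path, header) -> None:
    df = pd.DataFrame({header[0]: w.times, header[1]: w.samples})
    df.to_csv(path, index=False, float_format="%.12g")


def read_waveform_csv(path) -> PressureWaveform:
    """Read a pressure waveform CSV (``time_s,pressure_mmHg``)."""
    return _read(path, _PRESSURE_HEADER, PressureWaveform)


def write_waveform_csv(w: PressureWaveform, path) -> None:
    """Write a pressure waveform CSV; round-trips to 1e-9 mmHg."""
    _write(w, path, _PRESSURE_HEADER)


def read_flow_csv(path) -> FlowWaveform:
    """Read a flow waveform CSV (``time_s,flow_m3s``)."""
    return _read(path, _FLOW_HEADER, FlowWaveform)


def write_flow_csv(w: FlowWaveform, path) -> None:
    """Write a flow waveform CSV."""
    _write(w, path, _FLOW_HEADER)
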
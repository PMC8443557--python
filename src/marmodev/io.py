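"""Tab-separated input/output for every data kind the pipeline exchanges.

All tables are UTF-8 TSV with '.' decimal and no thousands separators;
floats are written with repr-precision so a rerun with the same seed
produces byte-identical files.  Traces are single-column TSVs carrying
their acquisition settings in ``# key=value`` comment lines.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._util import ConfigurationError
from .ephys import EventList, LTDSeries, Trace

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_trace",
    "read_trace",
    "write_events",
    "read_events",
    "write_ltd_series",
    "read_ltd_series",
]


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")
    return path


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")


def write_trace(trace: Trace, path, fmt: str = "%.4f") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# sampling_hz={trace.sampling_hz!r}\n")
        fh.write(f"# polarity={trace.polarity}\n")
        fh.write(f"# condition={trace.condition}\n")
        fh.write(f"# age={trace.age}\n")
        fh.write("current_pa\n")
        np.savetxt(fh, trace.samples, fmt=fmt)
    return path


def read_trace(path) -> Trace:
    meta = {"sampling_hz": None, "polarity": "negative",
            "condition": "mEPSC", "age": "3M"}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    samples = pd.read_csv(path, comment="#").iloc[:, 0].to_numpy(dtype=float)
    if meta["sampling_hz"] is None:
        raise ConfigurationError(f"sampling_hz: missing from trace header {path}")
    return Trace(samples=samples, sampling_hz=float(meta["sampling_hz"]),
                 polarity=meta["polarity"], condition=meta["condition"],
                 age=meta["age"])


def write_events(events: EventList, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# trace_duration_s={events.trace_duration_s!r}\n")
        events.events.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    return path


def read_events(path) -> EventList:
    duration = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "trace_duration_s":
                duration = float(val)
    if duration is None:
        raise ConfigurationError(f"trace_duration_s: missing from {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    return EventList(events=df, trace_duration_s=duration)


def write_ltd_series(series: LTDSeries, path) -> Path:
    df = pd.DataFrame({"time_min": series.times_min,
                       "amplitude": series.amplitudes})
    return write_tsv(df, path, index=False)


def read_ltd_series(path) -> LTDSeries:
    df = pd.read_csv(path, sep="\t")
    return LTDSeries(times_min=df["time_min"].to_numpy(),
                     amplitudes=df["amplitude"].to_numpy())
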
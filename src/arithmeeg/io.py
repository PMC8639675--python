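"""File interchange: BIDS-flavored events TSV and EDF continuous recordings.

Events are written with millisecond timestamp precision and round-trip
losslessly at that precision.  Continuous EEG goes to EDF (16-bit, 1-second
data records); reading uses MNE's EDF reader.  The EDF writer lives here
because the environment's MNE export path requires an extra EDF backend;
the format itself is simple (ASCII header + little-endian int16 samples).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import mne
import numpy as np
import pandas as pd

from .stimuli import ArithmeticProblem, Operation
from .synthdata import Recording, TrialEvent, size_expected_strategy

__all__ = [
    "SchemaError",
    "write_events_tsv",
    "read_events_tsv",
    "write_edf",
    "read_edf",
]


class SchemaError(ValueError):
    """An events table is missing a required column."""


_REQUIRED_COLUMNS = (
    "onset",
    "duration",
    "trial_type",
    "response_time",
    "correct",
    "report",
    "block",
    "operand1",
    "operation",
    "operand2",
)


def write_events_tsv(
    events: Sequence[TrialEvent], path: str | Path, participant: str | None = None
) -> None:
    """Write a trial-events table (tab-separated, millisecond precision)."""
    rows = []
    for ev in events:
        strategy = size_expected_strategy(ev.problem.size)
        rows.append(
            {
                "onset": round(ev.onset, 3),
                "duration": round(ev.rt, 3),
                "trial_type": f"{strategy}_{ev.problem.operation.value}",
                "response_time": round(ev.rt, 3),
                "correct": int(ev.correct),
                "report": ev.report,
                "block": ev.problem.block,
                "operand1": ev.problem.operand1,
                "operation": ev.problem.operation.value,
                "operand2": ev.problem.operand2,
                "participant": participant or ev.participant,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_events_tsv(path: str | Path) -> list[TrialEvent]:
    """Read a trial-events table back into :class:`TrialEvent` objects.

    Raises :class:`SchemaError` naming any missing required column and
    ``ValueError`` if onsets are not strictly increasing.  Unknown columns
    are ignored (preserved in the file, not the objects).
    """
    df = pd.read_csv(path, sep="\t")
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"events table {path} is missing column {col!r}")
    onsets = df["onset"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError(f"events table {path}: onsets must be strictly increasing")
    participant = (
        str(df["participant"].iloc[0]) if "participant" in df.columns else "unknown"
    )
    events = []
    for _, row in df.iterrows():
        problem = ArithmeticProblem(
            int(row["operand1"]),
            int(row["operand2"]),
            Operation(row["operation"]),
            str(row["block"]),
        )
        events.append(
            TrialEvent(
                participant=participant,
                problem=problem,
                onset=float(row["onset"]),
                rt=float(row["response_time"]),
                correct=bool(int(row["correct"])),
                report=str(row["report"]),
            )
        )
    return events


# ---------------------------------------------------------------------------
# EDF


def _pad_ascii(value: str, width: int) -> bytes:
    b = value.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a recording to EDF (16-bit, 1-second data records).

    The sampling rate must be a whole number of samples per second.  A final
    partial data record is zero-padded; callers who need exact round-trips
    should use whole-second recordings.
    """
    sfreq = recording.sfreq
    spr = int(round(sfreq))
    if abs(spr - sfreq) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    data = recording.samples
    n_ch, n_times = data.shape
    n_records = int(np.ceil(n_times / spr))
    if n_records * spr != n_times:
        warnings.warn("recording length padded to a whole number of 1 s records")
        pad = n_records * spr - n_times
        data = np.pad(data, ((0, 0), (0, pad)))

    # physical range: slightly generous, rounded to what the ASCII header
    # stores, so the header and the digital scaling agree exactly
    phys_max = np.array(
        [float(f"{v:.5g}") for v in np.maximum(np.abs(data).max(axis=1) * 1.001, 1e-6)]
    )
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)

    header = b"".join(
        [
            _pad_ascii("0", 8),
            _pad_ascii("X X X X", 80),
            _pad_ascii("Startdate 01-JAN-2000 X X X", 80),
            _pad_ascii("01.01.00", 8),
            _pad_ascii("00.00.00", 8),
            _pad_ascii(str(256 * (1 + n_ch)), 8),
            _pad_ascii("", 44),
            _pad_ascii(str(n_records), 8),
            _pad_ascii("1", 8),
            _pad_ascii(str(n_ch), 4),
        ]
    )

    def field(fmt, width):
        return b"".join(_pad_ascii(fmt(i), width) for i in range(n_ch))

    header += field(lambda i: recording.channels[i], 16)
    header += field(lambda i: "AgAgCl electrode", 80)
    header += field(lambda i: "uV", 8)
    def _num(v: float) -> str:
        s = f"{v:.5g}"
        return s if len(s) <= 8 else f"{v:.0f}"

    header += field(lambda i: _num(phys_min[i]), 8)
    header += field(lambda i: _num(phys_max[i]), 8)
    header += field(lambda i: str(dig_min), 8)
    header += field(lambda i: str(dig_max), 8)
    header += field(lambda i: "", 80)
    header += field(lambda i: str(spr), 8)
    header += field(lambda i: "", 32)

    digital = np.clip(
        np.round((data - phys_min[:, None]) * scale[:, None] + dig_min),
        dig_min,
        dig_max,
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            sl = slice(r * spr, (r + 1) * spr)
            fh.write(digital[:, sl].tobytes())


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a :class:`Recording` (microvolts)."""
    raw = mne.io.read_raw_edf(path, preload=True, verbose=False)
    data = raw.get_data() * 1e6  # MNE loads EEG in volts
    return Recording(
        samples=data,
        channels=tuple(raw.ch_names),
        sfreq=float(raw.info["sfreq"]),
    )
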
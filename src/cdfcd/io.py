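"""Readers and writers: EDF signals, delimited hypnograms/matrices, reports.

Hypnograms are two-column delimited text (``epoch_index,stage``) where stage
is one of AWA/REM/S1/S2/S3/S4 or an ignored marker (Movement/Unscored).
Matrices are delimited numeric text with a header row.  EDF files are parsed
with :mod:`mne`; a minimal 16-bit EDF writer is provided so synthetic
recordings can be exercised end to end.
"""

from __future__ import annotations

import struct
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    IGNORED_STAGES,
    STAGE_CODES,
    EpochMatrix,
    LabelVector,
    SignalRecord,
    class_scheme,
)


def read_edf(path: str | Path) -> SignalRecord:
    """Load an EDF recording into a :class:`SignalRecord` (values in uV).

    All channels must share one sampling rate; mixed-rate files raise.
    """
    import mne  # deferred: slow import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data(units="uV")
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: non-finite samples after loading")
    return SignalRecord(
        channels=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        data=data,
        subject_id=Path(path).stem,
    )


def write_edf(record: SignalRecord, path: str | Path) -> None:
    """Write a basic single-data-record EDF file (16-bit, physical unit uV).

    Minimal writer intended for round-tripping synthetic recordings; it emits
    one data record holding the whole signal, which standard readers accept.
    """
    data = record.data
    n_ch, n_samp = data.shape
    duration = n_samp / record.fs
    phys_min = float(np.floor(data.min() - 1))
    phys_max = float(np.ceil(data.max() + 1))
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min) * scale + dig_min).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),  # patient id
            pad("Startdate X X X X", 80),  # recording id
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 + 256 * n_ch), 8),
            pad("", 44),
            pad("1", 8),  # number of data records
            pad(f"{duration:g}", 8),
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        [pad(ch, 16) for ch in record.channels],  # label
        [pad("", 80)] * n_ch,  # transducer
        [pad("uV", 8)] * n_ch,
        [pad(f"{phys_min:g}", 8)] * n_ch,
        [pad(f"{phys_max:g}", 8)] * n_ch,
        [pad(str(dig_min), 8)] * n_ch,
        [pad(str(dig_max), 8)] * n_ch,
        [pad("", 80)] * n_ch,  # prefiltering
        [pad(str(n_samp), 8)] * n_ch,
        [pad("", 32)] * n_ch,  # reserved
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for block in fields:
            fh.write(b"".join(block))
        for c in range(n_ch):
            fh.write(struct.pack(f"<{n_samp}h", *digital[c]))


def read_hypnogram(path: str | Path) -> tuple[LabelVector, np.ndarray]:
    """Read a delimited hypnogram; returns labels and removed-epoch indices.

    Epochs marked Movement/Unscored are dropped (their original indices are
    returned so the caller can drop the matching signal epochs); unknown
    stage strings raise naming the offending record.
    """
    df = pd.read_csv(path, header=None, names=["epoch", "stage"], comment="#")
    codes, removed = [], []
    for _, row in df.iterrows():
        stage = str(row["stage"]).strip().upper()
        if stage in IGNORED_STAGES:
            removed.append(int(row["epoch"]))
        elif stage in STAGE_CODES:
            codes.append(STAGE_CODES[stage])
        else:
            raise ValueError(f"{path}: unknown stage {row['stage']!r} at epoch {row['epoch']}")
    return LabelVector(np.array(codes, dtype=int), class_scheme(6)), np.array(removed, dtype=int)


def write_hypnogram(labels: LabelVector, path: str | Path) -> None:
    if labels.scheme.n_classes != 6:
        raise ValueError("hypnograms are written in six-stage codes")
    names = ("AWA", "REM", "S1", "S2", "S3", "S4")
    with open(path, "w") as fh:
        for i, code in enumerate(labels.y):
            fh.write(f"{i},{names[code]}\n")


def read_matrix(path: str | Path) -> EpochMatrix:
    """Read a delimited numeric matrix with header into an EpochMatrix."""
    df = pd.read_csv(path)
    X = df.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError(f"{path}: non-finite values in matrix")
    return EpochMatrix(X)


def write_matrix(epochs: EpochMatrix, path: str | Path) -> None:
    cols = [f"f{j}" for j in range(epochs.n_features)]
    pd.DataFrame(epochs.X, columns=cols).to_csv(path, index=False)


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a report as structured key/value text with simple tables."""
    with open(path, "w") as fh:
        for key, value in report.items():
            if isinstance(value, (np.ndarray, list)) and np.ndim(value) == 2:
                fh.write(f"[{key}]\n")
                for row in np.asarray(value):
                    fh.write("  " + "\t".join(f"{v:g}" for v in row) + "\n")
            elif isinstance(value, dict):
                fh.write(f"[{key}]\n")
                for k, v in value.items():
                    fh.write(f"  {k} = {v}\n")
            else:
                fh.write(f"{key} = {value}\n")
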
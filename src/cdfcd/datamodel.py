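"""Core domain types for EEG sleep staging.

The pipeline operates on 30 s epochs of multichannel EEG, each carrying one
Rechtschaffen & Kales stage label (AWA, REM, S1, S2, S3, S4).  Coarser
schemes (2–5 classes) are obtained by merging stages: 5-class merges the two
deep-sleep stages S3+S4, 4-class additionally merges the light stages S1+S2,
3-class collapses all NREM stages, and 2-class separates wake from sleep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical six-stage code order: AWA=0, REM=1, S1=2, S2=3, S3=4, S4=5
STAGE_NAMES = ("AWA", "REM", "S1", "S2", "S3", "S4")
STAGE_CODES = {name: i for i, name in enumerate(STAGE_NAMES)}

#: hypnogram entries that are discarded before any analysis
IGNORED_STAGES = frozenset({"MOVEMENT", "MOVEMENT TIME", "MT", "UNSCORED", "?"})


@dataclass
class SignalRecord:
    """A multichannel recording: ``data`` is channels x samples."""

    channels: list[str]
    fs: float
    data: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} signal rows"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("signal contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochMatrix:
    """n_epochs x n_features matrix with per-row provenance.

    When built from a raw signal, each row is the concatenation of all
    channels over one epoch window, so
    ``n_features = epoch_len_s * fs * n_channels``.
    """

    X: np.ndarray
    epoch_len_s: float | None = None
    source_ids: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.source_ids is None:
            self.source_ids = [("", i) for i in range(self.X.shape[0])]
        if len(self.source_ids) != self.X.shape[0]:
            raise ValueError("source_ids length must match row count")

    @property
    def n_epochs(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def take(self, idx: np.ndarray) -> "EpochMatrix":
        """Row subset preserving provenance."""
        idx = np.asarray(idx)
        return EpochMatrix(
            self.X[idx], self.epoch_len_s, [self.source_ids[i] for i in idx]
        )


@dataclass(frozen=True)
class ClassScheme:
    """Mapping from six-stage codes onto a merged scheme.

    ``merge_map[code]`` gives the merged class of six-stage ``code``; it is
    total on {0..5} and surjective onto {0..n_classes-1}.
    """

    n_classes: int
    merge_map: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.merge_map) != 6:
            raise ValueError("merge_map must cover all six stages")
        if set(self.merge_map) != set(range(self.n_classes)):
            raise ValueError("merge_map must be surjective onto merged codes")


def class_scheme(n_classes: int) -> ClassScheme:
    """Standard merged schemes.

    ========  =========================================
    classes   grouping (six-stage order AWA REM S1..S4)
    ========  =========================================
    6         identity
    5         S3+S4 merged
    4         S1+S2 and S3+S4 merged
    3         AWA | REM | NREM (S1..S4)
    2         AWA | sleep (everything else)
    ========  =========================================
    """
    maps = {
        6: (0, 1, 2, 3, 4, 5),
        5: (0, 1, 2, 3, 4, 4),
        4: (0, 1, 2, 2, 3, 3),
        3: (0, 1, 2, 2, 2, 2),
        2: (0, 1, 1, 1, 1, 1),
    }
    if n_classes not in maps:
        raise ValueError(f"unsupported class scheme: {n_classes}")
    return ClassScheme(n_classes, maps[n_classes])


@dataclass
class LabelVector:
    """Per-epoch integer stage codes under a given scheme."""

    y: np.ndarray
    scheme: ClassScheme = field(default_factory=lambda: class_scheme(6))

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        bad = ~np.isin(self.y, np.arange(self.scheme.n_classes))
        if bad.any():
            raise ValueError(f"invalid stage codes under scheme: {np.unique(self.y[bad])}")

    def __len__(self) -> int:
        return len(self.y)

    def counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=self.scheme.n_classes)


def segment_epochs(record: SignalRecord, epoch_len_s: float = 30.0) -> EpochMatrix:
    """Cut a recording into fixed-length epochs.

    Windows are 0-based, half-open, non-overlapping: epoch ``k`` covers
    samples ``[k*L, (k+1)*L)`` with ``L = epoch_len_s * fs``; a trailing
    partial window is discarded.  Each output row concatenates all channels
    over one window.
    """
    L = epoch_len_s * record.fs
    if L <= 0 or abs(L - round(L)) > 1e-9:
        raise ValueError("epoch_len_s * fs must be a positive integer")
    L = int(round(L))
    n_epochs = record.n_samples // L
    if n_epochs < 1:
        raise ValueError(
            f"signal of {record.n_samples} samples shorter than one epoch ({L} samples)"
        )
    # (channels, n_epochs, L) -> rows concatenate channels
    trimmed = record.data[:, : n_epochs * L].reshape(len(record.channels), n_epochs, L)
    X = np.concatenate([trimmed[c] for c in range(len(record.channels))], axis=1)
    ids = [(record.subject_id, k) for k in range(n_epochs)]
    return EpochMatrix(X, epoch_len_s=epoch_len_s, source_ids=ids)


def merge_classes(labels: LabelVector, target: ClassScheme | int) -> LabelVector:
    """Map six-stage labels onto a merged scheme; class totals are conserved."""
    if isinstance(target, int):
        target = class_scheme(target)
    if labels.scheme.n_classes != 6:
        raise ValueError("merge_classes expects six-stage input labels")
    merge = np.asarray(target.merge_map)
    return LabelVector(merge[labels.y], target)
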
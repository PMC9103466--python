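"""Synthetic inputs with known ground truth for every pipeline stage.

``gen_sleep_epochs`` emulates class-conditional EEG: each stage-like class
has a spectral profile over the conventional EEG bands (delta 0.5-4, theta
4-8, alpha 8-13, sigma 12-16, beta 16-30 Hz) and each epoch is a sum of
band-limited Gaussian noise components weighted by that profile plus
broadband noise.  This captures what sleep stages look like spectrally
(e.g. deep sleep is delta-dominant, wake is alpha/beta-rich) but none of
the transient morphology of real EEG (spindles, K-complexes, artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .datamodel import EpochMatrix, LabelVector, class_scheme
from .ranking import MeasurementGraph
from .sgl import GroupedDesign


@dataclass
class ClassProfile:
    """Relative power per band (delta, theta, alpha, sigma, beta)."""

    band_powers: tuple[float, ...]
    amp_scale: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        bp = np.asarray(self.band_powers, dtype=float)
        if (bp < 0).any():
            raise ValueError("band powers must be nonnegative")
        if abs(bp.sum() - 1.0) > 1e-8:
            raise ValueError("band powers must sum to one")


#: stage-like default profiles (delta, theta, alpha, sigma, beta)
DEFAULT_PROFILES = [
    ClassProfile((0.05, 0.10, 0.45, 0.10, 0.30), 1.0, "AWA-like"),
    ClassProfile((0.10, 0.50, 0.15, 0.10, 0.15), 1.0, "REM-like"),
    ClassProfile((0.20, 0.35, 0.20, 0.15, 0.10), 1.0, "S1-like"),
    ClassProfile((0.35, 0.20, 0.10, 0.30, 0.05), 1.2, "S2-like"),
    ClassProfile((0.60, 0.20, 0.08, 0.07, 0.05), 1.5, "S3-like"),
    ClassProfile((0.80, 0.10, 0.04, 0.03, 0.03), 1.8, "S4-like"),
]

_BAND_EDGES = [(0.5, 4.0), (4.0, 8.0), (8.0, 13.0), (12.0, 16.0), (16.0, 30.0)]


def _band_noise(n_samp: int, fs: float, lo: float, hi: float, rng) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to [lo, hi] Hz (FFT mask)."""
    white = rng.standard_normal(n_samp)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(spec, n=n_samp)
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_sleep_epochs(
    n_per_class: list[int],
    profiles: list[ClassProfile] | None = None,
    fs: float = 100.0,
    epoch_len_s: float = 30.0,
    n_channels: int = 2,
    broadband_sd: float = 0.2,
    seed: int = 0,
) -> tuple[EpochMatrix, LabelVector]:
    """Class-conditional band-limited EEG epochs with attached labels."""
    profiles = DEFAULT_PROFILES[: len(n_per_class)] if profiles is None else profiles
    if len(n_per_class) != len(profiles):
        raise ValueError("n_per_class and profiles must have matching lengths")
    rng = np.random.default_rng(seed)
    L = int(round(epoch_len_s * fs))
    rows, labels = [], []
    for cls, (count, prof) in enumerate(zip(n_per_class, profiles)):
        weights = np.sqrt(np.asarray(prof.band_powers))
        for _ in range(count):
            chans = []
            for _ in range(n_channels):
                x = sum(
                    w * _band_noise(L, fs, lo, hi, rng)
                    for w, (lo, hi) in zip(weights, _BAND_EDGES)
                )
                x = prof.amp_scale * x + broadband_sd * rng.standard_normal(L)
                chans.append(x)
            rows.append(np.concatenate(chans))
            labels.append(cls)
    X = np.asarray(rows)
    n_classes = len(n_per_class)
    scheme = class_scheme(n_classes) if n_classes in (2, 3, 4, 5, 6) else class_scheme(6)
    y = np.asarray(labels)
    if n_classes not in (2, 3, 4, 5, 6):
        raise ValueError("between 2 and 6 classes supported")
    return (
        EpochMatrix(X, epoch_len_s=epoch_len_s, source_ids=[("synthetic", i) for i in range(len(y))]),
        LabelVector(y, scheme),
    )


def gen_subspace_points(
    k: int, d: int, D: int, n_per: int, noise_sd: float = 0.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Points on k random d-dimensional linear subspaces of R^D plus noise."""
    if d >= D:
        raise ValueError("subspace dimension must be below ambient dimension")
    rng = np.random.default_rng(seed)
    points, labels, bases = [], [], []
    for c in range(k):
        B, _ = np.linalg.qr(rng.standard_normal((D, d)))
        bases.append(B)
        coeff = rng.standard_normal((n_per, d))
        pts = coeff @ B.T + noise_sd * rng.standard_normal((n_per, D))
        points.append(pts)
        labels.extend([c] * n_per)
    return np.vstack(points), np.asarray(labels), bases


def gen_pairwise_comparisons(
    n: int, p: float = 1.0, eta: float = 1.0, M: float = 10.0, seed: int = 0
) -> tuple[MeasurementGraph, np.ndarray]:
    """Noisy pairwise score differences: scores uniform on [0, M]; each pair
    is an edge with probability p; an edge measures ``r_i - r_j`` with
    probability eta, else uniform noise on [-M, M]."""
    if not (0 <= p <= 1 and 0 <= eta <= 1):
        raise ValueError("p and eta must lie in [0, 1]")
    if M <= 0:
        raise ValueError("M must be positive")
    rng = np.random.default_rng(seed)
    r = rng.uniform(0, M, size=n)
    edges, R = [], {}
    for i in range(n):
        for j in range(i + 1, n):
            if p >= 1.0 or rng.random() < p:
                edges.append((i, j))
                if eta >= 1.0 or rng.random() < eta:
                    R[(i, j)] = float(r[i] - r[j])
                else:
                    R[(i, j)] = float(rng.uniform(-M, M))
    return MeasurementGraph(n=n, edges=edges, R=R, M_bound=M, p=p, eta=eta), r


def gen_lowrank_matrix(
    P: int, Q: int, K: int, noise_sd: float = 0.0, missing_frac: float = 0.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Z = U'V + noise with a uniformly random observation mask."""
    rng = np.random.default_rng(seed)
    if K == 0:
        U = np.zeros((0, P))
        V = np.zeros((0, Q))
    else:
        U = rng.standard_normal((K, P))
        V = rng.standard_normal((K, Q))
    Z = U.T @ V + noise_sd * rng.standard_normal((P, Q))
    mask = rng.random((P, Q)) >= missing_frac
    return Z, mask, U, V


def gen_group_sparse_regression(
    N: int,
    group_sizes: list[int],
    active_groups: list[int],
    within_sparsity: float = 1.0,
    snr: float = 5.0,
    seed: int = 0,
) -> tuple[GroupedDesign, np.ndarray]:
    """Gaussian design with group-sparse coefficients scaled to a target SNR."""
    rng = np.random.default_rng(seed)
    q = int(np.sum(group_sizes))
    X = rng.standard_normal((N, q))
    beta = np.zeros(q)
    groups, start = [], 0
    for size in group_sizes:
        groups.append(np.arange(start, start + size))
        start += size
    for g in active_groups:
        idx = groups[g]
        n_active = max(1, int(round(within_sparsity * len(idx))))
        chosen = idx[:n_active]
        beta[chosen] = rng.normal(scale=1.0, size=n_active)
    signal = X @ beta
    sig_var = signal.var()
    noise_sd = np.sqrt(sig_var / snr) if sig_var > 0 and np.isfinite(snr) and snr > 0 else 0.0
    y = signal + noise_sd * rng.standard_normal(N)
    return GroupedDesign(X, y, groups), beta
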
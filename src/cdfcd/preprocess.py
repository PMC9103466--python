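"""Signal preprocessing: ICA cleanup and spectral band-power features."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .datamodel import EpochMatrix

#: conventional EEG bands (Hz): delta, theta, alpha, sigma, beta
EEG_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 30.0),
}


def whiten(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and decorrelate rows-as-observations to unit sample covariance.

    Returns ``(Z, mean, back_projection)`` with ``np.cov(Z.T)`` the identity
    (on the retained non-degenerate directions) and
    ``Z @ back_projection + mean`` recovering the input.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD whitening; drop numerically-zero directions
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > max(1e-12, s[0] * 1e-10) if s.size else slice(0)
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    n = X.shape[0]
    Z = U * np.sqrt(n - 1)
    back = (s[:, None] / np.sqrt(n - 1)) * Vt
    return Z, mean, back


def ica_preprocess(
    epochs: EpochMatrix, n_components: int | None = None, seed: int = 0
) -> EpochMatrix:
    """Reconstruct epochs from retained independent components.

    FastICA (fixed-point, deflation) is run on the centered epoch matrix;
    the data are then back-projected from the ``n_components`` retained
    sources (default: all, a lossless cleanup).  Output shape equals input
    shape.  If the fixed-point iteration does not converge, a warning is
    issued and the whitened-then-backprojected data are returned.
    """
    X = epochs.X
    n, q = X.shape
    k = min(n, q) if n_components is None else int(n_components)
    if k > q:
        raise ValueError("n_components cannot exceed n_features")
    mean = X.mean(axis=0)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica = FastICA(
            n_components=min(k, n, q),
            algorithm="deflation",
            fun="logcosh",
            whiten="unit-variance",
            random_state=seed,
            max_iter=500,
        )
        S = ica.fit_transform(X)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    if not converged:
        warnings.warn("ICA did not converge; returning whitened back-projection")
        Z, mu, back = whiten(X)
        return EpochMatrix(Z @ back + mu, epochs.epoch_len_s, list(epochs.source_ids))
    recon = S @ ica.mixing_.T + ica.mean_
    # keep output centered the same way as the input was handed in
    recon = recon - recon.mean(axis=0) + mean
    return EpochMatrix(recon, epochs.epoch_len_s, list(epochs.source_ids))


def band_power_features(
    epochs: EpochMatrix,
    fs: float,
    n_channels: int = 1,
    bands: dict[str, tuple[float, float]] | None = None,
    relative: bool = True,
    log: bool = True,
) -> EpochMatrix:
    """Per-epoch, per-channel spectral band powers via Welch periodograms.

    Each raw epoch row (channels concatenated) is mapped to
    ``n_channels * len(bands)`` features.  Relative powers (each channel's
    band powers normalized to sum to one) discard overall amplitude, which
    varies per epoch; a log transform stabilizes variance.
    """
    bands = EEG_BANDS if bands is None else bands
    X = epochs.X
    n, q = X.shape
    if q % n_channels:
        raise ValueError("feature count not divisible by channel count")
    L = q // n_channels
    per_ch = X.reshape(n, n_channels, L)
    nperseg = min(L, max(64, int(2 * fs)))
    freqs, psd = sps.welch(per_ch, fs=fs, nperseg=nperseg, axis=-1)
    feats = []
    for lo, hi in bands.values():
        sel = (freqs >= lo) & (freqs < hi)
        feats.append(psd[:, :, sel].sum(axis=-1))
    P = np.stack(feats, axis=-1)  # (n, ch, band)
    if relative:
        P = P / np.maximum(P.sum(axis=-1, keepdims=True), 1e-30)
    if log:
        P = np.log(np.maximum(P, 1e-30))
    return EpochMatrix(P.reshape(n, -1), epochs.epoch_len_s, list(epochs.source_ids))
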
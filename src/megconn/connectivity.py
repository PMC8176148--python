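"""Leakage-corrected amplitude-envelope-correlation (AEC) connectomes.

The per-band pipeline is, in order:

1. zero-phase (two-pass) FIR band-pass of each source epoch;
2. symmetric orthogonalization of all seed time series jointly, which
   removes zero-lag correlations induced by source leakage;
3. Hilbert envelope (modulus of the analytic signal);
4. temporal down-sampling of the envelopes to 1 Hz by block averaging;
5. Pearson correlation between every seed pair within each epoch;
6. averaging of the per-epoch correlation matrices into a "static"
   connectivity estimate.

Orthogonalization before the envelope is essential: the envelope is a
non-linear operation, so correcting afterwards would not remove the
leakage-driven zero-lag dependence.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .bands import Band

__all__ = [
    "fir_bandpass",
    "symmetric_orthogonalize",
    "hilbert_envelope",
    "downsample_envelope",
    "aec",
    "static_aec",
    "band_aec",
    "connectivity_tensor",
]


class OrthogonalizationError(ValueError):
    pass


def _fir_order(fs: float, band: Band) -> int:
    """FIR order for one band's zero-phase band-pass.

    Two floors: >= 3 cycles of the band's lowest frequency in the
    impulse response, and a Hamming-window transition width no wider
    than half the band (otherwise narrow bands such as alpha never
    reach unity gain in their passband).
    """
    cycles = 3 * fs / band.f_lo
    transition = 3.3 * fs / ((band.f_hi - band.f_lo) / 2)
    order = int(round(max(cycles, transition) / 2) * 2)
    return max(order, 66)


def fir_bandpass(x: np.ndarray, fs: float, band: Band, order: int | None = None) -> np.ndarray:
    """Zero-phase band-pass via two passes of a windowed-sinc FIR filter.

    ``x`` may be (..., n_samples); filtering is along the last axis.
    The two-pass application squares the magnitude response and cancels
    the phase, leaving envelopes undistorted.
    """
    x = np.asarray(x, dtype=float)
    nyq = fs / 2
    if band.f_hi >= nyq:
        raise ValueError(f"band {band.name} upper edge {band.f_hi} Hz >= Nyquist {nyq} Hz")
    order = _fir_order(fs, band) if order is None else order
    numtaps = order + 1  # odd -> type I linear phase, exact zero phase per pass
    b = signal.firwin(numtaps, [band.f_lo, band.f_hi], pass_zero=False, fs=fs)

    n = x.shape[-1]
    pad = min(numtaps, n - 1)
    # odd reflection at both ends, as in filtfilt, to limit edge transients
    left = 2 * x[..., :1] - x[..., pad:0:-1]
    right = 2 * x[..., -1:] - x[..., -2 : -pad - 2 : -1]
    ext = np.concatenate([left, x, right], axis=-1)
    for _ in range(2):  # symmetric kernel: 'same' convolution is zero-phase
        ext = signal.oaconvolve(ext, b[(None,) * (x.ndim - 1) + (slice(None),)], mode="same", axes=-1)
    return ext[..., pad : pad + n]


def symmetric_orthogonalize(
    x: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> np.ndarray:
    """Closest set of mutually orthogonal rows to ``x`` (seeds x samples).

    Solves min ||X - diag(d) W||_F over diagonal scalings d and
    orthonormal-row matrices W by alternating a Procrustes step (polar
    factor of diag(d) X, via SVD) with a row-wise least-squares rescale.
    The objective is non-increasing at every iteration; convergence is
    declared when its relative change falls below ``tol``.

    The output rows are exactly mutually orthogonal (they are scaled
    rows of an orthonormal basis), which is what removes zero-lag
    leakage correlations between reconstructed sources.
    """
    X = np.asarray(x, dtype=float)
    n_rows, n_samples = X.shape
    if n_samples <= n_rows:
        raise ValueError("need more samples than seeds for orthogonalization")
    row_norms = np.linalg.norm(X, axis=1)
    if np.any(row_norms == 0):
        raise OrthogonalizationError("zero row: cannot orthogonalize degenerate input")

    d = row_norms.copy()
    prev_obj = np.inf
    W = None
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(d[:, None] * X, full_matrices=False)
        if s[-1] < 1e-12 * s[0]:
            # rank-deficient direction: polar factor still defined via SVD
            # basis; duplicated rows are split into orthogonal components.
            pass
        W = U @ Vt  # orthonormal rows, closest in Frobenius sense
        d = np.einsum("ij,ij->i", X, W)
        obj = np.linalg.norm(X - d[:, None] * W) ** 2
        if prev_obj - obj <= tol * max(prev_obj, 1e-300):
            break
        prev_obj = obj
    else:
        warnings.warn("symmetric orthogonalization did not converge", RuntimeWarning)
    return d[:, None] * W


def hilbert_envelope(x: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude: modulus of the analytic signal (last axis)."""
    return np.abs(signal.hilbert(np.asarray(x, dtype=float), axis=-1))


def downsample_envelope(env: np.ndarray, fs: float, target_rate: float = 1.0) -> np.ndarray:
    """Block-average the envelope to ``target_rate`` (default 1 Hz).

    Averaging over non-overlapping windows acts as an anti-alias filter;
    a 10 s epoch at any integer sampling rate yields 10 samples.
    """
    window = fs / target_rate
    if abs(window - round(window)) > 1e-9:
        raise ValueError("sampling rate must be an integer multiple of the target rate")
    window = int(round(window))
    n = env.shape[-1]
    if n % window != 0:
        raise ValueError(
            f"epoch length {n} is not an integer number of {window}-sample windows"
        )
    new_shape = env.shape[:-1] + (n // window, window)
    return env.reshape(new_shape).mean(axis=-1)


def aec(envelopes: np.ndarray) -> np.ndarray:
    """Pearson correlation between seed envelopes within one epoch.

    ``envelopes`` is (n_seeds, n_samples_downsampled).  Returns a
    symmetric matrix with the diagonal set to 0 by convention.  Pairs
    involving a constant envelope are undefined and set to NaN.
    """
    env = np.asarray(envelopes, dtype=float)
    if env.shape[-1] < 3:
        raise ValueError("need at least 3 envelope samples per epoch")
    sd = env.std(axis=-1)
    constant = sd <= 1e-10 * (np.abs(env).max(axis=-1) + 1e-30)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(env)
    r = np.asarray(r, dtype=float)
    if constant.any():
        r[constant, :] = np.nan
        r[:, constant] = np.nan
    r = np.clip(r, -1.0, 1.0)
    r = 0.5 * (r + r.T)
    np.fill_diagonal(r, 0.0)
    return r


def static_aec(per_epoch: np.ndarray) -> np.ndarray:
    """Element-wise mean of per-epoch AEC matrices (epochs, seeds, seeds)."""
    per_epoch = np.asarray(per_epoch, dtype=float)
    if per_epoch.ndim != 3 or per_epoch.shape[0] < 1:
        raise ValueError("expected a non-empty stack of square matrices")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(per_epoch, axis=0)


def band_aec(
    source_epochs: np.ndarray,
    fs: float,
    band: Band,
    orthogonalize: bool = True,
    envelope_rate: float = 1.0,
    return_epochs: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Full AEC pipeline for one band.

    Parameters
    ----------
    source_epochs
        (n_epochs, n_seeds, n_samples) virtual-sensor data.
    orthogonalize
        Apply symmetric orthogonalization per epoch before the envelope
        (the leakage correction).  Disable only for diagnostics.

    Returns
    -------
    The static (epoch-averaged) seed-by-seed AEC matrix; with
    ``return_epochs=True`` also the per-epoch stack.
    """
    source_epochs = np.asarray(source_epochs, dtype=float)
    filtered = fir_bandpass(source_epochs, fs, band)
    mats = []
    for ep in filtered:
        if orthogonalize:
            ep = symmetric_orthogonalize(ep)
        env = hilbert_envelope(ep)
        env = downsample_envelope(env, fs, envelope_rate)
        mats.append(aec(env))
    per_epoch = np.stack(mats)
    static = static_aec(per_epoch)
    if return_epochs:
        return static, per_epoch
    return static


def connectivity_tensor(
    source_epochs: np.ndarray,
    fs: float,
    bands: tuple[Band, ...],
    orthogonalize: bool = True,
) -> np.ndarray:
    """Static AEC for several bands, shape (n_bands, n_seeds, n_seeds)."""
    return np.stack(
        [band_aec(source_epochs, fs, b, orthogonalize=orthogonalize) for b in bands]
    )
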
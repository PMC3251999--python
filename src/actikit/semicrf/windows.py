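"""Sliding-window feature extraction for wearable sensor signals.

Raw accelerometer/gyroscope channels are summarized per window with the
mean, standard deviation and mean-crossing rate of each axis, plus the
window mid-time.  Defaults follow common long-term activity-recognition
practice: 512-sample windows with 50% overlap over a signal whose
effective rate comes from averaging 0.4-s blocks of a 100 Hz stream
(2.5 Hz, so one window spans about 3.41 minutes).
"""

from __future__ import annotations

import numpy as np

from ..errors import ContractError


def mean_crossing_rate(window: np.ndarray) -> float:
    """Fraction of sample-to-sample sign changes of ``window - mean(window)``.

    A constant window has rate 0; a strictly alternating window of
    length ``n`` has ``(n-1)/n``.
    """
    window = np.asarray(window, dtype=float)
    centered = window - window.mean()
    s = np.sign(centered)
    crossings = int(np.sum(s[:-1] * s[1:] < 0))
    return crossings / window.shape[0]


def extract_window_features(
    signal: np.ndarray,
    window: int = 512,
    overlap: float = 0.5,
    times: np.ndarray | None = None,
):
    """Per-window (mean, std, mean-crossing rate) for each axis.

    Parameters
    ----------
    signal : array, shape (T,) or (T, n_axes)
        Multi-axis time series.
    window : int
        Window length in samples.
    overlap : float in [0, 1)
        Fractional overlap; windows advance by ``window * (1 - overlap)``.
    times : array, shape (T,), optional
        Per-sample time stamps; defaults to sample indices.

    Returns
    -------
    features : array, shape (n_windows, 3 * n_axes)
        Columns ordered ``mean_0, std_0, mcr_0, mean_1, ...``.
    mid_times : array, shape (n_windows,)
        Time stamp at each window's midpoint.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim == 1:
        signal = signal[:, None]
    T, n_axes = signal.shape
    if T < window:
        raise ContractError(f"signal length {T} shorter than window {window}")
    if not 0.0 <= overlap < 1.0:
        raise ContractError("overlap must be in [0, 1)")
    step = max(1, int(round(window * (1.0 - overlap))))
    if times is None:
        times = np.arange(T, dtype=float)
    else:
        times = np.asarray(times, dtype=float)
    starts = range(0, T - window + 1, step)
    feats = []
    mids = []
    for s0 in starts:
        block = signal[s0 : s0 + window]
        row = []
        for ax in range(n_axes):
            col = block[:, ax]
            row.extend([col.mean(), col.std(), mean_crossing_rate(col)])
        feats.append(row)
        mids.append(0.5 * (times[s0] + times[s0 + window - 1]))
    return np.asarray(feats), np.asarray(mids)


def effective_sampling_rate(raw_hz: float, mean_window_s: float) -> float:
    """Rate of the stream after averaging ``mean_window_s``-second blocks.

    E.g. a 100 Hz signal averaged over 0.4-s blocks yields 2.5 Hz.
    """
    if raw_hz <= 0 or mean_window_s <= 0:
        raise ContractError("rates and window lengths must be positive")
    return 1.0 / mean_window_s


def window_duration_minutes(n_samples: int, rate_hz: float) -> float:
    """Span of an ``n_samples`` window at ``rate_hz``, in minutes."""
    if n_samples < 1 or rate_hz <= 0:
        raise ContractError("need n_samples >= 1 and rate_hz > 0")
    return n_samples / rate_hz / 60.0
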
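"""Band-limited amplitude and long-range temporal correlation (DFA).

A channel signal is band-passed with a zero-phase Butterworth filter,
its Hilbert envelope taken, and two summaries computed: the mean
envelope amplitude, and the detrended-fluctuation-analysis exponent of
the envelope over log-spaced window sizes (default 5-50 s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "BandDefinition",
    "EnvelopeStats",
    "ALPHA",
    "BETA",
    "GAMMA",
    "DEFAULT_BANDS",
    "band_envelope",
    "mean_amplitude",
    "dfa_exponent",
    "recording_band_stats",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"invalid band {self.name}: {self.low_hz}-{self.high_hz}")


ALPHA = BandDefinition("alpha", 8.0, 12.0)
BETA = BandDefinition("beta", 20.0, 25.0)
GAMMA = BandDefinition("gamma", 35.0, 40.0)
DEFAULT_BANDS = (ALPHA, BETA, GAMMA)


@dataclass(frozen=True)
class EnvelopeStats:
    channel: str
    band: str
    mean_amplitude_uv: float
    dfa_exponent: float
    fit_r2: float
    window_sizes_s: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.mean_amplitude_uv < 0:
            raise ValueError("mean amplitude cannot be negative")


def band_envelope(
    x: np.ndarray, band: BandDefinition, sample_rate: float, order: int = 4
) -> np.ndarray:
    """Hilbert envelope of the band-passed signal (single channel)."""
    nyq = sample_rate / 2.0
    if band.high_hz >= nyq:
        raise ValueError(f"band {band.name} exceeds Nyquist ({nyq} Hz)")
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("band_envelope expects a single-channel series")
    sos = signal.butter(
        order, [band.low_hz, band.high_hz], btype="bandpass", fs=sample_rate,
        output="sos",
    )
    filtered = signal.sosfiltfilt(sos, x)
    return np.abs(signal.hilbert(filtered))


def mean_amplitude(envelope: np.ndarray) -> float:
    envelope = np.asarray(envelope, dtype=float)
    if envelope.size == 0:
        raise ValueError("empty envelope")
    return float(envelope.mean())


def _log_spaced_sizes(
    window_range_s: tuple[float, float], n_windows: int, sample_rate: float
) -> np.ndarray:
    lo, hi = window_range_s
    sizes = np.unique(
        np.round(np.logspace(np.log10(lo), np.log10(hi), n_windows) * sample_rate)
        .astype(int)
    )
    return sizes[sizes >= 4]


def dfa_exponent(
    envelope: np.ndarray,
    sample_rate: float,
    window_range_s: tuple[float, float] = (5.0, 50.0),
    n_windows: int = 10,
    overlap: float = 0.5,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """DFA scaling exponent of a series over log-spaced window sizes.

    The mean-centred series is integrated; each window of the profile is
    linearly detrended and its RMS fluctuation computed; fluctuations are
    averaged per window size (50% overlapping placement).  Returns
    ``(exponent, fit_r2, sizes_s, fluctuations)`` where the exponent is
    the OLS slope of log10 fluctuation against log10 window size.
    """
    x = np.asarray(envelope, dtype=float)
    sizes = _log_spaced_sizes(window_range_s, n_windows, sample_rate)
    min_len = 2 * int(sizes.max()) if sizes.size else 0
    if sizes.size < 2 or len(x) < min_len:
        raise ValueError(
            f"series too short for DFA: need >= {min_len} samples "
            f"(2 x largest window of {window_range_s[1]} s at {sample_rate} Hz), "
            f"got {len(x)}"
        )
    profile = np.cumsum(x - x.mean())
    flucts = np.empty(len(sizes))
    for k, w in enumerate(sizes):
        step = max(1, int(round(w * (1.0 - overlap))))
        windows = np.lib.stride_tricks.sliding_window_view(profile, w)[::step]
        # orthonormal basis of [1, t]: residual = x - Q Q^T x
        t = np.arange(w, dtype=float)
        q1 = np.full(w, w**-0.5)
        t0 = t - t.mean()
        q2 = t0 / np.linalg.norm(t0)
        coeff1 = windows @ q1
        coeff2 = windows @ q2
        resid_sq = (
            np.einsum("ij,ij->i", windows, windows)
            - coeff1**2
            - coeff2**2
        )
        flucts[k] = np.sqrt(np.mean(resid_sq / w))
    sizes_s = sizes / sample_rate
    fit = stats.linregress(np.log10(sizes_s), np.log10(flucts))
    return float(fit.slope), float(fit.rvalue**2), sizes_s, flucts


def recording_band_stats(
    data: np.ndarray,
    channel_names: tuple[str, ...],
    sample_rate: float,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    window_range_s: tuple[float, float] = (5.0, 50.0),
    n_windows: int = 10,
) -> pd.DataFrame:
    """Per channel x band envelope summaries for a continuous recording."""
    rows = []
    for band in bands:
        for i, ch in enumerate(channel_names):
            env = band_envelope(data[i], band, sample_rate)
            exponent, r2, sizes_s, _ = dfa_exponent(
                env, sample_rate, window_range_s, n_windows
            )
            rows.append(
                {
                    "channel": ch,
                    "band": band.name,
                    "amplitude_uv": mean_amplitude(env),
                    "dfa_exponent": exponent,
                    "fit_r2": r2,
                }
            )
    return pd.DataFrame(rows)
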
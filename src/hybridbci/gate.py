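"""Stage-1 SSVEP gate features: Welch PSD, band areas, and the band ratio.

A 7 Hz flicker response concentrates spectral power in a narrow band
around the stimulation frequency.  The gate feature is, per channel,
the trapezoidal area of the Welch power spectral density over 6-8 Hz
divided by the area over 4-10 Hz: close to the flat-spectrum baseline
of 1/3 when no stimulus is present and approaching 1 when power piles
up at 7 Hz.  The ratio is invariant to global amplitude scaling, which
is what lets a single threshold-free classifier separate LED-on from
LED-off segments across subjects.

Welch defaults follow the analysis protocol: 640-sample Hamming windows
with 639-sample overlap (129 sub-segments per 768-sample window) and no
zero padding, giving a 0.4 Hz grid on which all four band edges
(4, 6, 8, 10 Hz) are exact grid points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

DEFAULT_WINDOW_LEN = 640
DEFAULT_OVERLAP = 639
WIDE_BAND = (4.0, 10.0)
NARROW_BAND = (6.0, 8.0)


@dataclass
class SpectralEstimate:
    """One-sided Welch PSD per channel (density scaling, uV^2/Hz)."""

    freqs: np.ndarray      # ascending grid, spacing fs / window_len
    psd: np.ndarray        # (n_freqs, n_channels)
    window_len: int
    overlap: int


@dataclass
class GateFeature:
    """Per-channel narrow/wide band-area ratio for one segment."""

    ratios: np.ndarray     # (n_channels,), in (0, 1] for positive spectra
    segment_ref: tuple | None = None


def welch_segment_count(n: int, window_len: int, overlap: int) -> int:
    """Number of averaged sub-segments K for given length/window/overlap."""
    return (n - window_len) // (window_len - overlap) + 1


def welch_psd(x: np.ndarray, fs: float, window_len: int = DEFAULT_WINDOW_LEN,
              overlap: int = DEFAULT_OVERLAP) -> SpectralEstimate:
    """Hamming-windowed, overlap-averaged periodogram along the time axis.

    Density normalization: the integral of the PSD over frequency
    approximates the signal variance.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if window_len > n:
        raise ValueError(f"window_len {window_len} exceeds segment length {n}")
    if not 0 <= overlap < window_len:
        raise ValueError("overlap must satisfy 0 <= overlap < window_len")
    freqs, psd = signal.welch(
        x, fs=fs, window="hamming", nperseg=window_len, noverlap=overlap,
        nfft=window_len, detrend="constant", scaling="density", axis=0,
    )
    return SpectralEstimate(freqs=freqs, psd=np.atleast_2d(psd.T).T,
                            window_len=window_len, overlap=overlap)


def band_area(est: SpectralEstimate, band: tuple[float, float]) -> np.ndarray:
    """Composite trapezoid rule over grid points in [low, high], per channel."""
    low, high = band
    if low >= high:
        raise ValueError("band must satisfy low < high")
    if low < est.freqs[0] - 1e-9 or high > est.freqs[-1] + 1e-9:
        raise ValueError(
            f"band {band} outside the frequency grid "
            f"[{est.freqs[0]:g}, {est.freqs[-1]:g}]"
        )
    mask = (est.freqs >= low - 1e-9) & (est.freqs <= high + 1e-9)
    return np.trapezoid(est.psd[mask], est.freqs[mask], axis=0)


def gate_feature(est: SpectralEstimate, wide: tuple[float, float] = WIDE_BAND,
                 narrow: tuple[float, float] = NARROW_BAND) -> GateFeature:
    """Per-channel ratio (narrow band area) / (wide band area)."""
    l1 = band_area(est, wide)
    l2 = band_area(est, narrow)
    if np.any(l1 <= 0):
        raise ValueError("degenerate spectrum: zero wide-band area")
    return GateFeature(ratios=l2 / l1)


def gate_ratios(segment: np.ndarray, fs: float,
                window_len: int = DEFAULT_WINDOW_LEN,
                overlap: int = DEFAULT_OVERLAP) -> np.ndarray:
    """Convenience: PSD + band ratio for one filtered segment."""
    return gate_feature(welch_psd(segment, fs, window_len, overlap)).ratios
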
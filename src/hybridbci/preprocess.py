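"""Trial trimming, sliding-window segmentation, and zero-phase filtering.

The analysis chain removes the 3 s audio-warning periods at both ends
of each 16 s trial (leaving 2560 samples of task data), cuts the
remaining 10 s into 3 s windows, and band-pass filters each window with
a forward-backward (zero-phase) Butterworth design: order 5, 1-15 Hz
for the SSVEP gate stage; order 4, 0.5-32 Hz for the trajectory stage.

The protocol text fixes the number of windows per trial at five; with a
768-sample window over 2560 samples that forces a 448-sample stride
(1.75 s step), which is the default here.  The stride is configurable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import Recording


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass applied forward-backward (zero net phase)."""

    order: int
    band: tuple[float, float]

    def validate(self, fs: float) -> None:
        low, high = self.band
        if not (0 < low < high < fs / 2):
            raise ValueError(
                f"band {self.band} must satisfy 0 < low < high < fs/2 ({fs / 2:g})"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    def sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        return signal.butter(self.order, self.band, btype="bandpass", fs=fs,
                             output="sos")


STAGE1_FILTER = FilterSpec(order=5, band=(1.0, 15.0))
STAGE2_FILTER = FilterSpec(order=4, band=(0.5, 32.0))

#: Defaults of the segmentation grid: 3 s windows, 448-sample stride.
DEFAULT_WINDOW_SECONDS = 3.0
DEFAULT_STRIDE_SAMPLES = 448


@dataclass
class SegmentSet:
    """The analysis windows of one trimmed trial, with provenance."""

    segments: np.ndarray            # (n_windows, window_len, n_channels)
    trial_ref: tuple                # (subject_id, session, class_label, repetition)
    window_starts: np.ndarray       # 0-based start sample of each window

    def __len__(self) -> int:
        return self.segments.shape[0]


def trim_warnings(rec: Recording, warning_seconds: float = 3.0) -> Recording:
    """Drop warning_seconds from both ends; returns a trimmed Recording."""
    cut = int(round(warning_seconds * rec.fs))
    if rec.n_samples <= 2 * cut:
        raise ValueError(
            f"trial of {rec.duration:g} s cannot be trimmed by "
            f"{warning_seconds:g} s at each end"
        )
    samples = rec.samples[cut:rec.n_samples - cut]
    return dataclasses.replace(rec, samples=samples, trimmed=warning_seconds > 0
                               or rec.trimmed)


def segment_trial(rec: Recording, window_seconds: float = DEFAULT_WINDOW_SECONDS,
                  stride_samples: int = DEFAULT_STRIDE_SAMPLES) -> SegmentSet:
    """Cut half-open windows [start, start + window_len) at multiples of the stride.

    With the defaults on a trimmed trial (2560 samples) this yields
    exactly five 768-sample windows, the last ending at sample 2560.
    """
    window_len = int(round(window_seconds * rec.fs))
    n = rec.n_samples
    if window_len > n:
        raise ValueError(f"window of {window_len} samples exceeds trial of {n}")
    if stride_samples < 1:
        raise ValueError("stride_samples must be >= 1")
    starts = np.arange(0, n - window_len + 1, stride_samples)
    segments = np.stack([rec.samples[s:s + window_len] for s in starts])
    return SegmentSet(segments=segments, trial_ref=rec.key,
                      window_starts=starts)


def bandpass_zero_phase(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Forward-backward Butterworth filtering along the time axis.

    Edge transients are suppressed by odd-reflection padding of up to
    3 s (capped at signal length - 1).  The slowest pole of the 0.5-1 Hz
    high-pass edges rings for hundreds of samples, so the short default
    padding of generic filtfilt routines leaves visible transients; a
    multi-second pad keeps the passband flat to well under 1% away from
    the edges.
    """
    x = np.asarray(x, dtype=float)
    sos = spec.sos(fs)
    min_len = 3 * (2 * sos.shape[0] + 1)
    n = x.shape[0]
    if n <= min_len:
        raise ValueError(
            f"signal of {n} samples too short for edge padding "
            f"({min_len} samples minimum)"
        )
    padlen = min(n - 1, int(round(3 * fs)))
    return signal.sosfiltfilt(sos, x, axis=0, padlen=padlen)
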
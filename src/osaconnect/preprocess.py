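"""Power-line notch and sleep-band filtering applied before decomposition.

The chain is a 50 Hz IIR notch followed by a 0.5-35 Hz Butterworth band-pass,
both applied forward-backward so the net phase response is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import Recording

__all__ = ["FilterSpec", "notch_filter", "bandpass_filter", "preprocess_recording"]


@dataclass(frozen=True)
class FilterSpec:
    """Design parameters of the preprocessing chain.

    notch_freq : Hz — power-line frequency to remove (50 Hz in Europe).
    notch_q : quality factor of the second-order IIR notch (bandwidth =
        notch_freq / Q).
    band_low, band_high : Hz — pass-band of the Butterworth band-pass;
        0.5-35 Hz keeps the five clinical sleep-EEG bands.
    butter_order : order of the Butterworth prototype (doubled effectively by
        zero-phase application).
    zero_phase : apply each filter forward and backward (no group delay).
    """

    notch_freq: float = 50.0
    notch_q: float = 30.0
    band_low: float = 0.5
    band_high: float = 35.0
    butter_order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not 0 < self.band_low < self.band_high < fs / 2:
            raise ValueError(
                f"need 0 < band_low < band_high < fs/2, got "
                f"({self.band_low}, {self.band_high}) at fs={fs}"
            )
        if not 0 < self.notch_freq < fs / 2:
            raise ValueError(
                f"notch at {self.notch_freq} Hz not below Nyquist ({fs / 2} Hz)"
            )
        if self.butter_order < 1:
            raise ValueError("butter_order must be >= 1")
        if self.notch_q <= 0:
            raise ValueError("notch_q must be positive")


def _apply_ba(b, a, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    order = max(len(b), len(a))
    if len(x) <= 3 * order:
        raise ValueError(
            f"signal of {len(x)} samples too short for a filter of order "
            f"{order} (need > {3 * order} for padded zero-phase application)"
        )
    if zero_phase:
        return sps.filtfilt(b, a, x)
    return sps.lfilter(b, a, x)


def notch_filter(x: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Remove the power-line component with a second-order IIR notch."""
    spec.validate(fs)
    x = np.asarray(x, dtype=float)
    b, a = sps.iirnotch(spec.notch_freq, spec.notch_q, fs=fs)
    return _apply_ba(b, a, x, spec.zero_phase)


def bandpass_filter(x: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Restrict to [band_low, band_high] Hz with a Butterworth band-pass."""
    spec.validate(fs)
    x = np.asarray(x, dtype=float)
    sos = sps.butter(
        spec.butter_order, [spec.band_low, spec.band_high], btype="bandpass", fs=fs,
        output="sos",
    )
    # padlen mirrors filtfilt's default 3 * order rule for the sos cascade
    n_order = 2 * sos.shape[0]
    if len(x) <= 3 * (n_order + 1):
        raise ValueError(
            f"signal of {len(x)} samples too short for zero-phase band-pass"
        )
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def preprocess_recording(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Apply notch then band-pass to every channel; labels and fs unchanged."""
    spec.validate(rec.fs)
    out = np.empty_like(rec.data)
    for i in range(rec.n_channels):
        out[i] = bandpass_filter(notch_filter(rec.data[i], rec.fs, spec), rec.fs, spec)
    return Recording(
        channel_labels=list(rec.channel_labels),
        fs=rec.fs,
        data=out,
        subject_id=rec.subject_id,
        group_label=rec.group_label,
    )


def notch_response(fs: float, spec: FilterSpec, freqs: np.ndarray) -> np.ndarray:
    """Magnitude response of the (possibly zero-phase) notch at ``freqs`` Hz."""
    b, a = sps.iirnotch(spec.notch_freq, spec.notch_q, fs=fs)
    _, h = sps.freqz(b, a, worN=np.asarray(freqs, dtype=float), fs=fs)
    mag = np.abs(h)
    return mag ** 2 if spec.zero_phase else mag


def bandpass_response(fs: float, spec: FilterSpec, freqs: np.ndarray) -> np.ndarray:
    """Magnitude response of the (possibly zero-phase) band-pass at ``freqs``."""
    sos = sps.butter(
        spec.butter_order, [spec.band_low, spec.band_high], btype="bandpass", fs=fs,
        output="sos",
    )
    _, h = sps.sosfreqz(sos, worN=np.asarray(freqs, dtype=float), fs=fs)
    mag = np.abs(h)
    return mag ** 2 if spec.zero_phase else mag
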
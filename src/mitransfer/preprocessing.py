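"""Band-pass filtering and decimation applied before modelling.

The chain is fixed: an 8–30 Hz Butterworth band-pass (isolating the mu and
beta sensorimotor rhythms that carry motor-imagery information) followed by
integer decimation from the acquisition rate down to 100 Hz.  Because the
band-pass already limits the signal well below the post-decimation Nyquist
frequency (30 < 50 Hz), decimation needs no extra anti-alias filter; a
spectral guard re-checks this and refuses to decimate broadband signals
unless forced.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .io import RawRecording, TrialTensor


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass design.

    ``order`` is the per-pass order; with ``zero_phase=True`` the filter is
    applied forward and backward (zero phase lag, squared magnitude
    response), which avoids phase distortion of short imagery epochs.
    """

    low_hz: float = 8.0
    high_hz: float = 30.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"need 0 < low_hz < high_hz, got {self.low_hz}, {self.high_hz}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    def sos(self, fs: float) -> np.ndarray:
        if fs <= 2 * self.high_hz:
            raise ValueError(
                f"sampling rate {fs} Hz too low for a {self.high_hz} Hz band edge"
            )
        return sps.butter(
            self.order, [self.low_hz, self.high_hz], btype="bandpass", fs=fs,
            output="sos",
        )

    def magnitude_response(self, freqs_hz, fs: float) -> np.ndarray:
        """Single-pass |H(f)|; the zero-phase response is its square."""
        _, h = sps.sosfreqz(self.sos(fs), worN=np.atleast_1d(freqs_hz), fs=fs)
        mag = np.abs(h)
        return mag**2 if self.zero_phase else mag


def _filter_array(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    sos = spec.sos(fs)
    t = x.shape[-1]
    if spec.zero_phase:
        # Short even-reflection padding keeps edge transients local in 3 s epochs.
        padlen = min(3 * spec.order, t - 1)
        return sps.sosfiltfilt(sos, x, axis=-1, padtype="even", padlen=padlen)
    return sps.sosfilt(sos, x, axis=-1)


def bandpass(x: RawRecording | TrialTensor, spec: FilterSpec | None = None):
    """Apply the Butterworth band-pass per channel (and per trial).

    Returns an object of the same type with the signal replaced.
    """
    spec = spec or FilterSpec()
    if isinstance(x, RawRecording):
        return replace(x, signal=_filter_array(x.signal, spec, x.fs))
    if isinstance(x, TrialTensor):
        return replace(x, data=_filter_array(x.data, spec, x.fs))
    raise TypeError(f"expected RawRecording or TrialTensor, got {type(x).__name__}")


def _band_limited_fraction(x2d: np.ndarray, fs: float, cutoff_hz: float) -> float:
    """Fraction of total spectral power below ``cutoff_hz`` (Welch average)."""
    nper = min(x2d.shape[-1], 1024)
    freqs, pxx = sps.welch(x2d, fs=fs, nperseg=nper, axis=-1)
    total = pxx.sum()
    if total <= 0:
        return 1.0
    return float(pxx[..., freqs < cutoff_hz].sum() / total)


def downsample(
    x: RawRecording | TrialTensor, target_fs: float, force: bool = False
):
    """Integer decimation to ``target_fs`` (keeps every ``fs/target_fs``-th sample).

    Valid only for signals already band-limited below ``target_fs / 2`` —
    guaranteed when the 8–30 Hz band-pass has run first.  A Welch-spectrum
    guard raises if more than 5% of the power sits above the new Nyquist
    frequency, unless ``force=True``.
    """
    fs = x.fs
    ratio = fs / target_fs
    k = int(round(ratio))
    if target_fs <= 0 or abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(
            f"sampling rate {fs} Hz is not an integer multiple of target {target_fs} Hz"
        )
    arr = x.signal if isinstance(x, RawRecording) else x.data
    if not force and k > 1:
        flat = arr.reshape(-1, arr.shape[-1])
        if _band_limited_fraction(flat, fs, target_fs / 2) < 0.95:
            raise ValueError(
                f"signal has substantial power above {target_fs / 2} Hz; "
                "band-pass filter first or pass force=True"
            )
    t_out = arr.shape[-1] // k
    dec = arr[..., : t_out * k : k]
    if isinstance(x, RawRecording):
        events = [(s // k, code) for s, code in x.event_markers if s // k < t_out]
        return RawRecording(
            signal=dec, fs=target_fs, channel_names=list(x.channel_names),
            event_markers=events,
        )
    return replace(x, data=dec, fs=target_fs)


def preprocess(
    x: RawRecording | TrialTensor,
    spec: FilterSpec | None = None,
    target_fs: float = 100.0,
):
    """The full chain in canonical order: band-pass, then decimate."""
    return downsample(bandpass(x, spec), target_fs)


__all__ = ["FilterSpec", "bandpass", "downsample", "preprocess"]
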
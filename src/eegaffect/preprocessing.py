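"""Signal conditioning: detrend, power-line notch, EOG suppression, band FIR.

The conditioning chain applied to each channel before feature extraction
is detrend -> 50 Hz notch -> wavelet-threshold EOG suppression; the
alpha/beta/gamma bands are then isolated with zero-phase FIR band-pass
filters. Gamma is capped at 45 Hz: the band is open-ended ("> 30 Hz")
physiologically, but the 50 Hz power-line notch and 128 Hz sampling of
typical affective-EEG datasets force an upper edge below the notch.

All filters are applied forward-backward (zero phase) so that features
computed on epoch-aligned windows are not delayed relative to the raw
signal; the magnitude response is squared as a side effect, which only
sharpens the band selectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from .errors import EEGAffectError

__all__ = [
    "BandDefinition",
    "PreprocConfig",
    "DEFAULT_BANDS",
    "detrend",
    "notch_filter",
    "bandpass_fir",
    "suppress_eog",
    "preprocess_channel",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise EEGAffectError(f"invalid band edges ({self.low_hz}, {self.high_hz})")


DEFAULT_BANDS: dict[str, BandDefinition] = {
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 45.0),
}

WAVE_ORDER = ("alpha", "beta", "gamma")


@dataclass(frozen=True)
class PreprocConfig:
    """Parameters of the conditioning chain.

    ``adaptive_ecg`` is a hook for reference-based ECG artifact removal;
    it is not implemented (no ECG reference enters the feature pipeline)
    and enabling it raises.
    """

    notch_hz: float = 50.0
    notch_q: float = 30.0
    fir_order: int = 129
    detrend_mode: str = "linear"
    eog_suppression: bool = True
    eog_threshold_rule: str = "clip"  # clip | soft | none
    wavelet_name: str = "db4"
    decomposition_levels: int = 4
    adaptive_ecg: bool = False

    def __post_init__(self) -> None:
        if self.fir_order < 3 or self.fir_order % 2 == 0:
            raise EEGAffectError("fir_order must be odd and >= 3")
        if self.decomposition_levels < 1:
            raise EEGAffectError("decomposition_levels must be >= 1")
        if self.detrend_mode not in ("constant", "linear"):
            raise EEGAffectError("detrend_mode must be 'constant' or 'linear'")
        if self.adaptive_ecg:
            raise NotImplementedError(
                "adaptive ECG filtering requires an ECG reference channel "
                "and is not implemented"
            )


def detrend(x: np.ndarray, mode: str = "linear") -> np.ndarray:
    """Remove the mean (``constant``) or best-fit line (``linear``)."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise EEGAffectError("detrend expects a 1-D signal of length >= 2")
    if not np.all(np.isfinite(x)):
        raise EEGAffectError("non-finite samples")
    if mode not in ("constant", "linear"):
        raise EEGAffectError(f"unknown detrend mode {mode!r}")
    return sps.detrend(x, type=mode)


def notch_filter(
    x: np.ndarray, fs: float, notch_hz: float = 50.0, notch_q: float = 30.0
) -> np.ndarray:
    """Zero-phase IIR notch removing one narrow line frequency."""
    x = np.asarray(x, dtype=np.float64)
    if notch_hz >= fs / 2:
        raise EEGAffectError(f"notch at {notch_hz} Hz >= Nyquist ({fs / 2} Hz)")
    b, a = sps.iirnotch(notch_hz, notch_q, fs=fs)
    return sps.filtfilt(b, a, x)


def bandpass_fir(
    x: np.ndarray, fs: float, band: BandDefinition, fir_order: int = 129
) -> np.ndarray:
    """Zero-phase windowed-sinc (Hamming) FIR band-pass."""
    x = np.asarray(x, dtype=np.float64)
    if band.high_hz >= fs / 2:
        raise EEGAffectError(
            f"band {band.name} upper edge {band.high_hz} Hz >= Nyquist ({fs / 2} Hz)"
        )
    taps = sps.firwin(
        fir_order, [band.low_hz, band.high_hz], pass_zero=False,
        window="hamming", fs=fs,
    )
    # padlen must stay below the signal length for short epochs
    padlen = min(3 * fir_order, x.size - 1)
    return sps.filtfilt(taps, [1.0], x, padlen=padlen)


def _mad_sigma(c: np.ndarray) -> float:
    return float(np.median(np.abs(c - np.median(c))) / 0.6745)


def _soft(c: np.ndarray, lam: float) -> np.ndarray:
    return np.sign(c) * np.maximum(np.abs(c) - lam, 0.0)


def suppress_eog(
    x: np.ndarray,
    wavelet: str = "db4",
    levels: int = 4,
    threshold: float | None = None,
    rule: str = "clip",
) -> np.ndarray:
    """Wavelet-threshold suppression of ocular (blink-like) artifacts.

    The signal is decomposed to ``levels`` scales with a periodised db4
    DWT and each coefficient array is thresholded at the universal level
    lambda = sigma * sqrt(2 ln N).

    ``rule='clip'`` (default) estimates sigma robustly per scale (median
    absolute deviation / 0.6745, approximation included) and clips
    coefficient magnitudes to lambda. Ocular artifacts are large slow
    excursions whose energy sits in outlier coefficients at the coarse
    scales, so clipping the outliers removes them while leaving ongoing
    oscillations — whose coefficients set the per-scale typical
    magnitude — essentially untouched.

    ``rule='soft'`` is classical denoising shrinkage: sigma from the
    finest detail scale only, soft-thresholding all detail scales. It
    removes broadband measurement noise but biases sustained
    oscillations and leaves large transients mostly intact.

    Pass ``threshold=0`` to disable thresholding entirely, or a positive
    value to override the universal lambda at every scale.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2 ** levels:
        raise EEGAffectError(f"signal too short for {levels} decomposition levels")
    if rule not in ("clip", "soft"):
        raise EEGAffectError(f"unknown threshold rule {rule!r}")
    if threshold is not None and threshold == 0:
        return x.copy()
    coeffs = pywt.wavedec(x, wavelet, level=levels, mode="periodization")
    scale = np.sqrt(2.0 * np.log(x.size))
    out = []
    if rule == "soft":
        lam = threshold if threshold is not None else _mad_sigma(coeffs[-1]) * scale
        out = [coeffs[0]] + [_soft(c, lam) for c in coeffs[1:]]
    else:
        for c in coeffs:
            lam = threshold if threshold is not None else _mad_sigma(c) * scale
            out.append(np.clip(c, -lam, lam))
    rec = pywt.waverec(out, wavelet, mode="periodization")
    return rec[: x.size]


def preprocess_channel(x: np.ndarray, fs: float, config: PreprocConfig) -> np.ndarray:
    """Full conditioning chain for one channel (no band extraction)."""
    y = detrend(x, config.detrend_mode)
    y = notch_filter(y, fs, config.notch_hz, config.notch_q)
    if config.eog_suppression and config.eog_threshold_rule != "none":
        y = suppress_eog(
            y, config.wavelet_name, config.decomposition_levels,
            rule=config.eog_threshold_rule,
        )
    return y
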
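"""Per-channel EEG features and hemispheric-asymmetry transforms.

Eight features are computed per channel and band:

* ``H1`` activity — population variance of the signal;
* ``H2`` mobility — sqrt(activity(x') / activity(x)) with the first
  difference as derivative; a normalised mean frequency;
* ``H3`` complexity — mobility(x') / mobility(x); 1 for a pure sine,
  larger for broadband signals;
* ``SE`` spectral entropy — Shannon entropy (bits) of the normalised
  power spectrum (|DFT|^2 over positive frequencies);
* ``WP``/``WE`` wavelet energy and entropy of the db4 detail
  coefficients at the band's decomposition level (3-level DWT at
  fs = 128: D1 -> gamma, D2 -> beta, D3 -> alpha);
* ``IMFP``/``IMFE`` energy and spectral entropy of the band's intrinsic
  mode function (IMF1 -> gamma, IMF2 -> beta, IMF3 -> alpha).

Hjorth parameters and spectral entropy are evaluated on band-passed
signals; wavelet and IMF features are evaluated on the broadband
preprocessed signal, since the DWT and EMD are themselves band-limited
decompositions.

Degenerate inputs (constant signals, zero spectral energy, missing
IMFs) raise :class:`~eegaffect.errors.FeatureUndefinedError` rather
than returning NaN; vector assembly decides the fill policy.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pywt

from .emd import EmdResult, emd_decompose
from .errors import EEGAffectError, FeatureUndefinedError, MissingIMFError

__all__ = [
    "FeatureName",
    "hjorth_activity",
    "hjorth_mobility",
    "hjorth_complexity",
    "spectral_entropy",
    "spectral_entropy_from_psd",
    "dwt_detail_coefficients",
    "wavelet_energy",
    "wavelet_entropy",
    "emd_decompose",
    "imf_energy",
    "imf_entropy",
    "asymmetry",
    "WAVE_TO_DWT_LEVEL",
    "WAVE_TO_IMF_INDEX",
]


class FeatureName(str, Enum):
    H1 = "H1"  # Hjorth activity
    H2 = "H2"  # Hjorth mobility
    H3 = "H3"  # Hjorth complexity
    SE = "SE"  # spectral entropy
    WP = "WP"  # wavelet energy
    WE = "WE"  # wavelet entropy
    IMFP = "IMFP"  # IMF energy
    IMFE = "IMFE"  # IMF entropy


# 3-level db4 DWT at fs = 128 Hz: detail subbands 32-64 / 16-32 / 8-16 Hz
WAVE_TO_DWT_LEVEL = {"gamma": "D1", "beta": "D2", "alpha": "D3"}
# EMD extracts the fastest oscillation first
WAVE_TO_IMF_INDEX = {"gamma": 0, "beta": 1, "alpha": 2}


def _check_signal(x: np.ndarray, min_len: int = 2) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < min_len:
        raise EEGAffectError(f"expected a 1-D signal of length >= {min_len}")
    if not np.all(np.isfinite(x)):
        raise EEGAffectError("non-finite samples")
    return x


def hjorth_activity(x: np.ndarray) -> float:
    """Signal variance (population)."""
    x = _check_signal(x)
    return float(np.var(x))


def hjorth_mobility(x: np.ndarray) -> float:
    x = _check_signal(x, 3)
    act = np.var(x)
    if act == 0:
        raise FeatureUndefinedError("mobility undefined on a constant signal")
    return float(np.sqrt(np.var(np.diff(x)) / act))


def hjorth_complexity(x: np.ndarray) -> float:
    x = _check_signal(x, 4)
    mob = hjorth_mobility(x)
    if mob == 0:
        raise FeatureUndefinedError("complexity undefined: zero mobility")
    return float(hjorth_mobility(np.diff(x)) / mob)


def spectral_entropy_from_psd(psd: np.ndarray) -> float:
    """Shannon entropy (bits) of a power spectrum taken as a distribution."""
    psd = np.asarray(psd, dtype=np.float64)
    total = psd.sum()
    if total <= 0 or not np.isfinite(total):
        raise FeatureUndefinedError("spectral entropy undefined: zero spectral power")
    p = psd / total
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def spectral_entropy(x: np.ndarray, fs: float | None = None) -> float:
    """Spectral entropy of a signal (bits).

    The PSD is the magnitude-squared DFT of the mean-removed signal over
    the positive-frequency bins (DC excluded); no taper is applied. The
    sampling rate does not affect the value and is accepted only for
    interface symmetry.
    """
    x = _check_signal(x, 4)
    spec = np.fft.rfft(x - x.mean())
    psd = np.abs(spec[1:]) ** 2
    return spectral_entropy_from_psd(psd)


def dwt_detail_coefficients(
    x: np.ndarray, wavelet: str = "db4", levels: int = 3
) -> dict[str, np.ndarray]:
    """Multi-level DWT detail coefficients D1..Dn plus final approximation.

    Periodised transform, so the decomposition is orthogonal and obeys
    Parseval's identity exactly (up to float round-off).
    """
    x = np.asarray(x, dtype=np.float64)
    min_len = pywt.Wavelet(wavelet).dec_len * 2 ** levels
    if x.size < min_len:
        raise EEGAffectError(
            f"signal of {x.size} samples too short for {levels}-level "
            f"{wavelet} DWT (need >= {min_len})"
        )
    coeffs = pywt.wavedec(x, wavelet, level=levels, mode="periodization")
    out = {f"A{levels}": coeffs[0]}
    for i, c in enumerate(coeffs[1:]):  # coeffs[1] is the coarsest detail
        out[f"D{levels - i}"] = c
    return out


def wavelet_energy(detail: np.ndarray) -> float:
    """Sum of squared magnitudes of one level's detail coefficients."""
    detail = np.asarray(detail, dtype=np.float64)
    return float(np.sum(np.abs(detail) ** 2))


def wavelet_entropy(detail: np.ndarray) -> float:
    """Shannon entropy (bits) of the squared coefficients within one level."""
    detail = np.asarray(detail, dtype=np.float64)
    return spectral_entropy_from_psd(detail ** 2)


def imf_energy(emd: EmdResult, imf_index: int) -> float:
    """Total energy sum c_i(t)^2 of one IMF."""
    if imf_index >= emd.n_imfs:
        raise MissingIMFError(
            f"IMF {imf_index + 1} requested but only {emd.n_imfs} produced"
        )
    return float(np.sum(emd.imfs[imf_index] ** 2))


def imf_entropy(emd: EmdResult, imf_index: int) -> float:
    """Spectral entropy (bits) of one IMF."""
    if imf_index >= emd.n_imfs:
        raise MissingIMFError(
            f"IMF {imf_index + 1} requested but only {emd.n_imfs} produced"
        )
    return spectral_entropy(emd.imfs[imf_index])


def asymmetry(
    features_left: np.ndarray,
    features_right: np.ndarray,
    mode: str = "differential",
) -> np.ndarray:
    """Hemispheric asymmetry over aligned homologous-pair feature values.

    ``differential`` is left - right, ``rational`` is left / right,
    ``both`` concatenates the two (differential first).
    """
    left = np.asarray(features_left, dtype=np.float64)
    right = np.asarray(features_right, dtype=np.float64)
    if left.shape != right.shape:
        raise EEGAffectError("left/right feature lists must align")
    if mode == "differential":
        return left - right
    if mode == "rational":
        if np.any(right == 0):
            raise FeatureUndefinedError("rational asymmetry undefined: right value 0")
        return left / right
    if mode == "both":
        return np.concatenate(
            [asymmetry(left, right, "differential"), asymmetry(left, right, "rational")]
        )
    raise EEGAffectError(f"unknown asymmetry mode {mode!r}")
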
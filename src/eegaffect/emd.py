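"""Empirical mode decomposition by cubic-spline envelope sifting.

EMD decomposes a signal x(t) into intrinsic mode functions (IMFs) —
locally narrow-band oscillations extracted fastest first — plus a final
monotone-ish residue, with exact additive completeness:

    x(t) = sum_i c_i(t) + r_N(t)

One sifting pass finds all local extrema, interpolates the maxima and
minima separately with cubic splines into upper/lower envelopes u(t) and
l(t), and subtracts the envelope mean m(t) = (u + l)/2 from the working
signal. The pass repeats until the candidate satisfies the IMF
conditions (extrema and zero-crossing counts differing by at most one)
and a Cauchy-type stoppage criterion

    SD = sum (h_prev - h_cur)^2 / sum h_prev^2 < stop_threshold

with a hard cap on sift iterations. Spline end effects are handled by
mirroring the two extrema nearest each boundary. Extraction stops when
the residue holds no more than one extremum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import EEGAffectError

__all__ = ["EmdResult", "emd_decompose", "local_extrema", "zero_crossings"]

_DEFAULT_STOP = 0.2
_MAX_SIFT = 100


def local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima.

    Plateau runs count once, at the run midpoint, so a sampled triangle
    wave and its slightly-quantised version agree.
    """
    x = np.asarray(x, dtype=np.float64)
    d = np.sign(np.diff(x))
    # collapse zero slopes onto the preceding trend so plateaus register once
    for i in range(1, d.size):
        if d[i] == 0:
            d[i] = d[i - 1]
    turn = np.diff(d)
    maxima = np.nonzero(turn < 0)[0] + 1
    minima = np.nonzero(turn > 0)[0] + 1
    return maxima, minima


def zero_crossings(x: np.ndarray) -> int:
    """Count sign changes, ignoring exact zeros between opposite signs."""
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


@dataclass
class EmdResult:
    """Ordered IMFs, final residue and per-IMF sift-iteration counts."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    n_sift_iterations: list[int] = field(default_factory=list)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for c in self.imfs:
            out += c
        return out


def _mirrored_envelope(x: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through extrema at ``idx``, mirror-extended.

    The two extrema nearest each end are reflected across the boundary so
    the spline is anchored outside [0, n-1] and does not swing wildly at
    the edges.
    """
    t = idx.astype(np.float64)
    v = x[idx]
    k = min(2, idx.size)
    left_t = -t[:k][::-1]
    left_v = v[:k][::-1]
    right_t = 2 * (n - 1) - t[-k:][::-1]
    right_v = v[-k:][::-1]
    # drop mirrored knots that coincide with originals (extremum at boundary)
    tt = np.concatenate([left_t, t, right_t])
    vv = np.concatenate([left_v, v, right_v])
    tt, keep = np.unique(tt, return_index=True)
    vv = vv[keep]
    spline = CubicSpline(tt, vv)
    return spline(np.arange(n, dtype=np.float64))


def _is_imf(h: np.ndarray) -> bool:
    maxima, minima = local_extrema(h)
    n_ext = maxima.size + minima.size
    return abs(n_ext - zero_crossings(h)) <= 1


def _sift_one(
    x: np.ndarray, stop_threshold: float, max_sift: int
) -> tuple[np.ndarray, int] | None:
    """Extract a single IMF from ``x``; None if ``x`` has < 2 of each extremum."""
    n = x.size
    h = x.copy()
    for it in range(1, max_sift + 1):
        maxima, minima = local_extrema(h)
        if maxima.size < 2 or minima.size < 2:
            return None if it == 1 else (h, it - 1)
        upper = _mirrored_envelope(h, maxima, n)
        lower = _mirrored_envelope(h, minima, n)
        m = 0.5 * (upper + lower)
        d = h - m
        denom = float(np.sum(h * h))
        sd = float(np.sum((h - d) ** 2)) / denom if denom > 0 else 0.0
        h = d
        if sd < stop_threshold and _is_imf(h):
            return h, it
    return h, max_sift


def emd_decompose(
    x: np.ndarray,
    max_imfs: int = 10,
    stop_threshold: float = _DEFAULT_STOP,
) -> EmdResult:
    """Decompose a signal into IMFs plus residue.

    A monotone (or otherwise extremum-poor) signal yields zero IMFs with
    the input as residue. Completeness ``sum(imfs) + residue == x`` holds
    exactly by construction: the residue is updated by subtraction.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 8:
        raise EEGAffectError("emd_decompose expects a 1-D signal of length >= 8")
    if not np.all(np.isfinite(x)):
        raise EEGAffectError("non-finite samples")
    imfs: list[np.ndarray] = []
    sift_counts: list[int] = []
    residue = x.copy()
    for _ in range(max_imfs):
        maxima, minima = local_extrema(residue)
        if maxima.size + minima.size <= 1:
            break
        extracted = _sift_one(residue, stop_threshold, _MAX_SIFT)
        if extracted is None:
            break
        imf, n_it = extracted
        imfs.append(imf)
        sift_counts.append(n_it)
        residue = residue - imf
    return EmdResult(imfs=imfs, residue=residue, n_sift_iterations=sift_counts)
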
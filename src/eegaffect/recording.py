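"""Core data model: trial labels, recordings and fixed-length epochs.

A :class:`Recording` is one participant-trial multichannel EEG segment
(channels x samples, microvolts) with its sampling rate, montage and
self-assessment labels. Valence and arousal ratings arrive on a source
scale (typically the 9-point SAM scale) and are normalised affinely to
[0, 1], the scale on which all prediction errors are reported.

Epoch segmentation cuts a recording into fixed-length windows (default
4 s with 50 % overlap); every epoch inherits the trial's labels, since
self-reports refer to the whole stimulus.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EEGAffectError, LabelError
from .montage import Montage

logger = logging.getLogger(__name__)

__all__ = ["AffectLabel", "Recording", "Epoch", "segment_epochs"]


@dataclass(frozen=True)
class AffectLabel:
    """Valence/arousal self-assessment on a source rating scale.

    ``valence`` and ``arousal`` are the normalised values
    ``(raw - scale_min) / (scale_max - scale_min)`` in [0, 1].
    """

    valence_raw: float
    arousal_raw: float
    scale_min: float = 1.0
    scale_max: float = 9.0

    def __post_init__(self) -> None:
        if not self.scale_max > self.scale_min:
            raise LabelError("scale_max must exceed scale_min")
        for raw in (self.valence_raw, self.arousal_raw):
            if not (self.scale_min <= raw <= self.scale_max):
                raise LabelError(
                    f"rating {raw} outside scale [{self.scale_min}, {self.scale_max}]"
                )

    def _normalise(self, raw: float) -> float:
        return (raw - self.scale_min) / (self.scale_max - self.scale_min)

    @property
    def valence(self) -> float:
        return self._normalise(self.valence_raw)

    @property
    def arousal(self) -> float:
        return self._normalise(self.arousal_raw)

    def denormalise(self, value: float) -> float:
        """Inverse of the affine normalisation (normalised -> raw)."""
        return value * (self.scale_max - self.scale_min) + self.scale_min

    @classmethod
    def from_normalised(
        cls, valence: float, arousal: float,
        scale_min: float = 1.0, scale_max: float = 9.0,
    ) -> "AffectLabel":
        span = scale_max - scale_min
        return cls(valence * span + scale_min, arousal * span + scale_min,
                   scale_min, scale_max)


@dataclass
class Recording:
    """One participant-trial multichannel EEG recording.

    ``data`` is channels x samples in montage order, microvolts.
    """

    data: np.ndarray
    fs: float
    montage: Montage
    labels: AffectLabel
    trial_id: str = "trial0"
    subject_id: str = "s0"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise EEGAffectError("recording data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise EEGAffectError(
                f"data has {self.data.shape[0]} rows but montage "
                f"{self.montage.name!r} has {self.montage.n_channels} channels"
            )
        if not self.fs > 0:
            raise EEGAffectError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise EEGAffectError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Epoch:
    """A fixed-length window of a recording carrying the trial's labels."""

    data: np.ndarray
    fs: float
    montage: Montage
    labels: AffectLabel
    trial_id: str = "trial0"
    subject_id: str = "s0"
    epoch_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != self.montage.n_channels:
            raise EEGAffectError("epoch data shape inconsistent with montage")


def segment_epochs(
    rec: Recording, epoch_seconds: float = 4.0, overlap_fraction: float = 0.5
) -> list[Epoch]:
    """Cut a recording into fixed windows with fractional overlap.

    Windows start at 0, hop, 2*hop, ... with
    ``hop = epoch_seconds * (1 - overlap_fraction)``; a trailing partial
    window is dropped (padding would distort spectral features). A
    recording shorter than one window yields an empty list with a warning.
    """
    if not 0 <= overlap_fraction < 1:
        raise EEGAffectError("overlap_fraction must be in [0, 1)")
    window = int(round(epoch_seconds * rec.fs))
    if window < 2:
        raise EEGAffectError("epoch shorter than 2 samples")
    hop = epoch_seconds * (1 - overlap_fraction) * rec.fs
    if rec.n_samples < window:
        logger.warning(
            "recording %s/%s (%d samples) shorter than one %d-sample epoch",
            rec.subject_id, rec.trial_id, rec.n_samples, window,
        )
        return []
    n_epochs = int(math.floor((rec.n_samples - window) / hop)) + 1
    epochs = []
    for i in range(n_epochs):
        start = int(round(i * hop))
        epochs.append(
            Epoch(
                data=rec.data[:, start : start + window],
                fs=rec.fs,
                montage=rec.montage,
                labels=rec.labels,
                trial_id=rec.trial_id,
                subject_id=rec.subject_id,
                epoch_index=i,
            )
        )
    return epochs
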
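"""Assembly of named feature-vector configurations into epoch matrices.

A :class:`VectorConfig` names which waves, per-wave feature subsets and
asymmetry block make up one feature vector. Column order is fixed and
documented for reproducibility: waves outermost (alpha, beta, gamma
order), channels in montage order, features innermost; the asymmetry
block is appended last (differential before rational when both are
used), pairs outer, features inner.

Built-in configurations mirror the models retained after feature
selection on 32-channel data plus the intermediate study vectors:

* ``knn_selected`` — all features except SE from all three bands, plus
  the alpha differential asymmetry with all features except H3
  (dimension 770 on 32 channels, 343 on 14);
* ``rf_selected`` — H1 and WP from beta and gamma, plus the alpha
  differential asymmetry of H1, WP and WE (170 / 77);
* ``full_per_band`` — all 8 features of one wave on every channel (256
  on 32 channels);
* ``asym_differential`` / ``asym_rational`` — all 8 features over the
  homologous pairs for one wave, one mode (112 on 32 channels);
* ``asym_both`` — the two previous blocks concatenated (224).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EEGAffectError, FeatureUndefinedError
from . import features as ft
from .features import FeatureName
from .montage import Montage
from .preprocessing import (
    DEFAULT_BANDS,
    WAVE_ORDER,
    PreprocConfig,
    bandpass_fir,
    preprocess_channel,
)
from .recording import Epoch

logger = logging.getLogger(__name__)

__all__ = ["VectorConfig", "FeatureMatrix", "builtin_config", "assemble",
           "ALL_FEATURES", "BUILTIN_CONFIG_NAMES"]

ALL_FEATURES: tuple[FeatureName, ...] = tuple(FeatureName)

# per-channel features needing a band-passed signal; the rest use the
# broadband signal through DWT / EMD
_BANDPASS_FEATURES = {FeatureName.H1, FeatureName.H2, FeatureName.H3, FeatureName.SE}


def _canonical_waves(waves) -> tuple[str, ...]:
    waves = tuple(waves)
    for w in waves:
        if w not in WAVE_ORDER:
            raise EEGAffectError(f"unknown wave {w!r}")
    return tuple(w for w in WAVE_ORDER if w in waves)


@dataclass(frozen=True)
class VectorConfig:
    """Declarative description of one feature-vector layout."""

    montage: Montage
    waves: tuple[str, ...] = ()
    features_per_wave: dict[str, tuple[FeatureName, ...]] = field(default_factory=dict)
    asymmetry_wave: str | None = None
    asymmetry_mode: str = "none"  # differential | rational | both | none
    asymmetry_features: tuple[FeatureName, ...] = ()
    name: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "waves", _canonical_waves(self.waves))
        if self.asymmetry_mode not in ("differential", "rational", "both", "none"):
            raise EEGAffectError(f"bad asymmetry mode {self.asymmetry_mode!r}")
        if self.asymmetry_mode != "none" and self.asymmetry_wave is None:
            raise EEGAffectError("asymmetry mode set but no asymmetry wave")
        for w in self.waves:
            if w not in self.features_per_wave or not self.features_per_wave[w]:
                raise EEGAffectError(f"no features declared for wave {w!r}")

    @property
    def n_asym_modes(self) -> int:
        return {"none": 0, "differential": 1, "rational": 1, "both": 2}[
            self.asymmetry_mode
        ]

    @property
    def dimension(self) -> int:
        n = sum(
            len(self.features_per_wave[w]) * self.montage.n_channels
            for w in self.waves
        )
        n += (
            len(self.asymmetry_features)
            * self.montage.n_pairs
            * self.n_asym_modes
        )
        return n

    def schema(self) -> list[dict]:
        """Ordered column descriptors (one dict per feature column)."""
        cols: list[dict] = []
        for wave in self.waves:
            for channel in self.montage.channels:
                for feat in self.features_per_wave[wave]:
                    cols.append(
                        {"kind": "channel", "wave": wave, "channel": channel,
                         "feature": feat.value}
                    )
        modes = {"differential": ["differential"], "rational": ["rational"],
                 "both": ["differential", "rational"], "none": []}[self.asymmetry_mode]
        for mode in modes:
            for left, right in self.montage.asymmetry_pairs:
                for feat in self.asymmetry_features:
                    cols.append(
                        {"kind": "asymmetry", "wave": self.asymmetry_wave,
                         "pair": f"{left}-{right}", "mode": mode,
                         "feature": feat.value}
                    )
        assert len(cols) == self.dimension
        return cols


def _except_features(*excluded: FeatureName) -> tuple[FeatureName, ...]:
    return tuple(f for f in ALL_FEATURES if f not in excluded)


BUILTIN_CONFIG_NAMES = (
    "knn_selected", "rf_selected", "full_per_band",
    "asym_differential", "asym_rational", "asym_both",
)


def builtin_config(name: str, montage: Montage, wave: str = "gamma") -> VectorConfig:
    """Return a built-in :class:`VectorConfig` for a montage.

    ``wave`` selects the band for the single-wave configurations
    (``full_per_band`` and the asymmetry-only vectors); the selected
    models fix their own waves.
    """
    if name == "knn_selected":
        feats = _except_features(FeatureName.SE)
        return VectorConfig(
            montage=montage,
            waves=("alpha", "beta", "gamma"),
            features_per_wave={w: feats for w in ("alpha", "beta", "gamma")},
            asymmetry_wave="alpha",
            asymmetry_mode="differential",
            asymmetry_features=_except_features(FeatureName.H3),
            name=name,
        )
    if name == "rf_selected":
        feats = (FeatureName.H1, FeatureName.WP)
        return VectorConfig(
            montage=montage,
            waves=("beta", "gamma"),
            features_per_wave={w: feats for w in ("beta", "gamma")},
            asymmetry_wave="alpha",
            asymmetry_mode="differential",
            asymmetry_features=(FeatureName.H1, FeatureName.WP, FeatureName.WE),
            name=name,
        )
    if name == "full_per_band":
        return VectorConfig(
            montage=montage,
            waves=(wave,),
            features_per_wave={wave: ALL_FEATURES},
            name=name,
        )
    if name in ("asym_differential", "asym_rational", "asym_both"):
        mode = name.removeprefix("asym_")
        return VectorConfig(
            montage=montage,
            asymmetry_wave=wave,
            asymmetry_mode=mode,
            asymmetry_features=ALL_FEATURES,
            name=name,
        )
    raise EEGAffectError(
        f"unknown config {name!r}; available: {BUILTIN_CONFIG_NAMES}"
    )


@dataclass
class FeatureMatrix:
    """Epoch-by-feature matrix with targets and a documented column schema."""

    X: np.ndarray
    schema: list[dict]
    targets: np.ndarray  # n x 2, columns (valence, arousal)
    subject_ids: list[str]
    trial_ids: list[str]
    epoch_indices: list[int]
    n_flagged: int = 0

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def valence(self) -> np.ndarray:
        return self.targets[:, 0]

    @property
    def arousal(self) -> np.ndarray:
        return self.targets[:, 1]

    def column_names(self) -> list[str]:
        names = []
        for col in self.schema:
            if col["kind"] == "channel":
                names.append(f"{col['wave']}:{col['channel']}:{col['feature']}")
            else:
                names.append(
                    f"asym:{col['mode']}:{col['wave']}:{col['pair']}:{col['feature']}"
                )
        return names

    def select_columns(self, mask) -> "FeatureMatrix":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return FeatureMatrix(
            X=self.X[:, idx],
            schema=[self.schema[i] for i in idx],
            targets=self.targets,
            subject_ids=self.subject_ids,
            trial_ids=self.trial_ids,
            epoch_indices=self.epoch_indices,
            n_flagged=self.n_flagged,
        )

    def to_csv(self, path) -> None:
        frame = pd.DataFrame(self.X, columns=self.column_names())
        frame.insert(0, "epoch_index", self.epoch_indices)
        frame.insert(0, "trial_id", self.trial_ids)
        frame.insert(0, "subject_id", self.subject_ids)
        frame.insert(3, "valence", self.targets[:, 0])
        frame.insert(4, "arousal", self.targets[:, 1])
        frame.to_csv(path, index=False)


class _ChannelCache:
    """Lazily computed per-channel signal derivatives for one epoch."""

    def __init__(self, raw: np.ndarray, fs: float, preproc: PreprocConfig):
        self.fs = fs
        self.preproc = preproc
        self.broadband = preprocess_channel(raw, fs, preproc)
        self._bands: dict[str, np.ndarray] = {}
        self._dwt: dict[str, np.ndarray] | None = None
        self._emd = None

    def band(self, wave: str) -> np.ndarray:
        if wave not in self._bands:
            self._bands[wave] = bandpass_fir(
                self.broadband, self.fs, DEFAULT_BANDS[wave], self.preproc.fir_order
            )
        return self._bands[wave]

    def dwt(self) -> dict[str, np.ndarray]:
        if self._dwt is None:
            levels = _dwt_levels_for_fs(self.fs)
            self._dwt = ft.dwt_detail_coefficients(self.broadband, levels=levels)
        return self._dwt

    def emd(self):
        if self._emd is None:
            self._emd = ft.emd_decompose(self.broadband)
        return self._emd

    def feature(self, wave: str, feat: FeatureName) -> float:
        if feat in _BANDPASS_FEATURES:
            x = self.band(wave)
            if feat == FeatureName.H1:
                return ft.hjorth_activity(x)
            if feat == FeatureName.H2:
                return ft.hjorth_mobility(x)
            if feat == FeatureName.H3:
                return ft.hjorth_complexity(x)
            return ft.spectral_entropy(x)
        if feat in (FeatureName.WP, FeatureName.WE):
            level = _dwt_level_for_wave(wave, self.fs)
            detail = self.dwt()[level]
            if feat == FeatureName.WP:
                return ft.wavelet_energy(detail)
            return ft.wavelet_entropy(detail)
        imf_index = ft.WAVE_TO_IMF_INDEX[wave]
        if feat == FeatureName.IMFP:
            return ft.imf_energy(self.emd(), imf_index)
        return ft.imf_entropy(self.emd(), imf_index)


def _dwt_levels_for_fs(fs: float) -> int:
    """Decomposition depth placing the alpha band in the coarsest detail.

    At 128 Hz three levels give details 32-64/16-32/8-16 Hz; each
    doubling of fs needs one extra level.
    """
    extra = math.log2(fs / 128.0)
    if extra < 0 or abs(extra - round(extra)) > 1e-9:
        raise EEGAffectError(
            f"DWT band mapping requires fs = 128 * 2^k, got {fs}"
        )
    return 3 + int(round(extra))


def _dwt_level_for_wave(wave: str, fs: float) -> str:
    extra = _dwt_levels_for_fs(fs) - 3
    base = int(ft.WAVE_TO_DWT_LEVEL[wave][1])
    return f"D{base + extra}"


def assemble(
    epochs: list[Epoch],
    config: VectorConfig,
    preproc: PreprocConfig | None = None,
) -> FeatureMatrix:
    """Compute the configured feature vector for every epoch.

    Undefined features (degenerate signals, missing IMFs, zero divisors
    in rational asymmetry) are recorded as 0 and counted in
    ``n_flagged`` so the matrix stays rectangular and NaN-free.
    """
    if not epochs:
        raise EEGAffectError("no epochs to assemble")
    preproc = preproc or PreprocConfig()
    montage = config.montage
    for ep in epochs:
        if ep.montage.name != montage.name:
            raise EEGAffectError(
                f"epoch montage {ep.montage.name!r} != config montage {montage.name!r}"
            )
    schema = config.schema()
    n_flagged = 0
    rows = []
    # channels actually needed: all montage channels for per-channel blocks,
    # pair members only for asymmetry-only configs
    needed = set()
    if config.waves:
        needed.update(montage.channels)
    if config.asymmetry_mode != "none":
        for left, right in montage.asymmetry_pairs:
            needed.update((left, right))

    for ep in epochs:
        caches = {
            ch: _ChannelCache(ep.data[montage.index(ch)], ep.fs, preproc)
            for ch in montage.channels
            if ch in needed
        }
        row = np.empty(len(schema))
        for j, col in enumerate(schema):
            try:
                if col["kind"] == "channel":
                    value = caches[col["channel"]].feature(
                        col["wave"], FeatureName(col["feature"])
                    )
                else:
                    left, right = col["pair"].split("-")
                    feat = FeatureName(col["feature"])
                    lv = caches[left].feature(col["wave"], feat)
                    rv = caches[right].feature(col["wave"], feat)
                    value = float(
                        ft.asymmetry([lv], [rv], col["mode"])[0]
                    )
            except FeatureUndefinedError:
                value = 0.0
                n_flagged += 1
            row[j] = value
        rows.append(row)
    if n_flagged:
        logger.warning("%d undefined feature values recorded as 0", n_flagged)
    X = np.vstack(rows)
    targets = np.array(
        [[ep.labels.valence, ep.labels.arousal] for ep in epochs], dtype=np.float64
    )
    return FeatureMatrix(
        X=X,
        schema=schema,
        targets=targets,
        subject_ids=[ep.subject_id for ep in epochs],
        trial_ids=[ep.trial_id for ep in epochs],
        epoch_indices=[ep.epoch_index for ep in epochs],
        n_flagged=n_flagged,
    )
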
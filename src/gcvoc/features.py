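"""Wavelet-coefficient feature extraction.

Each fully preprocessed chromatogram is reduced to a fixed-length vector
of 3601 discrete-wavelet coefficients: the first 1800 s of the run (3601
ticks at 0.5 s) are decomposed with a multilevel DWT (Daubechies-4 at the
maximum dyadic level by default) and the concatenated coefficient arrays
[cA_L, cD_L, ..., cD_1] are truncated (or zero-padded) to exactly 3601
entries.  The feature_id ↔ (level, position) mapping is deterministic and
identical across samples, partitions and runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

from gcvoc.preprocess import Chromatogram

N_FEATURES = 3601


@dataclass(frozen=True)
class WaveletConfig:
    wavelet: str = "db4"
    window_s: float = 1800.0
    level: int | None = None  # None = max dyadic level for the window
    n_features: int = N_FEATURES
    mode: str = "symmetric"

    def window_ticks(self, tick_s: float) -> int:
        return int(round(self.window_s / tick_s)) + 1


def decompose(values: np.ndarray, cfg: WaveletConfig = WaveletConfig()) -> list[np.ndarray]:
    """Multilevel DWT of the analysis window; returns the pywt coefficient list."""
    level = cfg.level or pywt.dwt_max_level(len(values), cfg.wavelet)
    return pywt.wavedec(values, cfg.wavelet, mode=cfg.mode, level=level)


def reconstruct(coeffs: list[np.ndarray], cfg: WaveletConfig = WaveletConfig()) -> np.ndarray:
    return pywt.waverec(coeffs, cfg.wavelet, mode=cfg.mode)


def feature_map(window_len: int, cfg: WaveletConfig = WaveletConfig()) -> pd.DataFrame:
    """feature_id → (band, position) table for the flattened coefficient vector.

    Band names follow the decomposition order: 'aL' for the level-L
    approximation, then 'dL' ... 'd1' details.  Each row also carries the
    approximate time support centre (seconds) of that coefficient, used to
    attribute selected features back to elution-time regions.
    """
    coeffs = decompose(np.zeros(window_len), cfg)
    level = len(coeffs) - 1
    names = [f"a{level}"] + [f"d{lv}" for lv in range(level, 0, -1)]
    rows = []
    k = 0
    for name, arr in zip(names, coeffs):
        lv = int(name[1:])
        scale = 2**lv
        for pos in range(len(arr)):
            if k >= cfg.n_features:
                break
            rows.append(
                dict(
                    feature_id=f"f{k + 1:04d}",
                    band=name,
                    position=pos,
                    time_centre_s=pos * scale * 0.5,  # tick_s fixed downstream of the window
                )
            )
            k += 1
    while k < cfg.n_features:
        rows.append(dict(feature_id=f"f{k + 1:04d}", band="pad", position=k, time_centre_s=np.nan))
        k += 1
    return pd.DataFrame(rows).set_index("feature_id")


def wavelet_transform(c: Chromatogram, cfg: WaveletConfig = WaveletConfig()) -> np.ndarray:
    """Fixed-length coefficient vector for one preprocessed chromatogram."""
    if not (c.baseline_corrected and c.normalised and c.aligned):
        raise ValueError(f"{c.sample_id}: chromatogram must be fully preprocessed before transformation")
    n = cfg.window_ticks(c.tick_s)
    if len(c.values) < n:
        raise ValueError(
            f"{c.sample_id}: trace length {len(c.values)} shorter than required analysis window {n}"
        )
    flat = np.concatenate(decompose(c.values[:n], cfg))
    if len(flat) >= cfg.n_features:
        return flat[: cfg.n_features]
    return np.pad(flat, (0, cfg.n_features - len(flat)))


@dataclass
class FeatureMatrix:
    """samples × 3601 wavelet coefficients with a train/validation partition."""

    values: pd.DataFrame  # index sample_id, columns feature_ids
    partition: pd.Series  # sample_id → 'training' | 'validation'
    config: WaveletConfig = field(default_factory=WaveletConfig)
    fmap: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.values.columns.duplicated().any() or self.values.index.duplicated().any():
            raise ValueError("duplicate feature_id or sample_id")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, sample_ids: list[str]) -> pd.DataFrame:
        return self.values.loc[sample_ids]

    def training(self) -> pd.DataFrame:
        return self.values.loc[self.partition[self.partition == "training"].index]

    def validation(self) -> pd.DataFrame:
        return self.values.loc[self.partition[self.partition == "validation"].index]


def build_feature_matrix(
    processed: list[Chromatogram], cfg: WaveletConfig = WaveletConfig()
) -> FeatureMatrix:
    """Transform each processed trace; rows follow the input order."""
    ids = [c.sample_id for c in processed]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in processed set")
    lengths = {len(c.values) for c in processed}
    if len(lengths) > 1:
        raise ValueError(f"mixed trace lengths {sorted(lengths)}")
    rows = np.stack([wavelet_transform(c, cfg) for c in processed])
    cols = [f"f{i + 1:04d}" for i in range(cfg.n_features)]
    values = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"), columns=cols)
    partition = pd.Series(
        {c.sample_id: ("validation" if c.batch == "validation" else "training") for c in processed},
        name="partition",
    )
    n = cfg.window_ticks(processed[0].tick_s)
    return FeatureMatrix(values=values, partition=partition, config=cfg, fmap=feature_map(n, cfg))
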
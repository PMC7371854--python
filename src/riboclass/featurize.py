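"""k-mer frequency features and fixed-length integer encodings.

Two feature spaces feed the classifiers:

* **k-mer frequencies** — 20 engineered features per sequence: the 4
  mononucleotide frequencies (A, C, G, T) followed by the 16 overlapping
  dinucleotide frequencies in lexicographic order (AA, AC, ..., TT).  These
  feed the conventional classifiers after standardization to zero mean and
  unit variance (statistics fitted on the training split only).
* **integer encoding** — the first ``L`` bases (default 250) mapped to codes
  1..4 with a dedicated pad code 0 on the right, consumed directly by the
  deep classifiers; the pad code carries no signal (all-zero one-hot row).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MONO_ORDER",
    "DI_ORDER",
    "FEATURE_NAMES",
    "DEFAULT_ENCODING_LENGTH",
    "kmer_features",
    "kmer_feature_matrix",
    "Standardizer",
    "encode_sequence",
    "encode_sequences",
    "decode_sequence",
]

MONO_ORDER: tuple[str, ...] = ("A", "C", "G", "T")
DI_ORDER: tuple[str, ...] = tuple(
    a + b for a, b in itertools.product(MONO_ORDER, MONO_ORDER)
)
FEATURE_NAMES: tuple[str, ...] = MONO_ORDER + DI_ORDER

DEFAULT_ENCODING_LENGTH = 250

_BASE_CODE = {"A": 1, "C": 2, "G": 3, "T": 4}
_CODE_BASE = {v: k for k, v in _BASE_CODE.items()}
_MONO_INDEX = {b: i for i, b in enumerate(MONO_ORDER)}
_DI_INDEX = {d: i for i, d in enumerate(DI_ORDER)}


def kmer_features(seq: str) -> np.ndarray:
    """The 20-element k-mer frequency vector of a sanitized sequence.

    Mononucleotide frequency is count/len; dinucleotide frequency is the
    count of overlapping dimers divided by len-1, so each block is a
    probability simplex.  Requires length >= 2 (dinucleotide frequencies are
    undefined otherwise).
    """
    n = len(seq)
    if n < 2:
        raise ValueError(
            f"sequence of length {n}: dinucleotide frequencies need length >= 2"
        )
    v = np.zeros(20)
    for ch in seq:
        v[_MONO_INDEX[ch]] += 1.0
    for i in range(n - 1):
        v[4 + _DI_INDEX[seq[i : i + 2]]] += 1.0
    v[:4] /= n
    v[4:] /= n - 1
    return v


def kmer_feature_matrix(seqs: Iterable[str]) -> np.ndarray:
    """Stack :func:`kmer_features` over sequences into an (n, 20) matrix."""
    return np.array([kmer_features(s) for s in seqs])


@dataclass
class Standardizer:
    """Per-feature zero-mean/unit-variance scaling.

    Fit on the training split only and applied unchanged to validation and
    test features, avoiding information leakage across the split.  Constant
    columns get scale 1 so they transform to all zeros.
    """

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, features: np.ndarray) -> "Standardizer":
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or features.shape[0] == 0:
            raise ValueError("fit set must be a non-empty 2-D matrix")
        mean = features.mean(axis=0)
        scale = features.std(axis=0)
        scale = np.where(scale == 0.0, 1.0, scale)
        return cls(mean=mean, scale=scale)

    def transform(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        return (features - self.mean) / self.scale

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"mean": self.mean.tolist(), "scale": self.scale.tolist()})
        )

    @classmethod
    def load(cls, path: str | Path) -> "Standardizer":
        d = json.loads(Path(path).read_text())
        return cls(mean=np.array(d["mean"]), scale=np.array(d["scale"]))


def encode_sequence(seq: str, length: int = DEFAULT_ENCODING_LENGTH) -> np.ndarray:
    """Integer-encode the first ``min(len, length)`` bases, right-padded with 0.

    Codes: 0 = pad, 1 = A, 2 = C, 3 = G, 4 = T.  Sequences longer than
    ``length`` are truncated to their first ``length`` bases, preserving the
    5'-proximal prefix that carries the aptamer.
    """
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    if length < 1:
        raise ValueError("encoding length must be positive")
    codes = np.zeros(length, dtype=np.int64)
    for i, ch in enumerate(seq[:length]):
        codes[i] = _BASE_CODE[ch]
    return codes


def encode_sequences(
    seqs: Sequence[str], length: int = DEFAULT_ENCODING_LENGTH
) -> np.ndarray:
    return np.stack([encode_sequence(s, length) for s in seqs])


def decode_sequence(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence` up to truncation (pads dropped)."""
    return "".join(_CODE_BASE[int(c)] for c in codes if c != 0)
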
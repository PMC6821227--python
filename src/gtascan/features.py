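"""Compositional feature encoders for protein sequences.

Three encoders are available and may be combined; their blocks are
concatenated in a fixed order (k-mer, PseAAC, physicochemical):

``k-mer``
    Counts of all overlapping length-k subsequences. The vocabulary is the
    lexicographically sorted union of k-mers seen at fit time and is frozen
    into the model, so prediction never depends on the query batch: unseen
    k-mers in a query are ignored and absent ones are zero-filled.

``PseAAC``
    Pseudo-amino-acid composition of dimension 20 + lambda: the 20 residue
    counts plus lambda sequence-order correlation factors built from
    standardized hydrophobicity, hydrophilicity and side-chain mass scales,
    mixed with weight omega (default 0.05). The vector is normalized to sum
    to 1 by construction.

``physchem``
    Length-normalized counts over 19 overlapping physicochemical residue
    classes.

The raw scales and the class table ship as editable TSV data files; see
``load_raw_scales`` and ``load_physchem_classes``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from gtascan.io import AA_ALPHABET, SequenceRecord

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

SCALE_NAMES = ("hydrophobicity", "hydrophilicity", "side_chain_mass")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("gtascan").joinpath("data", name)))


@dataclass(frozen=True)
class AminoAcidScales:
    """Raw and standardized per-residue scales, aligned to ``AA_ALPHABET``.

    ``raw`` holds one length-20 array per scale name; ``standardized`` holds
    the centered versions divided by the root of the mean squared deviation,
    so each standardized scale has zero mean and unit root-mean-square.
    """

    raw: dict[str, np.ndarray]
    standardized: dict[str, np.ndarray] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name, vals in self.raw.items():
            if np.asarray(vals).shape != (20,):
                raise ValueError(f"scale {name!r} must have 20 values")
        if self.standardized is None:
            object.__setattr__(
                self,
                "standardized",
                {n: _standardize_one(np.asarray(v, float)) for n, v in self.raw.items()},
            )


def _standardize_one(raw: np.ndarray) -> np.ndarray:
    centered = raw - raw.mean()
    denom = np.sqrt(np.mean(centered**2))
    if denom == 0:
        raise ValueError("constant scale cannot be standardized")
    return centered / denom


def standardize_scales(scales: AminoAcidScales) -> AminoAcidScales:
    """Return scales with the standardization recomputed from the raw values."""
    return AminoAcidScales(raw=dict(scales.raw))


def load_raw_scales(path: str | Path | None = None) -> AminoAcidScales:
    """Load (and standardize) the shipped or a user-supplied scale table."""
    path = Path(path) if path is not None else _data_path("aa_scales.tsv")
    raw = {name: np.zeros(20) for name in SCALE_NAMES}
    seen: set[str] = set()
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                if header[0] != "aa" or set(SCALE_NAMES) - set(header):
                    raise ValueError(f"{path}: bad scale table header {header}")
                continue
            aa = parts[0]
            if aa not in _AA_INDEX:
                raise ValueError(f"{path}: unknown residue {aa!r}")
            seen.add(aa)
            for name in SCALE_NAMES:
                raw[name][_AA_INDEX[aa]] = float(parts[header.index(name)])
    if seen != set(AA_ALPHABET):
        raise ValueError(f"{path}: missing residues {sorted(set(AA_ALPHABET) - seen)}")
    return AminoAcidScales(raw=raw)


def load_physchem_classes(path: str | Path | None = None) -> dict[str, frozenset[str]]:
    """Load the 19 overlapping physicochemical classes (name -> residue set)."""
    path = Path(path) if path is not None else _data_path("physchem_classes.tsv")
    classes: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        header_skipped = False
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if not header_skipped:
                header_skipped = True
                continue
            name, residues = line.split("\t")
            members = frozenset(residues)
            if not members or members - set(AA_ALPHABET):
                raise ValueError(f"{path}: bad class {name!r}")
            classes[name] = members
    if len(classes) != 19:
        raise ValueError(f"{path}: expected 19 classes, found {len(classes)}")
    return classes


# ---------------------------------------------------------------------------
# individual encoders


def kmer_features(seq: SequenceRecord | str, k: int) -> dict[str, int]:
    """Counts of all overlapping k-mers; the counts sum to L - k + 1."""
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    if not 1 <= k <= len(s):
        raise ValueError(f"k={k} out of range for sequence of length {len(s)}")
    counts: dict[str, int] = {}
    for i in range(len(s) - k + 1):
        kmer = s[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def pseaac_features(
    seq: SequenceRecord | str,
    lam: int,
    omega: float = 0.05,
    scales: AminoAcidScales | None = None,
) -> np.ndarray:
    """Pseudo-amino-acid composition vector of length 20 + lam.

    The first 20 components are residue counts and the last ``lam`` are the
    order-correlation factors, all divided by the common normalizer
    (sum of counts + omega * sum of factors); the vector sums to 1.
    """
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    L = len(s)
    if L <= lam:
        raise ValueError(f"sequence length {L} must exceed lambda={lam}")
    if scales is None:
        scales = _default_scales()
    idx = np.fromiter((_AA_INDEX[c] for c in s), dtype=int, count=L)
    counts = np.bincount(idx, minlength=20).astype(float)

    h1 = scales.standardized["hydrophobicity"][idx]
    h2 = scales.standardized["hydrophilicity"][idx]
    m = scales.standardized["side_chain_mass"][idx]
    theta = np.empty(lam)
    for k in range(1, lam + 1):
        # mean over i of J(i, i+k), J = mean sq. difference of the 3 scales
        d1 = h1[k:] - h1[:-k]
        d2 = h2[k:] - h2[:-k]
        dm = m[k:] - m[:-k]
        theta[k - 1] = np.mean((d1**2 + d2**2 + dm**2) / 3.0)

    denom = counts.sum() + omega * theta.sum()
    return np.concatenate([counts, omega * theta]) / denom


def physchem_features(
    seq: SequenceRecord | str,
    classes: Mapping[str, frozenset[str]] | None = None,
) -> np.ndarray:
    """Length-normalized counts over the 19 physicochemical classes."""
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    if not s:
        raise ValueError("empty sequence")
    if classes is None:
        classes = _default_classes()
    residue_counts = np.bincount(
        np.fromiter((_AA_INDEX[c] for c in s), dtype=int, count=len(s)), minlength=20
    )
    out = np.empty(len(classes))
    for j, members in enumerate(classes.values()):
        out[j] = sum(residue_counts[_AA_INDEX[aa]] for aa in members)
    return out / len(s)


_SCALES_CACHE: AminoAcidScales | None = None
_CLASSES_CACHE: dict[str, frozenset[str]] | None = None


def _default_scales() -> AminoAcidScales:
    global _SCALES_CACHE
    if _SCALES_CACHE is None:
        _SCALES_CACHE = load_raw_scales()
    return _SCALES_CACHE


def _default_classes() -> dict[str, frozenset[str]]:
    global _CLASSES_CACHE
    if _CLASSES_CACHE is None:
        _CLASSES_CACHE = load_physchem_classes()
    return _CLASSES_CACHE


# ---------------------------------------------------------------------------
# combined featurizer


@dataclass(frozen=True)
class FeatureSpec:
    """Which encoders are active: at most one k, at most one lambda, physchem flag."""

    kmer_k: int | None = None
    pseaac_lambda: int | None = None
    pseaac_omega: float = 0.05
    physchem: bool = False

    def __post_init__(self) -> None:
        if self.kmer_k is None and self.pseaac_lambda is None and not self.physchem:
            raise ValueError("at least one encoder must be active")
        if self.kmer_k is not None and not 1 <= self.kmer_k <= 6:
            raise ValueError("kmer_k must lie in 1..6")
        if self.pseaac_lambda is not None and self.pseaac_lambda not in (3, 6):
            raise ValueError("pseaac_lambda must be 3 or 6")
        if self.pseaac_omega <= 0:
            raise ValueError("pseaac_omega must be positive")

    def to_dict(self) -> dict:
        return {
            "kmer_k": self.kmer_k,
            "pseaac_lambda": self.pseaac_lambda,
            "pseaac_omega": self.pseaac_omega,
            "physchem": self.physchem,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        return cls(**d)


class SequenceFeaturizer:
    """Transformer mapping protein sequences to numeric feature rows.

    Follows the scikit-learn transformer protocol: ``fit`` freezes the k-mer
    vocabulary from the training sequences; ``transform`` encodes any batch
    against that vocabulary. ``kmer_normalize`` divides k-mer counts by
    L - k + 1 (off by default: raw counts).

    Attributes set by ``fit``: ``vocabulary_`` (sorted k-mer list, empty when
    the k-mer encoder is off) and ``feature_names_``.
    """

    def __init__(
        self,
        kmer_k: int | None = None,
        pseaac_lambda: int | None = None,
        pseaac_omega: float = 0.05,
        physchem: bool = False,
        kmer_normalize: bool = False,
        scales: AminoAcidScales | None = None,
        classes: Mapping[str, frozenset[str]] | None = None,
    ):
        self.kmer_k = kmer_k
        self.pseaac_lambda = pseaac_lambda
        self.pseaac_omega = pseaac_omega
        self.physchem = physchem
        self.kmer_normalize = kmer_normalize
        self.scales = scales
        self.classes = classes

    # -- sklearn plumbing ---------------------------------------------------
    _param_names = (
        "kmer_k",
        "pseaac_lambda",
        "pseaac_omega",
        "physchem",
        "kmer_normalize",
        "scales",
        "classes",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params) -> "SequenceFeaturizer":
        for key, value in params.items():
            if key not in self._param_names:
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -----------------------------------------------------------------------
    @property
    def spec(self) -> FeatureSpec:
        return FeatureSpec(
            kmer_k=self.kmer_k,
            pseaac_lambda=self.pseaac_lambda,
            pseaac_omega=self.pseaac_omega,
            physchem=self.physchem,
        )

    def fit(self, sequences: Iterable[SequenceRecord | str], y=None) -> "SequenceFeaturizer":
        self.spec  # validates the encoder combination
        vocab: set[str] = set()
        if self.kmer_k is not None:
            for seq in sequences:
                vocab.update(kmer_features(seq, self.kmer_k))
        self.vocabulary_ = sorted(vocab)
        self.feature_names_ = self._feature_names()
        return self

    def set_vocabulary(self, vocabulary: Sequence[str]) -> "SequenceFeaturizer":
        """Install a frozen vocabulary (e.g. from a serialized model)."""
        self.vocabulary_ = list(vocabulary)
        self.feature_names_ = self._feature_names()
        return self

    def _feature_names(self) -> list[str]:
        names = [f"kmer:{km}" for km in self.vocabulary_]
        if self.pseaac_lambda is not None:
            names += [f"pseaac:{aa}" for aa in AA_ALPHABET]
            names += [f"pseaac:theta{k}" for k in range(1, self.pseaac_lambda + 1)]
        if self.physchem:
            names += [f"physchem:{name}" for name in self._classes_map()]
        return names

    def _classes_map(self) -> Mapping[str, frozenset[str]]:
        return self.classes if self.classes is not None else _default_classes()

    def _scales_obj(self) -> AminoAcidScales:
        return self.scales if self.scales is not None else _default_scales()

    def transform(self, sequences: Iterable[SequenceRecord | str]) -> np.ndarray:
        if not hasattr(self, "vocabulary_"):
            raise RuntimeError("featurizer is not fitted")
        seqs = list(sequences)
        n_kmer = len(self.vocabulary_)
        rows = np.zeros((len(seqs), len(self.feature_names_)))
        kmer_index = {km: j for j, km in enumerate(self.vocabulary_)}
        for i, seq in enumerate(seqs):
            col = 0
            if self.kmer_k is not None:
                counts = kmer_features(seq, self.kmer_k)
                for km, c in counts.items():
                    j = kmer_index.get(km)
                    if j is not None:  # unseen k-mers are ignored
                        rows[i, j] = c
                if self.kmer_normalize:
                    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
                    rows[i, :n_kmer] /= len(s) - self.kmer_k + 1
                col = n_kmer
            if self.pseaac_lambda is not None:
                vec = pseaac_features(
                    seq, self.pseaac_lambda, self.pseaac_omega, self._scales_obj()
                )
                rows[i, col : col + len(vec)] = vec
                col += len(vec)
            if self.physchem:
                vec = physchem_features(seq, self._classes_map())
                rows[i, col : col + len(vec)] = vec
        return rows

    def fit_transform(self, sequences: Iterable[SequenceRecord | str], y=None) -> np.ndarray:
        seqs = list(sequences)
        return self.fit(seqs).transform(seqs)


@dataclass
class FeatureMatrix:
    """Encoded sequences: ordered feature names and one numeric row each."""

    vocabulary: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.vocabulary):
            raise ValueError("row width must equal the vocabulary size")


def encode(
    sequences: Sequence[SequenceRecord | str],
    spec: FeatureSpec,
    vocabulary: Sequence[str] | None = None,
    kmer_normalize: bool = False,
) -> FeatureMatrix:
    """Encode sequences under a feature spec.

    With ``vocabulary`` (prediction mode) the k-mer block is projected onto
    the given vocabulary; without it (training mode) the vocabulary is the
    sorted union over the input sequences.
    """
    fz = SequenceFeaturizer(
        kmer_k=spec.kmer_k,
        pseaac_lambda=spec.pseaac_lambda,
        pseaac_omega=spec.pseaac_omega,
        physchem=spec.physchem,
        kmer_normalize=kmer_normalize,
    )
    if vocabulary is not None:
        fz.set_vocabulary(vocabulary)
    else:
        fz.fit(sequences)
    return FeatureMatrix(fz.feature_names_, fz.transform(sequences))
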
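"""Assembly of per-transcript feature vectors into a FeatureTable.

The FeatureTable is the interchange object between extraction, selection
and modeling: an ids × feature-names matrix with optional class labels.
Three named feature sets are exposed:

* ``key3`` — ORF coverage, complex Fourier average, atomic Fourier
  amplitude: the production model's inputs;
* ``fourier`` — all spectral descriptors for all seven mappings;
* ``all-implemented`` — everything in the registry (ORF, k-mer, Fickett,
  Fourier, entropy families).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .auxfeatures import entropy_features, fickett_score, kmer_frequencies
from .fourier import DESCRIPTOR_NAMES, power_spectrum, spectral_descriptors
from .mappings import MAPPING_NAMES, map_sequence
from .orf import orf_features
from .seqio import LabeledDataset, SequenceRecord

FEATURE_SETS = ("key3", "fourier", "all-implemented")

KEY_FEATURES = ("orf_coverage", "complex_fourier_average", "atomic_fourier_amplitude")


@dataclass
class FeatureTable:
    """Sequences × named features, with optional aligned class labels."""

    X: pd.DataFrame  # index = sequence ids, columns = feature names
    y: pd.Series | None = None  # values in {lncRNA, mRNA}, index aligned to X

    def __post_init__(self) -> None:
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        if self.X.isna().any().any():
            bad = self.X.columns[self.X.isna().any()].tolist()
            raise ValueError(f"NaN values in features: {bad[:5]}")
        if self.y is not None:
            self.y = self.y.reindex(self.X.index)
            if self.y.isna().any():
                missing = self.y.index[self.y.isna()].tolist()
                raise ValueError(f"labels missing for ids: {missing[:5]}")

    @property
    def ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, names: Iterable[str]) -> "FeatureTable":
        names = list(names)
        missing = [n for n in names if n not in self.X.columns]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        return FeatureTable(self.X[names].copy(), None if self.y is None else self.y.copy())

    def to_csv(self, path: str | Path) -> None:
        out = self.X.copy()
        if self.y is not None:
            out["class"] = self.y
        out.to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="id")
        y = None
        if "class" in df.columns:
            y = df.pop("class")
        return cls(df, y)


def _fourier_vector(record: SequenceRecord) -> dict[str, float]:
    out: dict[str, float] = {}
    for m in MAPPING_NAMES:
        desc = spectral_descriptors(power_spectrum(map_sequence(record, m)))
        for d in DESCRIPTOR_NAMES:
            out[f"{m}_fourier_{d}"] = desc[d]
    return out


def feature_vector(record: SequenceRecord, feature_set: str = "key3") -> dict[str, float]:
    """Compute the named feature set for one transcript."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}; expected one of {FEATURE_SETS}")
    if feature_set == "key3":
        of = orf_features(record)
        cdesc = spectral_descriptors(power_spectrum(map_sequence(record, "complex")))
        adesc = spectral_descriptors(power_spectrum(map_sequence(record, "atomic")))
        return {
            "orf_coverage": of.orf_coverage,
            "complex_fourier_average": cdesc["average"],
            "atomic_fourier_amplitude": adesc["amplitude"],
        }
    if feature_set == "fourier":
        return _fourier_vector(record)
    # all-implemented
    of = orf_features(record)
    out: dict[str, float] = {
        "orf_coverage": of.orf_coverage,
        "orf_length_nt": float(of.orf_length_nt),
        "fickett_score": fickett_score(record),
    }
    out.update(kmer_frequencies(record, k_max=3))
    # "<mapping>_fourier_<stat>" naming already yields the two key names
    out.update(_fourier_vector(record))
    out.update(entropy_features(record))
    return out


def extract_features(
    dataset: LabeledDataset | Iterable[SequenceRecord],
    feature_set: str = "key3",
) -> FeatureTable:
    """Extract the named feature set for every record in a dataset."""
    if isinstance(dataset, LabeledDataset):
        records = dataset.records
        labels = dataset.labels or None
    else:
        records = list(dataset)
        labels = None
    rows = [feature_vector(r, feature_set) for r in records]
    ids = [r.id for r in records]
    X = pd.DataFrame(rows, index=pd.Index(ids, name="id"), dtype=float)
    y = None
    if labels:
        y = pd.Series({i: labels[i] for i in ids if i in labels}, name="class")
        if len(y) != len(ids):
            y = None if y.empty else y.reindex(ids)
            if y is not None and y.isna().any():
                raise ValueError("labels present but incomplete for the dataset")
    return FeatureTable(X, y)
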
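"""Numeric encodings of DNA sequences for Fourier analysis.

Seven mappings are supported. Five are per-base lookups (real, integer,
EIIP, complex-number, atomic-number), one is the four-channel Voss/binary
indicator, and one is the cumulative three-channel Z-curve walk. The
lookup constants live in ``data/encodings.json`` so they can be audited
or overridden without touching code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .seqio import SequenceRecord

MAPPING_NAMES = ("binary", "zcurve", "real", "integer", "eiip", "complex", "atomic")

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def load_encoding_tables(path: str | Path | None = None) -> dict:
    """Load the per-base encoding tables (package default or an override file)."""
    if path is None:
        text = resources.files("lncspect.data").joinpath("encodings.json").read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    tables: dict = {"version": raw.get("version", "unversioned")}
    for name in ("eiip", "atomic", "real", "integer"):
        tables[name] = {b: float(v) for b, v in raw[name].items()}
    tables["complex"] = {b: complex(re, im) for b, (re, im) in raw["complex"].items()}
    for name in ("eiip", "atomic", "real", "integer", "complex"):
        if set(tables[name]) != set(_BASES):
            raise ValueError(f"encoding table {name!r} must cover exactly A,C,G,T")
    return tables


_DEFAULT_TABLES = load_encoding_tables()


@dataclass(frozen=True)
class MappingProfile:
    """A sequence rendered numeric under one named mapping.

    ``channels`` has shape (n_channels, N): four indicator channels for
    binary, three cumulative coordinates for zcurve, one channel otherwise.
    """

    mapping: str
    channels: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if self.channels.ndim != 2 or self.channels.shape[1] != self.n:
            raise ValueError("channels must be (n_channels, N)")


def _lookup(seq: str, table: dict[str, complex | float]) -> np.ndarray:
    lut = np.array([table[b] for b in _BASES])
    idx = np.frombuffer(seq.encode(), dtype=np.uint8)
    # ASCII codes: A=65 C=67 G=71 T=84 → positions in _BASES
    pos = np.zeros(idx.shape, dtype=np.intp)
    pos[idx == ord("C")] = 1
    pos[idx == ord("G")] = 2
    pos[idx == ord("T")] = 3
    return lut[pos]


def map_sequence(
    record: SequenceRecord,
    mapping: str,
    tables: dict | None = None,
) -> MappingProfile:
    """Render *record* numeric under the named *mapping*."""
    if mapping not in MAPPING_NAMES:
        raise ValueError(f"unknown mapping {mapping!r}; expected one of {MAPPING_NAMES}")
    tables = tables or _DEFAULT_TABLES
    seq = record.seq
    n = record.length
    if mapping == "binary":
        channels = np.zeros((4, n))
        for i, base in enumerate(_BASES):
            channels[i] = np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)
        return MappingProfile("binary", channels, n)
    if mapping == "zcurve":
        ind = np.zeros((4, n))
        for i, base in enumerate(_BASES):
            ind[i] = np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)
        a, c, g, t = (np.cumsum(ind[i]) for i in range(4))
        x = (a + g) - (c + t)  # purine - pyrimidine
        y = (a + c) - (g + t)  # amino - keto
        z = (a + t) - (g + c)  # weak - strong
        return MappingProfile("zcurve", np.vstack([x, y, z]), n)
    series = _lookup(seq, tables[mapping])
    return MappingProfile(mapping, series[np.newaxis, :], n)


def profile_to_csv(profile: MappingProfile, path: str | Path) -> None:
    """Dump a mapping profile as CSV (one column per channel) for debugging."""
    import pandas as pd

    cols = {}
    for i, ch in enumerate(profile.channels):
        if np.iscomplexobj(ch):
            cols[f"ch{i}_re"] = ch.real
            cols[f"ch{i}_im"] = ch.imag
        else:
            cols[f"ch{i}"] = ch
    pd.DataFrame(cols).to_csv(path, index=False)
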
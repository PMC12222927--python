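"""Auxiliary sequence feature families: k-mers, Fickett TESTCODE, entropies.

These features are weaker discriminators than the ORF/spectral trio but
are required for the feature-selection study: the selection protocol has
to be able to *reject* them in favor of the key features.
"""

from __future__ import annotations

import json
from importlib import resources
from itertools import product

import numpy as np

from .seqio import SequenceRecord

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# k-mer frequencies


def kmer_frequencies(record: SequenceRecord, k_max: int = 3) -> dict[str, float]:
    """Overlapping k-mer frequencies for k = 1..k_max.

    Each k-mer count is divided by N − k + 1, so the 4^k frequencies for a
    given k sum to exactly 1. Feature names are ``kmer_<word>``.
    """
    if not 1 <= k_max <= 5:
        raise ValueError("k_max must be in 1..5")
    if record.length < k_max:
        raise ValueError(f"{record.id}: length {record.length} < k_max {k_max}")
    seq = record.seq
    out: dict[str, float] = {}
    for k in range(1, k_max + 1):
        total = record.length - k + 1
        counts = {"".join(w): 0 for w in product(_BASES, repeat=k)}
        for i in range(total):
            counts[seq[i : i + k]] += 1
        for word, c in counts.items():
            out[f"kmer_{word}"] = c / total
    return out


# ---------------------------------------------------------------------------
# Fickett TESTCODE


def _load_fickett() -> dict:
    text = resources.files("lncspect.data").joinpath("fickett.json").read_text()
    return json.loads(text)


_FICKETT = _load_fickett()


def _lookup_row(value: float, thresholds: list[float]) -> int:
    for i, t in enumerate(thresholds):
        if value >= t:
            return i
    return len(thresholds) - 1


def fickett_score(record: SequenceRecord) -> float:
    """Classic TESTCODE statistic of coding potential.

    For each base, the *position parameter* is max/(min+1) of its counts
    in the three codon positions, and the *content parameter* is its
    overall frequency; each is discretized through the published lookup
    tables and the eight resulting probabilities are combined with the
    published weights.
    """
    if record.length < 30:
        raise ValueError(f"{record.id}: Fickett score needs >= 30 nt")
    seq = record.seq
    score = 0.0
    n = record.length
    # positional counts: occurrences at codon positions i, i+3, i+6, ...
    for base in _BASES:
        counts = [sum(1 for j in range(i, n, 3) if seq[j] == base) for i in range(3)]
        position_param = max(counts) / (min(counts) + 1.0)
        content_param = sum(counts) / n
        prow = _lookup_row(position_param, _FICKETT["position_thresholds"])
        crow = _lookup_row(content_param, _FICKETT["content_thresholds"])
        score += _FICKETT["position_prob"][base][prow] * _FICKETT["position_weight"][base]
        score += _FICKETT["content_prob"][base][crow] * _FICKETT["content_weight"][base]
    return score


def fickett_score_bounds() -> tuple[float, float]:
    """(min, max) achievable TESTCODE score, from the tables alone."""
    lo = hi = 0.0
    for base in _BASES:
        pw = _FICKETT["position_weight"][base]
        cw = _FICKETT["content_weight"][base]
        lo += min(_FICKETT["position_prob"][base]) * pw + min(_FICKETT["content_prob"][base]) * cw
        hi += max(_FICKETT["position_prob"][base]) * pw + max(_FICKETT["content_prob"][base]) * cw
    return lo, hi


# ---------------------------------------------------------------------------
# Entropy features

#: Registry default: Shannon for k=1..10 and Tsallis for k=1..9 (q=2),
#: 19 entropy features in total.
SHANNON_K = tuple(range(1, 11))
TSALLIS_K = tuple(range(1, 10))
DEFAULT_TSALLIS_Q = 2.0


def _kmer_distribution(seq: str, k: int) -> np.ndarray:
    total = len(seq) - k + 1
    counts: dict[str, int] = {}
    for i in range(total):
        w = seq[i : i + k]
        counts[w] = counts.get(w, 0) + 1
    return np.array(list(counts.values()), dtype=float) / total


def shannon_entropy(record: SequenceRecord, k: int) -> float:
    """Shannon entropy (bits) of the observed k-mer distribution."""
    if k < 1 or record.length < k:
        raise ValueError(f"{record.id}: invalid k={k} for length {record.length}")
    p = _kmer_distribution(record.seq, k)
    return float(-np.sum(p * np.log2(p)))


def tsallis_entropy(record: SequenceRecord, k: int, q: float = DEFAULT_TSALLIS_Q) -> float:
    """Tsallis entropy S_q = (1 − Σ p^q)/(q − 1) of the k-mer distribution."""
    if q <= 0 or q == 1.0:
        raise ValueError("q must be positive and != 1")
    if k < 1 or record.length < k:
        raise ValueError(f"{record.id}: invalid k={k} for length {record.length}")
    p = _kmer_distribution(record.seq, k)
    return float((1.0 - np.sum(p**q)) / (q - 1.0))


def entropy_features(
    record: SequenceRecord,
    shannon_k: tuple[int, ...] = SHANNON_K,
    tsallis_k: tuple[int, ...] = TSALLIS_K,
    q: float = DEFAULT_TSALLIS_Q,
) -> dict[str, float]:
    out = {f"shannon_k{k}": shannon_entropy(record, k) for k in shannon_k}
    out.update({f"tsallis_k{k}": tsallis_entropy(record, k, q) for k in tsallis_k})
    return out


# ---------------------------------------------------------------------------
# Feature registry

def feature_registry(k_max: int = 3) -> list[dict[str, str]]:
    """Machine-readable manifest of every implemented feature.

    Families deliberately not implemented (complex-network descriptors)
    are absent from the registry rather than stubbed.
    """
    from .fourier import DESCRIPTOR_NAMES
    from .mappings import MAPPING_NAMES

    rows: list[dict[str, str]] = [
        {"name": "orf_coverage", "family": "orf", "params": "forward,stop-required"},
        {"name": "orf_length_nt", "family": "orf", "params": "forward,stop-required"},
        {"name": "fickett_score", "family": "fickett", "params": "testcode-1982"},
    ]
    for k in range(1, k_max + 1):
        for w in product(_BASES, repeat=k):
            rows.append({"name": f"kmer_{''.join(w)}", "family": "kmer", "params": f"k={k}"})
    for m in MAPPING_NAMES:
        for d in DESCRIPTOR_NAMES:
            if d == "none_levated":
                continue  # reconstruction of an underdocumented statistic; not registered
            rows.append({"name": f"{m}_fourier_{d}", "family": "fourier", "params": "exclude_dc"})
    for k in SHANNON_K:
        rows.append({"name": f"shannon_k{k}", "family": "entropy", "params": f"k={k}"})
    for k in TSALLIS_K:
        rows.append(
            {"name": f"tsallis_k{k}", "family": "entropy", "params": f"k={k},q={DEFAULT_TSALLIS_Q}"}
        )
    return rows
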
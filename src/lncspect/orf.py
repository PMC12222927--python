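"""Open-reading-frame detection and ORF-derived features.

Two configurations matter in practice and are kept strictly separate:

* the *feature* configuration (forward strand, three frames, ATG start,
  stop required, fall back to the longest ATG-to-end open span when no
  complete ORF exists) used to compute ORF coverage, the strongest single
  discriminator between mRNAs and lncRNAs; and
* an *NCBI-style scan* (both strands, minimum 75 nt) matching the
  defaults of the current NCBI ORF Finder, for auditing individual
  transcripts whose coding status is in question.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from .seqio import SequenceRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: NCBI ORF Finder default minimum ORF length (nt, including stop codon).
NCBI_MIN_ORF_NT = 75


@dataclass(frozen=True)
class OrfAnnotation:
    """A maximal ATG→stop span, in transcript coordinates (0-based, half-open).

    ``start``/``end`` always refer to the forward strand of the input
    transcript; for ``strand == '-'`` the ORF reads right-to-left on the
    reverse complement. ``complete`` is False only for ATG-to-sequence-end
    open spans admitted when no stop codon follows.
    """

    start: int
    end: int
    frame: int
    strand: Literal["+", "-"]
    complete: bool

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _scan_strand(seq: str, min_orf_nt: int, require_stop: bool) -> list[tuple[int, int, int, bool]]:
    """Maximal ATG→stop spans per frame: (start, end, frame, complete).

    Within a frame, only the first ATG after the previous stop opens an
    ORF (maximal spans; nested internal ATGs are suppressed).
    """
    n = len(seq)
    out: list[tuple[int, int, int, bool]] = []
    for frame in range(3):
        start: int | None = None
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == START_CODON:
                    start = pos
            elif codon in STOP_CODONS:
                length = pos + 3 - start
                if length >= min_orf_nt:
                    out.append((start, pos + 3, frame, True))
                start = None
            pos += 3
        if start is not None and not require_stop:
            end = start + ((n - start) // 3) * 3
            if end - start >= min_orf_nt:
                out.append((start, end, frame, False))
    return out


def find_orfs(
    record: SequenceRecord,
    min_orf_nt: int = 6,
    both_strands: bool = False,
    require_stop: bool = True,
) -> list[OrfAnnotation]:
    """All maximal ORFs of length >= *min_orf_nt*, longest first.

    Ties are broken by strand ('+' before '-'), then smaller start.
    Coordinates are on the forward strand of the transcript.
    """
    if min_orf_nt < 6 or min_orf_nt % 3 != 0:
        raise ValueError("min_orf_nt must be a multiple of 3 and >= 6")
    n = record.length
    orfs = [
        OrfAnnotation(s, e, f, "+", c)
        for s, e, f, c in _scan_strand(record.seq, min_orf_nt, require_stop)
    ]
    if both_strands:
        rc = reverse_complement(record.seq)
        for s, e, f, c in _scan_strand(rc, min_orf_nt, require_stop):
            # map back to forward coordinates
            orfs.append(OrfAnnotation(n - e, n - s, f, "-", c))
    orfs.sort(key=lambda o: (-o.length_nt, o.strand != "+", o.start))
    return orfs


@dataclass(frozen=True)
class OrfFeatures:
    """ORF-derived feature values for one transcript."""

    orf_length_nt: int
    orf_coverage: float
    longest_orf_aa: int
    n_orfs: int


def orf_features(record: SequenceRecord, min_orf_nt: int = 6) -> OrfFeatures:
    """ORF coverage and companions under the feature convention.

    Forward strand only, stop required; when no complete ORF exists the
    longest ATG-to-end open span stands in, so transcripts with a
    truncated reading frame score a small but non-zero coverage rather
    than an artificial zero.
    """
    complete = find_orfs(record, min_orf_nt=min_orf_nt, both_strands=False, require_stop=True)
    if complete:
        best = complete[0]
        aa = best.length_nt // 3 - 1
        n = len(complete)
    else:
        open_spans = [
            o
            for o in find_orfs(
                record, min_orf_nt=min_orf_nt, both_strands=False, require_stop=False
            )
            if not o.complete
        ]
        if open_spans:
            best = open_spans[0]
            aa = 0
            n = 0
        else:
            return OrfFeatures(0, 0.0, 0, 0)
    return OrfFeatures(best.length_nt, best.length_nt / record.length, aa, n)


def ncbi_style_scan(record: SequenceRecord, min_orf_nt: int = NCBI_MIN_ORF_NT) -> list[OrfAnnotation]:
    """Both-strand maximal-ORF scan with NCBI ORF Finder default minimum."""
    return find_orfs(record, min_orf_nt=min_orf_nt, both_strands=True, require_stop=True)


def write_orf_report(orfs: Iterable[OrfAnnotation], record_id: str, path: str | Path) -> None:
    """BED-like TSV (0-based half-open) of ORF annotations."""
    with open(path, "w") as fh:
        fh.write("id\tstart\tend\tstrand\tframe\tlength_nt\tcomplete\n")
        for o in orfs:
            fh.write(
                f"{record_id}\t{o.start}\t{o.end}\t{o.strand}\t{o.frame}"
                f"\t{o.length_nt}\t{str(o.complete).lower()}\n"
            )
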
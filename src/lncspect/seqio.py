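"""FASTA and label input/output with transcript-cleanliness rules.

Transcripts enter the pipeline as plain DNA strings over {A, C, G, T}.
RNA-alphabet input (U) is transparently converted to T; any other
non-ACGT character (N and IUPAC ambiguity codes) disqualifies the record
under the default ``skip`` policy, which mirrors the curation rule that
ambiguous sequences are discarded before feature extraction.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
VALID_CLASSES = ("lncRNA", "mRNA")

#: Floor below which the feature extractors are not all well defined.
DEFAULT_MIN_LENGTH = 30

#: Canonical lncRNA length convention; not enforced, only warned about.
LNCRNA_LENGTH_CONVENTION = 200


@dataclass(frozen=True)
class SequenceRecord:
    """One validated transcript: unique id and an uppercase ACGT string."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"{self.id}: invalid characters {sorted(bad)}; "
                "sequences must be uppercase ACGT"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class LabeledDataset:
    """Validated transcripts plus optional class labels and a skip log."""

    records: list[SequenceRecord]
    labels: dict[str, str] = field(default_factory=dict)
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = {r.id for r in self.records}
        orphan = set(self.labels) - ids
        if orphan:
            raise ValueError(f"labels without records: {sorted(orphan)[:5]}")
        overlap = ids & {sid for sid, _ in self.skipped}
        if overlap:
            raise ValueError(f"records both kept and skipped: {sorted(overlap)[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def _clean(raw: str) -> str:
    """Uppercase and convert RNA alphabet (U) to DNA (T)."""
    return raw.upper().replace("U", "T")


def read_fasta(
    path: str | Path,
    min_length: int = DEFAULT_MIN_LENGTH,
    on_ambiguous: Literal["skip", "error"] = "skip",
    labels: dict[str, str] | None = None,
) -> LabeledDataset:
    """Read a FASTA file into a :class:`LabeledDataset`.

    Records containing characters outside ACGT (after U→T conversion) are
    skipped with reason ``ambiguous`` or raise, per *on_ambiguous*.
    Records shorter than *min_length* are skipped with reason ``too_short``.
    Duplicate ids are an error.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    path = Path(path)
    records: list[SequenceRecord] = []
    skipped: list[tuple[str, str]] = []
    seen: set[str] = set()
    n_parsed = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        n_parsed += 1
        sid = entry.id
        if sid in seen:
            raise ValueError(f"duplicate sequence id: {sid}")
        seen.add(sid)
        seq = _clean(str(entry.seq))
        bad = set(seq) - VALID_BASES
        if bad:
            if on_ambiguous == "error":
                raise ValueError(f"{sid}: ambiguous characters {sorted(bad)}")
            skipped.append((sid, "ambiguous"))
            continue
        if len(seq) < min_length:
            skipped.append((sid, "too_short"))
            continue
        records.append(SequenceRecord(sid, seq))
    if n_parsed == 0:
        raise ValueError(f"{path}: empty or unreadable FASTA")
    if skipped:
        logger.info(
            "%s: skipped %d/%d records (%s)",
            path.name,
            len(skipped),
            n_parsed,
            ", ".join(sorted({r for _, r in skipped})),
        )
    kept_labels: dict[str, str] = {}
    if labels:
        kept = {r.id for r in records}
        kept_labels = {k: v for k, v in labels.items() if k in kept}
        for sid, cls in kept_labels.items():
            if cls == "lncRNA":
                rec = next(r for r in records if r.id == sid)
                if rec.length < LNCRNA_LENGTH_CONVENTION:
                    logger.warning(
                        "%s labeled lncRNA but only %d nt (< %d nt convention)",
                        sid,
                        rec.length,
                        LNCRNA_LENGTH_CONVENTION,
                    )
    return LabeledDataset(records=records, labels=kept_labels, skipped=skipped)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as multi-line FASTA."""
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read an ``id,class`` CSV into a normalized class map.

    Class tokens are matched case-insensitively against {lncRNA, mRNA}.
    A header row ``id,class`` is tolerated and ignored.
    """
    canon = {c.lower(): c for c in VALID_CLASSES}
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"line {i + 1}: expected 'id,class', got {row!r}")
            sid, cls = row[0].strip(), row[1].strip()
            if i == 0 and sid.lower() == "id" and cls.lower() == "class":
                continue
            norm = canon.get(cls.lower())
            if norm is None:
                raise ValueError(
                    f"line {i + 1}: unknown class {cls!r}; expected one of {VALID_CLASSES}"
                )
            if sid in out:
                raise ValueError(f"duplicate label for id {sid!r}")
            out[sid] = norm
    return out


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "class"])
        for sid, cls in labels.items():
            w.writerow([sid, cls])


def write_skipped_report(skipped: list[tuple[str, str]], path: str | Path) -> None:
    """Write the skip log as a two-column TSV (id, reason)."""
    with open(path, "w") as fh:
        fh.write("id\treason\n")
        for sid, reason in skipped:
            fh.write(f"{sid}\t{reason}\n")
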
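"""Reading, canonicalizing, QC-filtering and codon-counting of CDS FASTA.

The QC model mirrors common practice for transcriptome-derived CDS
collections: sequences shorter than 300 nt are always removed (they
carry too little codon signal and inflate sampling error), while
non-triplet lengths and internal stop codons — both plausible artifacts
of automated ORF reconstruction — are tallied and only removed on
request.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .genetic_code import ALL_CODONS, STOP_CODONS

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 300

_CANON = str.maketrans("uU", "tT")


class QcFlag(str, Enum):
    """Per-record quality flags; a record may carry several."""

    TOO_SHORT = "TOO_SHORT"
    NOT_TRIPLET = "NOT_TRIPLET"
    HAS_AMBIGUITY = "HAS_AMBIGUITY"
    INTERNAL_STOP = "INTERNAL_STOP"


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence, canonicalized to uppercase DNA.

    ``seq`` is the sequence as given (frame 0 is taken as the reading
    frame; no ORF re-detection is attempted). ``qc_flags`` is computed
    against a minimum-length threshold at construction time.
    """

    id: str
    seq: str
    description: str = ""
    qc_flags: frozenset[QcFlag] = field(default_factory=frozenset)

    @property
    def length_nt(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CodonCounts:
    """A 64-cell codon count vector for one gene or a pooled gene set.

    ``n_codons`` equals the sum of ``counts``; triplets containing a
    non-ACGT character are skipped (not counted) and tallied in
    ``n_skipped``. Addition pools cell-wise and concatenates
    ``source_ids``.
    """

    counts: Mapping[str, int]
    source_ids: tuple[str, ...] = ()
    n_skipped: int = 0

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return CodonCounts(
            counts=dict(merged),
            source_ids=self.source_ids + other.source_ids,
            n_skipped=self.n_skipped + other.n_skipped,
        )

    def get(self, codon: str) -> int:
        return self.counts.get(codon, 0)


def canonicalize(seq: str) -> str:
    """Uppercase and map U->T; other characters pass through unchanged."""
    return seq.translate(_CANON).upper()


def _compute_flags(seq: str, min_len: int) -> frozenset[QcFlag]:
    flags: set[QcFlag] = set()
    if len(seq) < min_len:
        flags.add(QcFlag.TOO_SHORT)
    if len(seq) % 3 != 0:
        flags.add(QcFlag.NOT_TRIPLET)
    if any(ch not in "ACGT" for ch in seq):
        flags.add(QcFlag.HAS_AMBIGUITY)
    # internal = any full triplet before the last full one
    n_full = len(seq) // 3
    for i in range(max(n_full - 1, 0)):
        if seq[3 * i : 3 * i + 3] in STOP_CODONS:
            flags.add(QcFlag.INTERNAL_STOP)
            break
    return frozenset(flags)


def make_record(
    id: str, seq: str, description: str = "", min_len: int = DEFAULT_MIN_LEN
) -> CdsRecord:
    """Canonicalize ``seq`` and build a flagged :class:`CdsRecord`."""
    canon = canonicalize(seq)
    return CdsRecord(
        id=id,
        seq=canon,
        description=description,
        qc_flags=_compute_flags(canon, min_len),
    )


def read_cds_fasta(
    path: str | Path, min_len: int = DEFAULT_MIN_LEN
) -> list[CdsRecord]:
    """Read a (possibly gzipped) multi-FASTA of CDS into records.

    Records are returned in file order; the id is the header token up to
    the first whitespace, the remainder is kept as ``description``.
    An empty file yields an empty list with a logged warning; sequence
    data before the first header is a hard error.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        first = handle.readline()
        while first and not first.strip():
            first = handle.readline()
        if not first:
            logger.warning("FASTA file %s is empty", path)
            return []
        if not first.startswith(">"):
            raise ValueError(
                f"malformed FASTA {path}: sequence data before first "
                f"header at line 1: {first.strip()[:40]!r}"
            )
        handle.seek(0)
        records = [
            make_record(
                id=rec.id,
                seq=str(rec.seq),
                description=rec.description[len(rec.id) :].strip(),
                min_len=min_len,
            )
            for rec in SeqIO.parse(handle, "fasta")
        ]
    return records


def write_cds_fasta(records: Iterable[CdsRecord], path: str | Path) -> None:
    """Write records as 60-column-wrapped FASTA."""
    path = Path(path)
    with open(path, "w") as out:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            out.write(f">{header}\n")
            for i in range(0, len(rec.seq), 60):
                out.write(rec.seq[i : i + 60] + "\n")


def qc_filter(
    records: Sequence[CdsRecord],
    min_len: int = DEFAULT_MIN_LEN,
    drop_not_triplet: bool = False,
    drop_internal_stop: bool = False,
) -> tuple[list[CdsRecord], dict[str, int]]:
    """Apply QC filters; return kept records and per-flag counts.

    Records shorter than ``min_len`` are always dropped. Non-triplet and
    internal-stop records are dropped only when the corresponding switch
    is on. The report tallies every flag independently over the input
    (a record can carry several flags).
    """
    if min_len <= 0:
        raise ValueError(f"min_len must be positive, got {min_len}")
    report: dict[str, int] = {flag.value: 0 for flag in QcFlag}
    kept: list[CdsRecord] = []
    for rec in records:
        flags = _compute_flags(rec.seq, min_len)
        if flags != rec.qc_flags:
            rec = replace(rec, qc_flags=flags)
        for flag in flags:
            report[flag.value] += 1
        drop = QcFlag.TOO_SHORT in flags
        drop |= drop_not_triplet and QcFlag.NOT_TRIPLET in flags
        drop |= drop_internal_stop and QcFlag.INTERNAL_STOP in flags
        if not drop:
            kept.append(rec)
    return kept, report


def write_qc_report(report: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("flag\tcount\n")
        for flag, count in report.items():
            out.write(f"{flag}\t{count}\n")


def count_codons(record: CdsRecord) -> CodonCounts:
    """Count consecutive non-overlapping triplets from position 0.

    A trailing 1-2 nt remainder is discarded; any triplet containing a
    non-ACGT character is skipped and tallied in ``n_skipped``. The
    terminal stop codon, if present, is counted here (index computations
    exclude stops downstream).
    """
    counts: Counter[str] = Counter()
    skipped = 0
    seq = record.seq
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if codon in _VALID_CODONS:
            counts[codon] += 1
        else:
            skipped += 1
    return CodonCounts(
        counts=dict(counts), source_ids=(record.id,), n_skipped=skipped
    )


_VALID_CODONS = frozenset(ALL_CODONS)


def pool_counts(counts: Iterable[CodonCounts]) -> CodonCounts:
    """Cell-wise sum of codon counts over a gene set."""
    total = CodonCounts(counts={})
    for c in counts:
        total = total + c
    return total
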
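"""Read quality control: end-trimming and whole-read quality filtering.

The QC contract applied before any mapping:

* terminal bases with phred <= ``qual_floor`` (default 15) are removed from
  both ends, inward, until a base above the floor is met; interior
  low-quality bases are retained;
* a trimmed read is kept only if it is strictly longer than ``min_len``
  (default 30 bp) and at least ``min_frac`` (default 80%) of its bases have
  phred >= ``qual_floor``. ``N`` bases count as failing the floor whatever
  their score.

Both thresholds are deliberately asymmetric (trim removes ``<= 15``, the
overall filter requires ``>= 15``): trimming strips bases that are at or
below the floor while the bulk-quality rule credits bases at the floor.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence

import numpy as np

PHRED_OFFSET = 33


class FastqParseError(ValueError):
    """Raised for malformed FASTQ records (length mismatch etc.)."""


@dataclass(slots=True)
class Read:
    """A sequencing read: id, bases (ACGTN string) and per-base phred scores."""

    id: str
    bases: str
    quals: np.ndarray  # int array, same length as bases

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != len(self.quals):
            raise FastqParseError(
                f"record {self.id!r}: sequence length {len(self.bases)} != "
                f"quality length {len(self.quals)}"
            )
        if len(self.quals) and self.quals.min() < 0:
            raise FastqParseError(f"record {self.id!r}: negative phred score")

    def __len__(self) -> int:
        return len(self.bases)


# A trimmed-and-kept read is plain `Read`; the alias documents intent at API
# boundaries (mapping and pileup consume CleanRead only).
CleanRead = Read


def trim_read(read: Read, qual_floor: int = 15) -> Optional[Read]:
    """Trim low-quality ends; return the trimmed read or None if nothing survives.

    Bases with phred <= ``qual_floor`` are removed from both ends inward until
    the terminal base at each end exceeds the floor. Interior low-quality
    bases are never touched; base calls are never altered.
    """
    q = read.quals
    keep = np.flatnonzero(q > qual_floor)
    if keep.size == 0:
        return None
    lo, hi = int(keep[0]), int(keep[-1]) + 1
    if lo == 0 and hi == len(q):
        return read
    return Read(read.id, read.bases[lo:hi], q[lo:hi])


def filter_read(
    read: Read,
    min_len: int = 30,
    min_frac: float = 0.8,
    qual_floor: int = 15,
) -> bool:
    """Keep a trimmed read iff length > min_len and >= min_frac of bases pass the floor.

    A base passes the floor when its phred is >= ``qual_floor`` and it is not
    an ``N`` call.
    """
    n = len(read)
    if n <= min_len:
        return False
    good = read.quals >= qual_floor
    if "N" in read.bases:
        good &= np.frombuffer(read.bases.encode("ascii"), dtype=np.uint8) != ord("N")
    return int(good.sum()) / n >= min_frac


def clean_reads(
    reads: Iterable[Read],
    min_len: int = 30,
    min_frac: float = 0.8,
    qual_floor: int = 15,
) -> tuple[List[Read], "QCReport"]:
    """Trim then filter a read set; returns (kept reads, QC summary)."""
    n_raw = n_kept = 0
    bases_raw = bases_kept = 0
    kept: List[Read] = []
    for read in reads:
        n_raw += 1
        bases_raw += len(read)
        trimmed = trim_read(read, qual_floor=qual_floor)
        if trimmed is None:
            continue
        if filter_read(trimmed, min_len=min_len, min_frac=min_frac, qual_floor=qual_floor):
            kept.append(trimmed)
            n_kept += 1
            bases_kept += len(trimmed)
    return kept, QCReport(
        n_raw=n_raw,
        n_kept=n_kept,
        bases_raw=bases_raw,
        bases_kept=bases_kept,
    )


@dataclass(slots=True)
class QCReport:
    n_raw: int
    n_kept: int
    bases_raw: int
    bases_kept: int

    @property
    def retained_fraction(self) -> float:
        return self.n_kept / self.n_raw if self.n_raw else float("nan")

    @property
    def mean_length_before(self) -> float:
        return self.bases_raw / self.n_raw if self.n_raw else float("nan")

    @property
    def mean_length_after(self) -> float:
        return self.bases_kept / self.n_kept if self.n_kept else float("nan")

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            ("reads_in", self.n_raw),
            ("reads_kept", self.n_kept),
            ("retained_fraction", f"{self.retained_fraction:.6f}"),
            ("bases_in", self.bases_raw),
            ("bases_kept", self.bases_kept),
            ("mean_length_before", f"{self.mean_length_before:.3f}"),
            ("mean_length_after", f"{self.mean_length_after:.3f}"),
        ]
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for k, v in rows:
                fh.write(f"{k}\t{v}\n")


def qc_report(raw: Sequence[Read], clean: Sequence[Read]) -> QCReport:
    """Retained-read/-base summary for an already-cleaned read set."""
    return QCReport(
        n_raw=len(raw),
        n_kept=len(clean),
        bases_raw=sum(len(r) for r in raw),
        bases_kept=sum(len(r) for r in clean),
    )


def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path, phred_offset: int = PHRED_OFFSET) -> Iterator[Read]:
    """Stream a (optionally gzipped) FASTQ file as Read objects."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_text(path) as fh:
        for title, bases, qual in FastqGeneralIterator(fh):
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16)
            quals -= phred_offset
            yield Read(title.split()[0], bases.upper(), quals)


def write_fastq(path: str | Path, reads: Iterable[Read], phred_offset: int = PHRED_OFFSET) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = (r.quals.astype(np.uint8) + phred_offset).tobytes().decode("ascii")
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")
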
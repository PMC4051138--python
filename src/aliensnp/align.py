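"""Ungapped k-mismatch read mapping against one reference at a time.

The mapping contract mirrors a classic short-read mapper run in
mismatch-only mode with a single best placement: each read is placed
end-to-end, without gaps, on either strand; the unique placement with the
fewest mismatches is reported if that minimum is <= ``max_mismatch``
(default 3). Reads whose best score is tied between two or more placements
are reported unmapped as ambiguous (the conservative choice for variant
calling; a seeded random-best mode reproduces report-one behaviour).

Completeness is guaranteed by pigeonhole seeding: a read is split into
``max_mismatch + 1`` disjoint chunks, so any placement with at most
``max_mismatch`` mismatches matches at least one chunk exactly; the index
is queried with a fixed-length prefix of each chunk and every candidate
offset is verified by full comparison. Reads too short for the seed length
fall back to exhaustive scanning. ``N`` in read or reference always counts
as a mismatch.

All contigs of one reference FASTA form a single search space; uniqueness
of the best placement is judged across contigs and strands together.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .dna import revcomp, seq_to_codes
from .reads import Read

N_BYTE = 4  # code for N in seq_to_codes output

UNMAPPED_NO_HIT = "no_hit"
UNMAPPED_AMBIGUOUS = "ambiguous"
UNMAPPED_TOO_LONG = "read_longer_than_reference"


@dataclass(slots=True)
class ReadAlignment:
    read_id: str
    ref_id: str
    start: int  # 0-based on the forward reference strand
    strand: str  # '+' or '-'
    n_mismatch: int
    sequence_length: int

    def key(self) -> tuple:
        return (self.read_id, self.ref_id, self.start, self.strand,
                self.n_mismatch, self.sequence_length)


@dataclass(slots=True)
class CoverageSummary:
    ref_id: str
    mapped_read_count: int
    covered_bases: int
    reference_length: int

    @property
    def covered_fraction(self) -> float:
        return self.covered_bases / self.reference_length if self.reference_length else 0.0


class ReferenceIndex:
    """Seed index over all contigs of one reference (fixed-length exact seeds)."""

    def __init__(self, reference: Dict[str, str], seed_len: int = 16):
        self.reference = reference
        self.seed_len = seed_len
        self.codes: Dict[str, np.ndarray] = {
            name: seq_to_codes(seq) for name, seq in reference.items()
        }
        self.max_contig = max((len(s) for s in reference.values()), default=0)
        index: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
        k = seed_len
        for name, seq in reference.items():
            for i in range(len(seq) - k + 1):
                index[seq[i:i + k]].append((name, i))
        self._index = dict(index)

    def seed_hits(self, seed: str) -> Sequence[Tuple[str, int]]:
        return self._index.get(seed, ())


def _count_mismatches(ref_codes: np.ndarray, read_codes: np.ndarray, start: int) -> int:
    window = ref_codes[start:start + read_codes.size]
    return int(np.count_nonzero((window != read_codes)
                                | (window == N_BYTE) | (read_codes == N_BYTE)))


def _candidate_placements(index: ReferenceIndex, bases: str,
                          max_mismatch: int) -> set[Tuple[str, int]]:
    """Candidate (contig, start) offsets for one read orientation."""
    L = len(bases)
    k = index.seed_len
    n_chunks = max_mismatch + 1
    candidates: set[Tuple[str, int]] = set()
    if L // n_chunks >= k:
        bounds = [L * i // n_chunks for i in range(n_chunks)]
        for c0 in bounds:
            for contig, pos in index.seed_hits(bases[c0:c0 + k]):
                start = pos - c0
                if 0 <= start <= len(index.reference[contig]) - L:
                    candidates.add((contig, start))
    else:
        # short-read fallback: every feasible offset on every contig
        for contig, seq in index.reference.items():
            for start in range(len(seq) - L + 1):
                candidates.add((contig, start))
    return candidates


def map_read(read: Read, index: ReferenceIndex, max_mismatch: int = 3,
             rng: Optional[np.random.Generator] = None
             ) -> Tuple[Optional[ReadAlignment], Optional[str]]:
    """Map one read; returns (alignment, None) or (None, unmapped reason)."""
    L = len(read)
    if L > index.max_contig:
        return None, UNMAPPED_TOO_LONG
    best: List[Tuple[str, int, str]] = []
    best_mm = max_mismatch + 1
    for strand, bases in (("+", read.bases), ("-", revcomp(read.bases))):
        read_codes = seq_to_codes(bases)
        for contig, start in _candidate_placements(index, bases, max_mismatch):
            mm = _count_mismatches(index.codes[contig], read_codes, start)
            if mm < best_mm:
                best_mm = mm
                best = [(contig, start, strand)]
            elif mm == best_mm:
                best.append((contig, start, strand))
    if best_mm > max_mismatch or not best:
        return None, UNMAPPED_NO_HIT
    if len(set(best)) > 1:
        if rng is None:
            return None, UNMAPPED_AMBIGUOUS
        contig, start, strand = best[int(rng.integers(len(best)))]
    else:
        contig, start, strand = best[0]
    return ReadAlignment(read.id, contig, start, strand, best_mm, L), None


def map_reads(reads: Iterable[Read], reference: Dict[str, str],
              max_mismatch: int = 3, drop_ties: bool = True,
              seed: int = 0, index: Optional[ReferenceIndex] = None,
              ) -> Tuple[List[ReadAlignment], Dict[str, str]]:
    """Map a read set; returns (alignments, {read id: unmapped reason}).

    With ``drop_ties`` (default) ambiguous-best reads are left unmapped;
    otherwise one of the tied placements is chosen with the seeded RNG.
    """
    if index is None:
        index = ReferenceIndex(reference)
    rng = None if drop_ties else np.random.default_rng([seed, 3])
    alignments: List[ReadAlignment] = []
    unmapped: Dict[str, str] = {}
    for read in reads:
        aln, reason = map_read(read, index, max_mismatch=max_mismatch, rng=rng)
        if aln is not None:
            alignments.append(aln)
        else:
            unmapped[read.id] = reason or UNMAPPED_NO_HIT
    return alignments, unmapped


def coverage_summary(alignments: Sequence[ReadAlignment], reference: Dict[str, str],
                     label: str = "reference") -> CoverageSummary:
    """Mapped-read count and covered-base count aggregated over all contigs."""
    depth_events: Dict[str, np.ndarray] = {
        name: np.zeros(len(seq) + 1, dtype=np.int32) for name, seq in reference.items()
    }
    for aln in alignments:
        ev = depth_events[aln.ref_id]
        ev[aln.start] += 1
        ev[aln.start + aln.sequence_length] -= 1
    covered = 0
    for name in reference:
        depth = np.cumsum(depth_events[name][:-1])
        covered += int(np.count_nonzero(depth))
    return CoverageSummary(
        ref_id=label,
        mapped_read_count=len(alignments),
        covered_bases=covered,
        reference_length=sum(len(s) for s in reference.values()),
    )


# ---------------------------------------------------------------------------
# SAM import/export

def export_sam(path: str | Path, alignments: Sequence[ReadAlignment],
               reads_by_id: Dict[str, Read], reference: Dict[str, str]) -> None:
    """Write alignments as plain SAM (ungapped: CIGAR <len>M, NM tag emitted).

    SEQ/QUAL follow SAM convention: reported on the forward reference
    strand, so reverse-strand reads are stored reverse-complemented with
    FLAG 16.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in reference.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for aln in alignments:
            read = reads_by_id[aln.read_id]
            bases, quals = read.bases, read.quals
            flag = 0
            if aln.strand == "-":
                flag = 16
                bases = revcomp(bases)
                quals = quals[::-1]
            qual = (quals.astype(np.uint8) + 33).tobytes().decode("ascii")
            fh.write(
                f"{aln.read_id}\t{flag}\t{aln.ref_id}\t{aln.start + 1}\t255\t"
                f"{aln.sequence_length}M\t*\t0\t0\t{bases}\t{qual}\tNM:i:{aln.n_mismatch}\n"
            )


def import_sam(path: str | Path, reference: Dict[str, str], max_mismatch: int = 3,
               ) -> Tuple[List[ReadAlignment], Dict[str, Read], int]:
    """Normalize a SAM file to ReadAlignment records.

    Unmapped, secondary and supplementary records are skipped; alignments
    with more than ``max_mismatch`` mismatches are dropped (their count is
    returned). Mismatch counts come from the NM tag when present, otherwise
    they are recomputed against the reference. Reads are returned keyed by
    id with bases on the original read strand.

    Raises ValueError when the SAM names reference sequences absent from the
    supplied FASTA.
    """
    alignments: List[ReadAlignment] = []
    reads_by_id: Dict[str, Read] = {}
    n_dropped = 0
    ref_codes = {name: seq_to_codes(seq) for name, seq in reference.items()}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        sam_refs = list(sam.references)
        unknown = sorted(set(sam_refs) - set(reference))
        if unknown:
            raise ValueError(
                f"SAM references not present in the supplied FASTA: {', '.join(unknown)}"
            )
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            seq = (rec.query_sequence or "").upper()
            quals = np.asarray(rec.query_qualities if rec.query_qualities is not None
                               else [0] * len(seq), dtype=np.int16)
            contig = rec.reference_name
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            else:
                nm = _count_mismatches(ref_codes[contig], seq_to_codes(seq),
                                       rec.reference_start)
            if nm > max_mismatch:
                n_dropped += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            bases, q = seq, quals
            if strand == "-":
                bases = revcomp(bases)
                q = q[::-1]
            alignments.append(ReadAlignment(rec.query_name, contig, rec.reference_start,
                                            strand, nm, len(seq)))
            reads_by_id[rec.query_name] = Read(rec.query_name, bases, q)
    return alignments, reads_by_id, n_dropped


def aligned_bases(aln: ReadAlignment, reads_by_id: Dict[str, Read]
                  ) -> Tuple[str, np.ndarray]:
    """Read bases and quals oriented to the forward reference strand."""
    read = reads_by_id[aln.read_id]
    if aln.strand == "+":
        return read.bases, read.quals
    return revcomp(read.bases), read.quals[::-1]
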
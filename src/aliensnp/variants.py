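"""Pileup construction, raw SNP calling, and depth/quality filtering.

The sample is a single (effectively haploid) chromosome arm, so calling is
one alt allele per site. Site quality is defined explicitly as the
phred-scaled binomial tail probability of seeing at least the observed
number of alt reads by sequencing error alone:

    quality = -10 * log10( P(X >= alt_count) ),  X ~ Binomial(depth, eps)

with ``eps`` the error probability implied by the mean phred score of the
alt-supporting bases, capped at 1000. This replaces the opaque score of an
external caller with a documented, testable statistic; the conventional
depth >= 4 and quality >= 50 cut-offs (both inclusive) are applied by
``filter_variants``.

Sites where the second-most-common base exceeds 20% of depth are flagged
``het_flag`` (possible within-sample heterozygosity or collapsed paralogy)
but still called with the single majority alt.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import binom

from .align import ReadAlignment, CoverageSummary, aligned_bases
from .dna import BASES, seq_to_codes
from .reads import Read

QUALITY_CAP = 1000.0


@dataclass(slots=True)
class PileupColumn:
    ref_id: str
    pos: int  # 0-based
    ref_base: str
    base_counts: Dict[str, int]
    base_qual_sums: Dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())


class Pileup:
    """Per-contig count and quality-sum matrices over ACGTN."""

    def __init__(self, reference: Dict[str, str]):
        self.reference = reference
        self.ref_codes = {name: seq_to_codes(seq) for name, seq in reference.items()}
        self.counts = {name: np.zeros((5, len(seq)), dtype=np.int32)
                       for name, seq in reference.items()}
        self.qual_sums = {name: np.zeros((5, len(seq)), dtype=np.int64)
                          for name, seq in reference.items()}

    def columns(self, covered_only: bool = True) -> Iterator[PileupColumn]:
        alpha = BASES + "N"
        for name in self.reference:
            counts = self.counts[name]
            depth = counts.sum(axis=0)
            positions = np.flatnonzero(depth) if covered_only else range(counts.shape[1])
            for pos in positions:
                pos = int(pos)
                yield PileupColumn(
                    ref_id=name,
                    pos=pos,
                    ref_base=self.reference[name][pos],
                    base_counts={b: int(counts[i, pos]) for i, b in enumerate(alpha)
                                 if counts[i, pos]},
                    base_qual_sums={b: int(self.qual_sums[name][i, pos])
                                    for i, b in enumerate(alpha)
                                    if self.qual_sums[name][i, pos]},
                )


def build_pileup(alignments: Sequence[ReadAlignment], reads_by_id: Dict[str, Read],
                 reference: Dict[str, str]) -> Pileup:
    """Accumulate per-base counts and quality sums from ungapped alignments."""
    pile = Pileup(reference)
    for aln in alignments:
        if aln.read_id not in reads_by_id:
            raise KeyError(f"alignment references unknown read id {aln.read_id!r}")
        bases, quals = aligned_bases(aln, reads_by_id)
        codes = seq_to_codes(bases)
        span = np.arange(aln.start, aln.start + len(bases))
        np.add.at(pile.counts[aln.ref_id], (codes, span), 1)
        np.add.at(pile.qual_sums[aln.ref_id], (codes, span), quals.astype(np.int64))
    return pile


@dataclass(slots=True)
class VariantCall:
    ref_id: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str
    depth: int
    alt_count: int
    quality: float
    het_flag: bool = False
    ambiguous_alt: bool = False

    def key(self) -> tuple:
        return (self.ref_id, self.pos, self.ref_allele, self.alt_allele)


def phred_tail_quality(alt_count: int, depth: int, eps: float,
                       cap: float = QUALITY_CAP) -> float:
    """Phred-scaled upper binomial tail P(X >= alt_count), X ~ B(depth, eps)."""
    if alt_count <= 0:
        return 0.0
    tail = float(binom.sf(alt_count - 1, depth, eps))
    if tail <= 0.0:
        return cap
    return min(cap, -10.0 * np.log10(tail))


def call_raw_variants(pileup: Pileup, cap: float = QUALITY_CAP) -> List[VariantCall]:
    """Emit one candidate call per column with any non-reference ACGT support.

    The alt allele is the non-reference base with the highest count; count
    ties are broken by higher quality sum, then lexicographically (flagged
    ``ambiguous_alt``). ``N`` never becomes an alt allele but contributes to
    depth.
    """
    calls: List[VariantCall] = []
    for name, counts in pileup.counts.items():
        qsums = pileup.qual_sums[name]
        depth = counts.sum(axis=0)
        ref_codes = pileup.ref_codes[name]
        L = counts.shape[1]
        cols = np.arange(L)

        acgt = counts[:4].copy()
        acgt_q = qsums[:4].copy()
        in_range = ref_codes < 4
        acgt[ref_codes[in_range], cols[in_range]] = 0  # mask the reference base
        acgt_q[ref_codes[in_range], cols[in_range]] = 0

        candidate = np.flatnonzero((acgt.sum(axis=0) > 0) & in_range)
        if candidate.size == 0:
            continue

        sub_counts = acgt[:, candidate]
        sub_q = acgt_q[:, candidate]
        # lexicographic tie-break via argmax on (count, qual sum, -base code)
        rank = (sub_counts.astype(np.float64) * 1e12
                + sub_q.astype(np.float64) * 1e-3
                + (3 - np.arange(4))[:, None] * 1e-9)
        alt_codes = np.argmax(rank, axis=0)
        alt_counts = sub_counts[alt_codes, np.arange(candidate.size)]
        alt_qsums = sub_q[alt_codes, np.arange(candidate.size)]

        top = np.sort(sub_counts, axis=0)[::-1]
        count_tied = top[0] == top[1]
        qs_sorted = np.sort(np.where(sub_counts == alt_counts[None, :], sub_q, -1), axis=0)[::-1]
        fully_tied = count_tied & (qs_sorted[0] == qs_sorted[1])

        mean_q = alt_qsums / np.maximum(alt_counts, 1)
        eps = np.power(10.0, -mean_q / 10.0)
        d = depth[candidate]
        tail = binom.sf(alt_counts - 1, d, eps)
        with np.errstate(divide="ignore"):
            qual = np.where(tail > 0, -10.0 * np.log10(np.maximum(tail, 1e-320)), cap)
        qual = np.minimum(qual, cap)

        all_counts = counts[:, candidate]
        second = np.sort(all_counts, axis=0)[::-1][1]
        het = second > 0.2 * d

        ref_b = [BASES[int(ref_codes[p])] for p in candidate]
        for j, p in enumerate(candidate):
            calls.append(VariantCall(
                ref_id=name,
                pos=int(p),
                ref_allele=ref_b[j],
                alt_allele=BASES[int(alt_codes[j])],
                depth=int(d[j]),
                alt_count=int(alt_counts[j]),
                quality=float(qual[j]),
                het_flag=bool(het[j]),
                ambiguous_alt=bool(fully_tied[j]),
            ))
    calls.sort(key=lambda c: (c.ref_id, c.pos))
    return calls


def filter_variants(calls: Iterable[VariantCall], min_depth: int = 4,
                    min_qual: float = 50.0) -> List[VariantCall]:
    """Keep calls with depth >= min_depth AND quality >= min_qual (inclusive)."""
    return [c for c in calls if c.depth >= min_depth and c.quality >= min_qual]


def snp_density(calls: Sequence[VariantCall], coverage: CoverageSummary) -> Optional[float]:
    """Filtered SNPs per kb of covered reference sequence (None if nothing covered)."""
    if coverage.covered_bases == 0:
        return None
    return len(calls) / coverage.covered_bases * 1000.0


# ---------------------------------------------------------------------------
# VCF I/O (v4.2, 1-based POS, INFO DP/AC)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=aliensnp
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at the site">
##INFO=<ID=AC,Number=1,Type=Integer,Description="Alt-supporting read count">
##INFO=<ID=HET,Number=0,Type=Flag,Description="Second allele above 20% of depth">
##INFO=<ID=AMBALT,Number=0,Type=Flag,Description="Alt allele tie broken lexicographically">
##FILTER=<ID=lowdepth,Description="Depth below the minimum">
##FILTER=<ID=lowqual,Description="Quality below the minimum">
"""


def write_vcf(path: str | Path, calls: Sequence[VariantCall],
              reference: Dict[str, str], emit_all: bool = False,
              min_depth: int = 4, min_qual: float = 50.0) -> None:
    """Write calls as VCF; with ``emit_all`` failing calls appear with FILTER codes."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name, seq in reference.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            fails = []
            if c.depth < min_depth:
                fails.append("lowdepth")
            if c.quality < min_qual:
                fails.append("lowqual")
            if fails and not emit_all:
                continue
            info = f"DP={c.depth};AC={c.alt_count}"
            if c.het_flag:
                info += ";HET"
            if c.ambiguous_alt:
                info += ";AMBALT"
            filt = ";".join(fails) if fails else "PASS"
            fh.write(f"{c.ref_id}\t{c.pos + 1}\t.\t{c.ref_allele}\t{c.alt_allele}\t"
                     f"{c.quality:.2f}\t{filt}\t{info}\n")


def read_vcf(path: str | Path) -> List[VariantCall]:
    """Parse a VCF written by :func:`write_vcf` back to VariantCall records."""
    import pysam

    calls: List[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            calls.append(VariantCall(
                ref_id=rec.chrom,
                pos=rec.pos - 1,
                ref_allele=rec.ref,
                alt_allele=rec.alts[0],
                depth=int(rec.info["DP"]),
                alt_count=int(rec.info["AC"]),
                quality=float(rec.qual),
                het_flag="HET" in rec.info,
                ambiguous_alt="AMBALT" in rec.info,
            ))
    return calls


def funnel_report(path: str | Path, rows: Sequence[Dict[str, object]]) -> None:
    """Write the per-reference discovery funnel (mapped reads, raw, filtered, genic)."""
    cols = ["reference", "mapped_reads", "raw_snps", "filtered_snps", "genic_snps"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "NA")) for c in cols) + "\n")


def count_genic(calls: Sequence[VariantCall],
                intervals: Sequence[Tuple[str, int, int]]) -> int:
    """Count calls whose position falls in any (contig, start, end) half-open interval."""
    by_contig: Dict[str, List[Tuple[int, int]]] = {}
    for contig, start, end in intervals:
        by_contig.setdefault(contig, []).append((start, end))
    n = 0
    for c in calls:
        for start, end in by_contig.get(c.ref_id, ()):
            if start <= c.pos < end:
                n += 1
                break
    return n
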
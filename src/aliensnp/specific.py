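"""Alien-chromosome-specific SNP discovery across a homoeologous trio.

A site is diagnostic for alien chromatin when all wheat homoeologues carry
one identical allele while the alien arm carries another: a single assay
then separates alien-carrying material from any wheat background. Working
from filtered calls of the same alien read set against each homoeologue:

1. every call on the anchor homoeologue (A by convention) contributes a
   ``(2*flank_width + 1)``-base window centred on the SNP;
2. the B and D references are searched on both strands for a full-length
   hit whose two ``flank_width`` flanks are 100% identical to the anchor
   window (the centre base is excluded from the identity requirement), and
   exactly one hit per reference is required;
3. the centre bases of the hits give the B and D alleles; the site is
   alien-specific iff the three wheat alleles agree, the alien alt allele
   differs, and concordant filtered calls exist at the B and D hit
   positions (the strictest reading; ``require_calls_on_all=False`` relaxes
   to reference-base agreement only).

Marker candidates additionally require clean flanks: no other filtered
anchor call within ``flank_width`` of the SNP, and — when a de-novo alien
assembly is supplied — a unique exact full-length match of the anchor
window (with the alien allele substituted at centre) in the alien contigs,
so that assay primers designed on the flank work on both genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .dna import revcomp, write_fasta
from .variants import VariantCall

FLANK_WIDTH = 100

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# reject reason codes
R_EDGE = "edge"
R_FLANK_MISMATCH = "flank_mismatch"
R_AMBIGUOUS = "ambiguous_flank_hit"
R_TRIO_DISCORDANT = "trio_discordant"
R_NO_CALL = "no_concordant_call"
R_NEARBY_VARIANT = "nearby_variant"
R_NO_CONTIG_HIT = "no_contig_hit"
R_MULTI_CONTIG_HIT = "multi_contig_hit"


@dataclass(slots=True)
class FlankHit:
    ref_id: str
    pos: int  # 0-based centre position on the forward strand of the hit contig
    strand: str


@dataclass(slots=True)
class TrioAnchoredSite:
    anchor_ref: str
    anchor_pos: int  # 0-based
    wheat_alleles: Tuple[str, str, str]  # (A, B, D), anchor-forward orientation
    alien_allele: str
    flank_a: str  # full (2*flank_width + 1)-base anchor window
    b_hit: Optional[FlankHit]
    d_hit: Optional[FlankHit]
    flank_identical_across_trio: bool
    flank_clean_vs_alien: Optional[bool] = None  # None = untested (no contigs given)


@dataclass(slots=True)
class RejectedSite:
    anchor_ref: str
    anchor_pos: int
    reason: str


@dataclass(slots=True)
class MarkerCandidate:
    marker_id: str
    site: TrioAnchoredSite
    wheat_allele: str
    alien_allele: str
    left_flank: str
    right_flank: str
    status: str  # "specific" or "candidate"
    reject_reason: Optional[str] = None


def _search_flank_hits(window: str, reference: Dict[str, str],
                       flank_width: int) -> List[FlankHit]:
    """All occurrences of the window in a reference, both strands, centre wildcarded."""
    hits: List[FlankHit] = []
    fw = flank_width
    for oriented, strand in ((window, "+"), (revcomp(window), "-")):
        left, right = oriented[:fw], oriented[fw + 1:]
        for name, seq in reference.items():
            i = seq.find(left)
            while i != -1:
                centre = i + fw
                if seq[centre + 1:centre + 1 + fw] == right:
                    hits.append(FlankHit(name, centre, strand))
                i = seq.find(left, i + 1)
    return hits


def _hit_base(hit: FlankHit, reference: Dict[str, str]) -> str:
    """Centre base of a flank hit, oriented to the anchor's forward strand."""
    base = reference[hit.ref_id][hit.pos]
    return base if hit.strand == "+" else _COMP[base]


def find_alien_specific(
    calls_a: Sequence[VariantCall],
    calls_b: Sequence[VariantCall],
    calls_d: Sequence[VariantCall],
    ref_a: Dict[str, str],
    ref_b: Dict[str, str],
    ref_d: Dict[str, str],
    flank_width: int = FLANK_WIDTH,
    require_calls_on_all: bool = True,
) -> Tuple[List[TrioAnchoredSite], List[RejectedSite]]:
    """Intersect filtered calls across the trio into alien-specific anchored sites.

    Returns (accepted sites sorted by anchor coordinate, rejected sites with
    reason codes).
    """
    fw = flank_width
    lookup_b = {(c.ref_id, c.pos): c for c in calls_b}
    lookup_d = {(c.ref_id, c.pos): c for c in calls_d}

    sites: List[TrioAnchoredSite] = []
    rejected: List[RejectedSite] = []

    for call in sorted(calls_a, key=lambda c: (c.ref_id, c.pos)):
        contig_seq = ref_a[call.ref_id]
        p = call.pos
        if p < fw or p + fw >= len(contig_seq):
            rejected.append(RejectedSite(call.ref_id, p, R_EDGE))
            continue
        window = contig_seq[p - fw:p + fw + 1]

        resolved: List[Optional[FlankHit]] = []
        reason = None
        for ref in (ref_b, ref_d):
            hits = _search_flank_hits(window, ref, fw)
            if len(hits) == 0:
                reason = R_FLANK_MISMATCH
                break
            if len(hits) > 1:
                reason = R_AMBIGUOUS
                break
            resolved.append(hits[0])
        if reason is not None:
            rejected.append(RejectedSite(call.ref_id, p, reason))
            continue
        b_hit, d_hit = resolved

        a_base = call.ref_allele
        b_base = _hit_base(b_hit, ref_b)
        d_base = _hit_base(d_hit, ref_d)
        if not (a_base == b_base == d_base):
            rejected.append(RejectedSite(call.ref_id, p, R_TRIO_DISCORDANT))
            continue
        # the alien alt differs from A by construction of the call; require
        # concordant alt calls on B and D unless relaxed
        if require_calls_on_all:
            ok = True
            for hit, lookup in ((b_hit, lookup_b), (d_hit, lookup_d)):
                other = lookup.get((hit.ref_id, hit.pos))
                expected_alt = (call.alt_allele if hit.strand == "+"
                                else _COMP[call.alt_allele])
                if other is None or other.alt_allele != expected_alt:
                    ok = False
                    break
            if not ok:
                rejected.append(RejectedSite(call.ref_id, p, R_NO_CALL))
                continue

        sites.append(TrioAnchoredSite(
            anchor_ref=call.ref_id,
            anchor_pos=p,
            wheat_alleles=(a_base, b_base, d_base),
            alien_allele=call.alt_allele,
            flank_a=window,
            b_hit=b_hit,
            d_hit=d_hit,
            flank_identical_across_trio=True,
        ))
    return sites, rejected


def flank_clean_filter(
    sites: Sequence[TrioAnchoredSite],
    calls_a: Sequence[VariantCall],
    alien_contigs: Optional[Dict[str, str]] = None,
    flank_width: int = FLANK_WIDTH,
    id_prefix: str = "gsnp_",
    arm_label: str = "s",
) -> List[MarkerCandidate]:
    """Promote sites with clean flanks to marker candidates.

    A site becomes status ``candidate`` iff no other filtered anchor call
    lies within ``flank_width`` of it and, when alien contigs are supplied,
    the anchor window with the alien allele substituted at centre has a
    unique exact full-length match in the contigs (either strand). Without
    contigs that check is recorded untested (``flank_clean_vs_alien`` stays
    None). All sites are returned, ordered by anchor coordinate; candidates
    carry serial marker ids ``<id_prefix><arm_label><serial>``.
    """
    fw = flank_width
    call_pos: Dict[str, List[int]] = {}
    for c in calls_a:
        call_pos.setdefault(c.ref_id, []).append(c.pos)

    ordered = sorted(sites, key=lambda s: (s.anchor_ref, s.anchor_pos))
    markers: List[MarkerCandidate] = []
    serial = 0
    for site in ordered:
        p = site.anchor_pos
        nearby = any(q != p and abs(q - p) <= fw
                     for q in call_pos.get(site.anchor_ref, ()))
        reason = R_NEARBY_VARIANT if nearby else None

        if reason is None and alien_contigs is not None:
            probe = (site.flank_a[:fw] + site.alien_allele + site.flank_a[fw + 1:])
            hits = _search_flank_hits(probe, alien_contigs, fw)
            # the centre is wildcarded by the search; require the alien allele there
            hits = [h for h in hits if _hit_base(h, alien_contigs) == site.alien_allele]
            if len(hits) == 0:
                reason = R_NO_CONTIG_HIT
            elif len(hits) > 1:
                reason = R_MULTI_CONTIG_HIT
            else:
                site.flank_clean_vs_alien = True
        if reason in (R_NO_CONTIG_HIT, R_MULTI_CONTIG_HIT):
            site.flank_clean_vs_alien = False

        if reason is None:
            serial += 1
            marker_id = f"{id_prefix}{arm_label}{serial}"
            status = "candidate"
        else:
            marker_id = ""
            status = "specific"
        markers.append(MarkerCandidate(
            marker_id=marker_id,
            site=site,
            wheat_allele=site.wheat_alleles[0],
            alien_allele=site.alien_allele,
            left_flank=site.flank_a[:fw],
            right_flank=site.flank_a[fw + 1:],
            status=status,
            reject_reason=reason,
        ))
    return markers


def export_marker_sheet(candidates: Sequence[MarkerCandidate],
                        path_tsv: str | Path,
                        path_fasta: Optional[str | Path] = None) -> None:
    """Write assay-ready candidates as TSV (1-based positions) and flank FASTA.

    Each row carries the two allele-variant centre sequences (flank with the
    wheat or the alien base substituted), the layout needed to derive the
    two allele-specific forward primers and the common reverse primer of a
    competitive allele-specific PCR assay.
    """
    rows = [c for c in candidates if c.status == "candidate"]
    seen = set()
    for c in rows:
        if c.marker_id in seen:
            raise ValueError(f"duplicate marker id {c.marker_id!r}")
        seen.add(c.marker_id)
    cols = ["marker_id", "anchor_ref", "position", "wheat_allele", "alien_allele",
            "left_flank", "right_flank", "wheat_variant_seq", "alien_variant_seq"]
    with open(path_tsv, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in rows:
            wheat_seq = c.left_flank + c.wheat_allele + c.right_flank
            alien_seq = c.left_flank + c.alien_allele + c.right_flank
            fh.write("\t".join([
                c.marker_id, c.site.anchor_ref, str(c.site.anchor_pos + 1),
                c.wheat_allele, c.alien_allele, c.left_flank, c.right_flank,
                wheat_seq, alien_seq,
            ]) + "\n")
    if path_fasta is not None:
        records = []
        for c in rows:
            records.append((f"{c.marker_id}_wheat",
                            c.left_flank + c.wheat_allele + c.right_flank))
            records.append((f"{c.marker_id}_alien",
                            c.left_flank + c.alien_allele + c.right_flank))
        write_fasta(path_fasta, records)


def read_marker_sheet(path: str | Path) -> List[Dict[str, str]]:
    """Parse a marker sheet TSV back into row dicts (position stays 1-based text)."""
    rows: List[Dict[str, str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    return rows


def write_candidate_bed(candidates: Sequence[MarkerCandidate], path: str | Path) -> None:
    """BED (0-based half-open) of candidate positions on the anchor reference."""
    with open(path, "w") as fh:
        for c in candidates:
            if c.status != "candidate":
                continue
            fh.write(f"{c.site.anchor_ref}\t{c.site.anchor_pos}\t"
                     f"{c.site.anchor_pos + 1}\t{c.marker_id}\n")


def write_rejected_sites(rejected: Sequence[RejectedSite],
                         markers: Sequence[MarkerCandidate],
                         path: str | Path) -> None:
    """TSV of all non-candidate sites with their reason codes (funnel diagnostics)."""
    with open(path, "w") as fh:
        fh.write("anchor_ref\tposition\tstage\treason\n")
        for r in rejected:
            fh.write(f"{r.anchor_ref}\t{r.anchor_pos}\tintersect\t{r.reason}\n")
        for m in markers:
            if m.status == "specific":
                fh.write(f"{m.site.anchor_ref}\t{m.site.anchor_pos}\tflank_clean\t"
                         f"{m.reject_reason}\n")
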
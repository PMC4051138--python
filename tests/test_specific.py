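"""Trio intersection and flank-cleanliness filtering on hand-built and simulated data."""

import numpy as np
import pytest

from aliensnp.dna import revcomp
from aliensnp.simulate import SimulationConfig, evolve_trio, slice_contigs
from aliensnp.specific import (
    R_AMBIGUOUS,
    R_EDGE,
    R_FLANK_MISMATCH,
    R_NEARBY_VARIANT,
    R_NO_CONTIG_HIT,
    R_TRIO_DISCORDANT,
    export_marker_sheet,
    find_alien_specific,
    flank_clean_filter,
    read_marker_sheet,
    write_candidate_bed,
)
from aliensnp.variants import VariantCall


def _call(contig, pos, ref, alt, depth=20, qual=300.0):
    return VariantCall(contig, pos, ref, alt, depth, depth, qual)


def _seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture()
def tiny_trio():
    """Identical 1-kb trio (fw=20 for readability); variants are injected per test."""
    rng = np.random.default_rng(42)
    seq = _seq(rng, 1_000)
    return {"A": {"cA": seq}, "B": {"cB": seq}, "D": {"cD": seq}, "seq": seq}


FW = 20


def _mut(seq, pos, base):
    return seq[:pos] + base + seq[pos + 1:]


def _other(base):
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[base]


def _find(trio, calls_a, calls_b=None, calls_d=None, **kw):
    return find_alien_specific(
        calls_a, calls_b or [], calls_d or [],
        trio["A"], trio["B"], trio["D"], flank_width=FW, **kw)


def test_concordant_trio_site_is_emitted(tiny_trio):
    seq = tiny_trio["seq"]
    p = 500
    w, m = seq[p], _other(seq[p])
    calls_a = [_call("cA", p, w, m)]
    calls_b = [_call("cB", p, w, m)]
    calls_d = [_call("cD", p, w, m)]
    sites, rejected = _find(tiny_trio, calls_a, calls_b, calls_d)
    assert rejected == []
    assert len(sites) == 1
    site = sites[0]
    assert site.wheat_alleles == (w, w, w)
    assert site.alien_allele == m
    assert site.flank_identical_across_trio
    assert site.b_hit.pos == p and site.d_hit.pos == p


def test_discordant_homoeologue_base_is_rejected(tiny_trio):
    seq = tiny_trio["seq"]
    p = 500
    w, m = seq[p], _other(seq[p])
    trio = dict(tiny_trio)
    trio["B"] = {"cB": _mut(seq, p, _other(w))}  # B carries a third allele
    sites, rejected = _find(trio, [_call("cA", p, w, m)],
                            [_call("cB", p, _other(w), m)], [_call("cD", p, w, m)])
    assert sites == []
    assert [r.reason for r in rejected] == [R_TRIO_DISCORDANT]


def test_flank_substitution_between_references_is_rejected(tiny_trio):
    seq = tiny_trio["seq"]
    p = 500
    w, m = seq[p], _other(seq[p])
    trio = dict(tiny_trio)
    trio["B"] = {"cB": _mut(seq, p - 5, _other(seq[p - 5]))}  # inside the flank
    sites, rejected = _find(trio, [_call("cA", p, w, m)],
                            [_call("cB", p, w, m)], [_call("cD", p, w, m)])
    assert sites == []
    assert [r.reason for r in rejected] == [R_FLANK_MISMATCH]


def test_missing_concordant_call_on_b_is_rejected_unless_relaxed(tiny_trio):
    seq = tiny_trio["seq"]
    p = 500
    w, m = seq[p], _other(seq[p])
    sites, rejected = _find(tiny_trio, [_call("cA", p, w, m)], [],
                            [_call("cD", p, w, m)])
    assert sites == [] and len(rejected) == 1
    sites, rejected = _find(tiny_trio, [_call("cA", p, w, m)], [], [],
                            require_calls_on_all=False)
    assert len(sites) == 1 and rejected == []


def test_edge_site_is_rejected(tiny_trio):
    seq = tiny_trio["seq"]
    p = FW - 1  # window truncated on the left
    sites, rejected = _find(tiny_trio, [_call("cA", p, seq[p], _other(seq[p]))])
    assert sites == [] and [r.reason for r in rejected] == [R_EDGE]


def test_duplicated_flank_is_ambiguous(tiny_trio):
    seq = tiny_trio["seq"]
    p = 500
    w, m = seq[p], _other(seq[p])
    window = seq[p - FW:p + FW + 1]
    trio = dict(tiny_trio)
    trio["B"] = {"cB": seq + "T" * 10 + window}  # second copy of the window
    sites, rejected = _find(trio, [_call("cA", p, w, m)],
                            [_call("cB", p, w, m)], [_call("cD", p, w, m)])
    assert sites == [] and [r.reason for r in rejected] == [R_AMBIGUOUS]


def test_reverse_strand_hit_reports_anchor_forward_alleles(tiny_trio):
    seq = tiny_trio["seq"]
    p = 500
    w, m = seq[p], _other(seq[p])
    trio = dict(tiny_trio)
    trio["B"] = {"cB": revcomp(seq)}
    p_rc = len(seq) - 1 - p
    sites, rejected = _find(trio, [_call("cA", p, w, m)],
                            [_call("cB", p_rc, revcomp(w), revcomp(m))],
                            [_call("cD", p, w, m)])
    assert rejected == []
    site = sites[0]
    assert site.b_hit.strand == "-" and site.b_hit.pos == p_rc
    assert site.wheat_alleles == (w, w, w) and site.alien_allele == m


def _emit_one_site(trio, p):
    seq = trio["seq"]
    w, m = seq[p], _other(seq[p])
    calls_a = [_call("cA", p, w, m)]
    sites, _ = _find(trio, calls_a, [_call("cB", p, w, m)], [_call("cD", p, w, m)])
    return sites, calls_a, m


def test_nearby_variant_blocks_promotion(tiny_trio):
    p = 500
    sites, calls_a, _ = _emit_one_site(tiny_trio, p)
    seq = tiny_trio["seq"]
    near = _call("cA", p + 15, seq[p + 15], _other(seq[p + 15]))
    markers = flank_clean_filter(sites, calls_a + [near], flank_width=FW)
    assert markers[0].status == "specific"
    assert markers[0].reject_reason == R_NEARBY_VARIANT
    clean = flank_clean_filter(sites, calls_a, flank_width=FW)
    assert clean[0].status == "candidate"


def test_contig_concordance_requires_alien_allele_at_centre(tiny_trio):
    p = 500
    sites, calls_a, m = _emit_one_site(tiny_trio, p)
    seq = tiny_trio["seq"]
    alien_arm = _mut(seq, p, m)
    contigs = slice_contigs(alien_arm, 400)
    markers = flank_clean_filter(sites, calls_a, alien_contigs=contigs, flank_width=FW)
    assert markers[0].status == "candidate"
    assert markers[0].site.flank_clean_vs_alien is True
    # contigs lacking the alien allele (e.g. stale assembly) -> no exact hit
    markers = flank_clean_filter(sites, calls_a, alien_contigs=slice_contigs(seq, 400),
                                 flank_width=FW)
    assert markers[0].status == "specific"
    assert markers[0].reject_reason == R_NO_CONTIG_HIT


def test_flank_spanning_contig_boundary_is_not_promoted(tiny_trio):
    p = 500
    sites, calls_a, m = _emit_one_site(tiny_trio, p)
    alien_arm = _mut(tiny_trio["seq"], p, m)
    # boundary right at the SNP: both pieces truncate the window
    contigs = {"left": alien_arm[:p + 5], "right": alien_arm[p + 5:]}
    markers = flank_clean_filter(sites, calls_a, alien_contigs=contigs, flank_width=FW)
    assert markers[0].status == "specific"
    assert markers[0].reject_reason == R_NO_CONTIG_HIT


def test_marker_sheet_layout_and_one_based_positions(tmp_path, tiny_trio):
    p = 500
    sites, calls_a, m = _emit_one_site(tiny_trio, p)
    markers = flank_clean_filter(sites, calls_a, flank_width=FW)
    tsv = tmp_path / "markers.tsv"
    export_marker_sheet(markers, tsv, tmp_path / "flanks.fasta")
    rows = read_marker_sheet(tsv)
    assert len(rows) == 1
    row = rows[0]
    assert int(row["position"]) == p + 1
    assert row["marker_id"] == "gsnp_s1"
    seq = tiny_trio["seq"]
    assert row["wheat_variant_seq"] == seq[p - FW:p + FW + 1]
    assert row["alien_variant_seq"] == seq[p - FW:p] + m + seq[p + 1:p + FW + 1]
    fasta = (tmp_path / "flanks.fasta").read_text()
    assert ">gsnp_s1_wheat" in fasta and ">gsnp_s1_alien" in fasta


def test_empty_candidate_set_writes_header_only_sheet(tmp_path):
    tsv = tmp_path / "markers.tsv"
    export_marker_sheet([], tsv)
    assert tsv.read_text().startswith("marker_id\t")
    assert len(tsv.read_text().splitlines()) == 1


def test_duplicate_marker_ids_are_a_hard_error(tmp_path, tiny_trio):
    sites, calls_a, _ = _emit_one_site(tiny_trio, 500)
    markers = flank_clean_filter(sites, calls_a, flank_width=FW)
    dup = markers + markers
    with pytest.raises(ValueError, match="duplicate"):
        export_marker_sheet(dup, tmp_path / "x.tsv")


def test_bed_export_is_zero_based_half_open(tmp_path, tiny_trio):
    sites, calls_a, _ = _emit_one_site(tiny_trio, 500)
    markers = flank_clean_filter(sites, calls_a, flank_width=FW)
    bed = tmp_path / "markers.bed"
    write_candidate_bed(markers, bed)
    assert bed.read_text() == "cA\t500\t501\tgsnp_s1\n"


# --- simulated end-to-end properties (sequence-level, no reads involved) ----


def _truth_calls(sim):
    """Perfect filtered call sets derived directly from the simulated sequences."""
    a, b, d = (sim.homoeologues[k] for k in ("homA", "homB", "homD"))
    m = sim.alien
    calls = {"homA": [], "homB": [], "homD": []}
    for name, ref in (("homA", a), ("homB", b), ("homD", d)):
        for i in range(len(ref)):
            if ref[i] != m[i]:
                calls[name].append(_call(name, i, ref[i], m[i]))
    return calls


def test_simulated_truth_classes_route_to_the_right_outcome(small_sim):
    sim = small_sim
    calls = _truth_calls(sim)
    fw = sim.config.flank_width
    refs = {k: {k: v} for k, v in sim.homoeologues.items()}
    sites, rejected = find_alien_specific(
        calls["homA"], calls["homB"], calls["homD"],
        refs["homA"], refs["homB"], refs["homD"], flank_width=fw)
    emitted = {s.anchor_pos for s in sites}
    spec = set(sim.truth.positions("alien_specific"))
    disc = set(sim.truth.positions("homoeologue_discordant"))
    contam = set(sim.truth.positions("flank_contaminated"))
    assert spec <= emitted                       # completeness of planted clean sites
    assert emitted & disc == set()               # soundness vs discordant plantings
    assert contam <= emitted                     # contaminated sites are still specific

    contigs = slice_contigs(sim.alien, sim.config.contig_length)
    markers = flank_clean_filter(sites, calls["homA"], alien_contigs=contigs,
                                 flank_width=fw)
    promoted = {mk.site.anchor_pos for mk in markers if mk.status == "candidate"}
    assert promoted & contam == set()            # never promoted
    assert promoted <= emitted                   # funnel monotonicity
    # alleles of promoted planted sites match the truth table exactly
    truth_by_pos = {r.position: r for r in sim.truth.records}
    for mk in markers:
        if mk.status != "candidate":
            continue
        rec = truth_by_pos[mk.site.anchor_pos]
        assert (mk.wheat_allele, mk.alien_allele) == (rec.wheat_allele, rec.alien_allele)


def test_anchor_symmetry_on_clean_sites(small_sim):
    """Swapping the anchor changes coordinates, not the (wheat, alien) allele pairs
    of planted clean specific sites."""
    sim = small_sim
    calls = _truth_calls(sim)
    fw = sim.config.flank_width
    refs = {k: {k: v} for k, v in sim.homoeologues.items()}
    sites_a, _ = find_alien_specific(calls["homA"], calls["homB"], calls["homD"],
                                     refs["homA"], refs["homB"], refs["homD"],
                                     flank_width=fw)
    sites_b, _ = find_alien_specific(calls["homB"], calls["homA"], calls["homD"],
                                     refs["homB"], refs["homA"], refs["homD"],
                                     flank_width=fw)
    spec = set(sim.truth.positions("alien_specific"))
    pairs_a = sorted((s.wheat_alleles[0], s.alien_allele) for s in sites_a
                     if s.anchor_pos in spec)
    pairs_b = sorted((s.wheat_alleles[0], s.alien_allele) for s in sites_b
                     if s.anchor_pos in spec)
    assert pairs_a == pairs_b
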
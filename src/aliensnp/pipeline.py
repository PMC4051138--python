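"""End-to-end orchestration: QC -> map (x3) -> call (x3) -> specific -> markers.

All stage outputs are standard text formats (SAM, VCF, TSV, BED, FASTA) so
any stage can be replaced by an external tool, and the manifest records the
discovery funnel plus SHA-256 hashes of every output. Nothing in the
outputs depends on wall-clock time, so rerunning with identical inputs and
config reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import align, reads as reads_mod, specific as specific_mod, variants
from .dna import read_fasta


class ConfigError(ValueError):
    """Invalid pipeline configuration (bad paths or thresholds)."""


class DataError(ValueError):
    """Malformed input data encountered mid-stage."""


@dataclass(slots=True)
class PipelineConfig:
    ref_a: str
    ref_b: str
    ref_d: str
    reads: str
    out_dir: str
    contigs: Optional[str] = None
    annotation: Optional[str] = None
    max_mismatch: int = 3
    min_depth: int = 4
    min_qual: float = 50.0
    flank_width: int = 100
    min_len: int = 30
    min_frac: float = 0.8
    qual_floor: int = 15
    drop_ties: bool = True
    seed: int = 0
    arm_label: str = "s"
    write_sam: bool = True

    def validate(self) -> None:
        for name in ("ref_a", "ref_b", "ref_d", "reads"):
            path = getattr(self, name)
            if not Path(path).is_file():
                raise ConfigError(f"{name}: no such file: {path}")
        for name in ("contigs", "annotation"):
            path = getattr(self, name)
            if path is not None and not Path(path).is_file():
                raise ConfigError(f"{name}: no such file: {path}")
        if not (0 <= self.max_mismatch <= 10):
            raise ConfigError("max_mismatch must be in 0..10")
        if self.min_depth < 1 or self.min_qual < 0:
            raise ConfigError("min_depth must be >= 1 and min_qual >= 0")
        if self.flank_width < 1 or self.min_len < 0 or not (0 <= self.min_frac <= 1):
            raise ConfigError("bad flank_width/min_len/min_frac")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _read_annotation(path: str) -> List[tuple]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            contig, start, end = line.split("\t")[:3]
            intervals.append((contig, int(start), int(end)))
    return intervals


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run all stages; writes outputs under ``config.out_dir`` and returns the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    refs = {label: read_fasta(getattr(config, f"ref_{label.lower()}"))
            for label in ("A", "B", "D")}
    contigs = read_fasta(config.contigs) if config.contigs else None
    annotation = _read_annotation(config.annotation) if config.annotation else None

    # --- QC
    raw_iter = reads_mod.read_fastq(config.reads)
    clean, qc = reads_mod.clean_reads(raw_iter, min_len=config.min_len,
                                      min_frac=config.min_frac,
                                      qual_floor=config.qual_floor)
    qc.to_tsv(out / "qc_report.tsv")
    reads_by_id = {r.id: r for r in clean}

    # --- map and call per homoeologue
    per_ref: Dict[str, Dict] = {}
    filtered_by_label: Dict[str, List[variants.VariantCall]] = {}
    funnel_rows = []
    for label in ("A", "B", "D"):
        reference = refs[label]
        alignments, unmapped = align.map_reads(
            clean, reference, max_mismatch=config.max_mismatch,
            drop_ties=config.drop_ties, seed=config.seed)
        if config.write_sam:
            align.export_sam(out / f"mapped_{label}.sam", alignments, reads_by_id,
                             reference)
        cov = align.coverage_summary(alignments, reference, label=label)
        pile = variants.build_pileup(alignments, reads_by_id, reference)
        raw_calls = variants.call_raw_variants(pile)
        filtered = variants.filter_variants(raw_calls, min_depth=config.min_depth,
                                            min_qual=config.min_qual)
        variants.write_vcf(out / f"calls_{label}.vcf", filtered, reference,
                           min_depth=config.min_depth, min_qual=config.min_qual)
        density = variants.snp_density(filtered, cov)
        genic = variants.count_genic(filtered, annotation) if annotation else None
        per_ref[label] = {
            "mapped_reads": cov.mapped_read_count,
            "unmapped_reads": len(unmapped),
            "covered_bases": cov.covered_bases,
            "covered_fraction": round(cov.covered_fraction, 6),
            "raw_snps": len(raw_calls),
            "filtered_snps": len(filtered),
            "snp_density_per_kb": None if density is None else round(density, 4),
            "genic_snps": genic,
        }
        filtered_by_label[label] = filtered
        funnel_rows.append({
            "reference": label,
            "mapped_reads": cov.mapped_read_count,
            "raw_snps": len(raw_calls),
            "filtered_snps": len(filtered),
            "genic_snps": "NA" if genic is None else genic,
        })
    variants.funnel_report(out / "funnel.tsv", funnel_rows)

    # --- trio intersection and marker candidates
    sites, rejected = specific_mod.find_alien_specific(
        filtered_by_label["A"], filtered_by_label["B"], filtered_by_label["D"],
        refs["A"], refs["B"], refs["D"], flank_width=config.flank_width)
    markers = specific_mod.flank_clean_filter(
        sites, filtered_by_label["A"], alien_contigs=contigs,
        flank_width=config.flank_width, arm_label=config.arm_label)
    candidates = [m for m in markers if m.status == "candidate"]

    specific_mod.export_marker_sheet(markers, out / "markers.tsv",
                                     out / "marker_flanks.fasta")
    specific_mod.write_candidate_bed(markers, out / "markers.bed")
    specific_mod.write_rejected_sites(rejected, markers, out / "rejected_sites.tsv")

    manifest = {
        "tool": "aliensnp",
        "config": asdict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()).hexdigest(),
        "counts": {
            "reads_in": qc.n_raw,
            "reads_kept": qc.n_kept,
            "retained_fraction": round(qc.retained_fraction, 6),
            "per_reference": per_ref,
            "specific_sites": len(sites),
            "marker_candidates": len(candidates),
        },
        "outputs": {},
    }
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
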
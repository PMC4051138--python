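"""Synthetic homoeologous-trio and alien-arm simulator.

The marker-discovery method assumes a very specific data geometry: three
homoeologous wheat chromosome-arm assemblies (A, B, D) that diverged from a
common ancestor, and a more-diverged alien chromosome arm sequenced as
single-end short reads. This module generates that geometry from scratch,
together with a truth table of planted sites, so every downstream stage can
be tested without any external download.

Evolution is substitution-only (no indels), so all four sequences share one
coordinate system; the detection code never relies on this, but truth
bookkeeping and test oracles become exact.

Three classes of sites are planted deliberately:

``alien_specific``
    all three homoeologues carry the ancestral allele, the alien arm carries
    a different one, and the +/-``flank_width`` window around the site is
    kept free of any other substitution — the ideal diagnostic marker.
``homoeologue_discordant``
    the alien arm differs from A, but homoeologue B also carries a
    non-ancestral allele; a correct pipeline must reject these at the
    trio-concordance step.
``flank_contaminated``
    an alien-specific site with a second alien variant planted within
    ``flank_width``; a correct pipeline calls it alien-specific but must not
    promote it to a marker candidate. Both members of the pair are recorded
    with this class, since a per-site rescan cannot tell them apart.

Background substitutions are drawn per branch at the configured rates
everywhere outside planted flank windows; every background position where
the alien arm differs from homoeologue A is recorded with class
``background``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .dna import BASES, codes_to_seq, revcomp, seq_to_codes, write_fasta
from .reads import Read, write_fastq

FLANK_WIDTH_DEFAULT = 100

SITE_CLASSES = ("alien_specific", "homoeologue_discordant", "flank_contaminated", "background")


class SimulationSizingError(ValueError):
    """Requested planted sites cannot be placed at the required spacing."""


@dataclass(slots=True)
class SimulationConfig:
    """All knobs of the synthetic study.

    Defaults are the simulated study conditions used throughout the test
    suite: a 200-kb arm, homoeologue branches at 0.01 substitutions/site,
    an alien branch at 0.02, 100-bp single-end reads at 30-fold coverage
    with a 1e-3 per-base error rate and moderate lognormal amplification
    bias.
    """

    seed: int = 0
    ancestor_length: int = 200_000
    trio_divergence: float = 0.01
    alien_divergence: float = 0.02
    n_planted_specific: int = 150
    n_planted_discordant: int = 50
    n_planted_flank_contaminated: int = 30
    read_length: int = 100
    coverage: float = 30.0
    error_rate: float = 0.001
    coverage_bias_sd: float = 0.3
    low_quality_read_frac: float = 0.10
    low_tail_frac: float = 0.30
    max_tail_length: int = 10
    flank_width: int = FLANK_WIDTH_DEFAULT
    contig_length: int = 20_000

    def validate(self) -> None:
        for name in ("trio_divergence", "alien_divergence", "error_rate",
                     "low_quality_read_frac", "low_tail_frac"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        for name in ("ancestor_length", "read_length", "flank_width", "contig_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_planted_specific", "n_planted_discordant",
                     "n_planted_flank_contaminated"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.coverage_bias_sd < 0:
            raise ValueError("coverage_bias_sd must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)}, fh,
                           sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass(slots=True)
class TruthRecord:
    position: int  # 0-based on homoeologue A (= shared coordinates)
    site_class: str
    wheat_allele: str  # allele on homoeologue A
    alien_allele: str


@dataclass(slots=True)
class TruthTable:
    records: List[TruthRecord] = field(default_factory=list)

    def by_class(self, site_class: str) -> List[TruthRecord]:
        return [r for r in self.records if r.site_class == site_class]

    def positions(self, site_class: str) -> List[int]:
        return [r.position for r in self.records if r.site_class == site_class]

    def __len__(self) -> int:
        return len(self.records)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tclass\twheat_allele\talien_allele\n")
            for r in sorted(self.records, key=lambda r: r.position):
                fh.write(f"{r.position}\t{r.site_class}\t{r.wheat_allele}\t{r.alien_allele}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        records = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("position"):
                raise ValueError(f"unexpected truth-table header: {header!r}")
            for line in fh:
                pos, cls_, wa, aa = line.rstrip("\n").split("\t")
                records.append(TruthRecord(int(pos), cls_, wa, aa))
        return cls(records)


@dataclass(slots=True)
class SimulatedTrio:
    """Four evolved sequences plus the planted-site truth table."""

    homoeologues: Dict[str, str]  # keys homA, homB, homD
    alien: str
    truth: TruthTable
    config: SimulationConfig

    @property
    def anchor(self) -> str:
        return self.homoeologues["homA"]


def _pick_different(rng: np.random.Generator, code: int) -> int:
    """A uniformly random base code different from `code` (codes 0..3)."""
    return (code + int(rng.integers(1, 4))) % 4


def _place_planted_sites(rng: np.random.Generator, cfg: SimulationConfig,
                         n_total: int) -> np.ndarray:
    """Choose main planted positions: >= 2*flank from ends, pairwise gap > 2*flank."""
    fw = cfg.flank_width
    lo, hi = 2 * fw, cfg.ancestor_length - 2 * fw
    min_gap = 2 * fw + 1
    if n_total == 0:
        return np.empty(0, dtype=np.int64)
    if hi - lo < n_total * min_gap:
        raise SimulationSizingError(
            f"cannot place {n_total} sites with pairwise spacing > {2 * fw} "
            f"in a {cfg.ancestor_length}-bp sequence; increase ancestor_length"
        )
    # draw gaps: positions = lo + cumsum(min_gap + slack), slack multinomial-ish
    # via sorted uniforms over the leftover room — exact and rejection-free
    room = (hi - lo) - n_total * min_gap
    slack = np.sort(rng.integers(0, room + 1, size=n_total))
    positions = lo + slack + min_gap * np.arange(n_total)
    rng.shuffle(positions)  # class assignment slices must not correlate with coordinate
    return positions


def evolve_trio(config: SimulationConfig) -> SimulatedTrio:
    """Evolve ancestor -> (homA, homB, homD, alien) and plant the truth sites."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    L = config.ancestor_length
    fw = config.flank_width

    ancestor = rng.integers(0, 4, size=L, dtype=np.uint8)

    ns, nd, nfc = (config.n_planted_specific, config.n_planted_discordant,
                   config.n_planted_flank_contaminated)
    mains = _place_planted_sites(rng, config, ns + nd + nfc)
    specific_pos = mains[:ns]
    discordant_pos = mains[ns:ns + nd]
    contaminated_pos = mains[ns + nd:]

    # companion variants for flank-contaminated sites: within flank_width
    companions = np.empty(nfc, dtype=np.int64)
    for i, p in enumerate(contaminated_pos):
        offset = int(rng.integers(10, fw + 1))
        sign = 1 if rng.random() < 0.5 else -1
        companions[i] = p + sign * offset

    planted_all = np.concatenate([specific_pos, discordant_pos, contaminated_pos, companions])

    # exclusion mask: no background substitution within flank_width of any
    # planted position (nor at the position itself)
    excluded = np.zeros(L, dtype=bool)
    for p in planted_all:
        excluded[max(0, p - fw):min(L, p + fw + 1)] = True

    def _branch(rate: float) -> np.ndarray:
        seq = ancestor.copy()
        if rate > 0:
            hit = (rng.random(L) < rate) & ~excluded
            idx = np.flatnonzero(hit)
            shifts = rng.integers(1, 4, size=idx.size).astype(np.uint8)
            seq[idx] = (seq[idx] + shifts) % 4
        return seq

    hom_a = _branch(config.trio_divergence)
    hom_b = _branch(config.trio_divergence)
    hom_d = _branch(config.trio_divergence)
    alien = _branch(config.alien_divergence)

    records: List[TruthRecord] = []

    def _plant_alien_variant(p: int) -> Tuple[str, str]:
        w = int(hom_a[p])  # ancestral at planted sites (excluded from background)
        m = _pick_different(rng, w)
        alien[p] = m
        return BASES[w], BASES[m]

    for p in specific_pos:
        w, m = _plant_alien_variant(int(p))
        records.append(TruthRecord(int(p), "alien_specific", w, m))

    for p in discordant_pos:
        p = int(p)
        w, m = _plant_alien_variant(p)
        hom_b[p] = _pick_different(rng, int(hom_a[p]))  # break trio concordance
        records.append(TruthRecord(p, "homoeologue_discordant", w, m))

    for p, q in zip(contaminated_pos, companions):
        w, m = _plant_alien_variant(int(p))
        records.append(TruthRecord(int(p), "flank_contaminated", w, m))
        w2, m2 = _plant_alien_variant(int(q))
        records.append(TruthRecord(int(q), "flank_contaminated", w2, m2))

    planted_set = {r.position for r in records}
    background = np.flatnonzero(alien != hom_a)
    for p in background:
        p = int(p)
        if p in planted_set:
            continue
        records.append(TruthRecord(p, "background", BASES[int(hom_a[p])], BASES[int(alien[p])]))

    return SimulatedTrio(
        homoeologues={
            "homA": codes_to_seq(hom_a),
            "homB": codes_to_seq(hom_b),
            "homD": codes_to_seq(hom_d),
        },
        alien=codes_to_seq(alien),
        truth=TruthTable(records),
        config=config,
    )


def _body_quality(error_rate: float) -> int:
    """Phred score consistent with the simulated per-base error probability."""
    if error_rate <= 0:
        return 40
    return int(min(40, max(2, round(-10 * np.log10(error_rate)))))


LOW_QUAL = 2  # phred of junk tails and whole-low-quality reads (below the trim floor)


def generate_reads(arm: str, config: SimulationConfig) -> List[Read]:
    """Simulate single-end reads from the alien arm.

    The total read count is fixed at ``round(coverage * L / read_length)``
    and distributed over 1-kb start windows by a multinomial whose weights
    carry a lognormal multiplier (sd ``coverage_bias_sd``) emulating
    amplification bias. Strands are assigned by a balanced shuffled quota.
    Per-base errors flip to a uniformly random different base with
    probability ``error_rate``; body quality declares that error rate.
    A fraction of reads is emitted entirely at phred 2 (QC must discard
    them) and another fraction receives a short appended junk tail at
    phred 2 (QC must trim it).
    """
    config.validate()
    L = len(arm)
    rl = config.read_length
    if rl > L:
        raise ValueError(f"read_length {rl} exceeds arm length {L}")
    rng = np.random.default_rng([config.seed, 1])

    n_total = int(round(config.coverage * L / rl))
    n_starts = L - rl + 1

    window = 1_000
    win_lo = np.arange(0, n_starts, window)
    win_hi = np.minimum(win_lo + window, n_starts)
    weights = (win_hi - win_lo).astype(float)
    if config.coverage_bias_sd > 0:
        weights *= rng.lognormal(0.0, config.coverage_bias_sd, size=weights.size)
    probs = weights / weights.sum()
    per_window = rng.multinomial(n_total, probs)

    starts = np.concatenate([
        rng.integers(lo, hi, size=k)
        for lo, hi, k in zip(win_lo, win_hi, per_window)
    ]) if n_total else np.empty(0, dtype=np.int64)
    rng.shuffle(starts)

    n_fwd = (n_total + 1) // 2
    strands = np.array(["+"] * n_fwd + ["-"] * (n_total - n_fwd))
    rng.shuffle(strands)

    arm_codes = seq_to_codes(arm)
    q_body = _body_quality(config.error_rate)
    junk = BASES

    reads: List[Read] = []
    for i in range(n_total):
        s = int(starts[i])
        codes = arm_codes[s:s + rl].copy()
        if config.error_rate > 0:
            err = rng.random(rl) < config.error_rate
            idx = np.flatnonzero(err)
            if idx.size:
                shifts = rng.integers(1, 4, size=idx.size).astype(np.uint8)
                codes[idx] = (codes[idx] + shifts) % 4
        bases = codes_to_seq(codes)
        if strands[i] == "-":
            bases = revcomp(bases)
        quals = np.full(len(bases), q_body, dtype=np.int16)

        u = rng.random()
        if u < config.low_quality_read_frac:
            quals[:] = LOW_QUAL
        elif u < config.low_quality_read_frac + config.low_tail_frac:
            tail_len = int(rng.integers(1, config.max_tail_length + 1))
            tail = "".join(junk[int(c)] for c in rng.integers(0, 4, size=tail_len))
            bases = bases + tail
            quals = np.concatenate([quals, np.full(tail_len, LOW_QUAL, dtype=np.int16)])
        reads.append(Read(f"r{i:06d}", bases, quals))
    return reads


def slice_contigs(seq: str, contig_length: int, min_length: int = 200,
                  prefix: str = "ctg") -> Dict[str, str]:
    """Cut a sequence into consecutive fixed-size pieces, emulating a de-novo assembly."""
    contigs: Dict[str, str] = {}
    n = 0
    for start in range(0, len(seq), contig_length):
        piece = seq[start:start + contig_length]
        if len(piece) >= min_length:
            n += 1
            contigs[f"{prefix}{n:05d}"] = piece
    return contigs


def write_outputs(sim: SimulatedTrio, out_dir: str | Path,
                  reads: Optional[List[Read]] = None,
                  contigs: bool = True) -> Dict[str, Path]:
    """Write FASTA/FASTQ/TSV/YAML artefacts of one simulation; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for name, seq in sim.homoeologues.items():
        p = out / f"{name}.fasta"
        write_fasta(p, {name: seq})
        paths[name] = p
    paths["alien"] = out / "alien_arm.fasta"
    write_fasta(paths["alien"], {"alien_arm": sim.alien})
    if contigs:
        paths["contigs"] = out / "alien_contigs.fasta"
        write_fasta(paths["contigs"], slice_contigs(sim.alien, sim.config.contig_length))
    paths["truth"] = out / "truth.tsv"
    sim.truth.to_tsv(paths["truth"])
    if reads is None:
        reads = generate_reads(sim.alien, sim.config)
    paths["reads"] = out / "reads.fastq"
    write_fastq(paths["reads"], reads)
    paths["config"] = out / "config.yaml"
    sim.config.to_yaml(paths["config"])
    return paths


# ---------------------------------------------------------------------------
# genotype-panel simulation for introgression-mapping tests


def simulate_panel(
    marker_coords: Sequence[int],
    n_whole_arm: int = 2,
    n_translocation: int = 8,
    n_null: int = 2,
    seed: int = 0,
) -> Tuple["pd.DataFrame", Dict[str, Optional[Tuple[int, int]]]]:
    """Clean genotype calls for a panel of lines over ordered markers.

    Whole-arm lines (addition/substitution-like) are heterozygous at every
    marker; translocation lines carry a terminal (distal) alien segment from
    a random breakpoint to the last marker; null lines carry no alien
    chromatin. Returns a wide calls DataFrame (rows = lines, columns =
    marker ids m0001..) and per-line truth segments as inclusive marker-index
    pairs (None for null lines).
    """
    import pandas as pd

    rng = np.random.default_rng([seed, 2])
    m = len(marker_coords)
    if m < 2:
        raise ValueError("need at least two markers")
    marker_ids = [f"m{i + 1:04d}" for i in range(m)]
    rows = {}
    truth: Dict[str, Optional[Tuple[int, int]]] = {}
    ln = 0
    for _ in range(n_whole_arm):
        ln += 1
        line = f"line{ln:02d}_whole"
        rows[line] = ["HET"] * m
        truth[line] = (0, m - 1)
    for _ in range(n_translocation):
        ln += 1
        line = f"line{ln:02d}_trans"
        # breakpoint: alien from marker k to the end; a translocation retains a
        # real wheat stub (>10% of markers), else it would be a whole-arm line
        k_min = int(0.1 * m) + 1
        k = int(rng.integers(k_min, m))
        rows[line] = ["WHEAT_HOM"] * k + ["HET"] * (m - k)
        truth[line] = (k, m - 1)
    for _ in range(n_null):
        ln += 1
        line = f"line{ln:02d}_null"
        rows[line] = ["WHEAT_HOM"] * m
        truth[line] = None
    calls = pd.DataFrame.from_dict(rows, orient="index", columns=marker_ids)
    return calls, truth
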
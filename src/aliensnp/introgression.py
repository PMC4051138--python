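"""Line classification and alien-segment delineation from marker genotypes.

Alien-specific markers genotyped on a wheat background read heterozygous
wherever alien chromatin is present together with the wheat homoeologues
(the wheat copies contribute the wheat allele, the alien segment the alien
allele). Whole-arm carriers (addition or substitution lines) are therefore
heterozygous at essentially every marker, translocation lines only across
the introgressed interval, and alien-free lines at none. Both HET and
ALIEN_HOM count as alien-positive, since allele dosage varies with how many
wheat homoeologues remain.

Segments are maximal runs of alien-positive calls along marker order;
``noise_tolerance`` interior non-alien calls may be absorbed per run.
MISSING calls neither support nor interrupt a run. Physical breakpoints
between markers are unobservable, so segment bounds are reported both as
marker indices and as half-open anchor-coordinate intervals extending to
the next marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

CALL_VALUES = ("WHEAT_HOM", "HET", "ALIEN_HOM", "MISSING")
_ALIEN_POSITIVE = {"HET", "ALIEN_HOM"}
_MISSING_TOKENS = {"NA", ".", "", "MISSING"}

CLASS_NO_ALIEN = "NO_ALIEN"
CLASS_WHOLE_ARM = "WHOLE_ARM"
CLASS_PARTIAL = "PARTIAL"
CLASS_UNCALLED = "UNCALLED"


@dataclass(slots=True)
class GenotypeTable:
    """Per-(line, marker) genotype calls with markers ordered by anchor coordinate."""

    lines: List[str]
    markers: List[str]
    coords: List[int]  # anchor coordinate per marker, strictly increasing
    calls: pd.DataFrame  # index = lines, columns = markers, values in CALL_VALUES

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.coords, self.coords[1:])):
            raise ValueError("marker coordinates must be strictly increasing")
        bad = set(np.unique(self.calls.values)) - set(CALL_VALUES)
        if bad:
            raise ValueError(f"invalid genotype calls: {sorted(bad)}")


@dataclass(slots=True)
class Segment:
    start_marker: int  # marker indices, inclusive
    end_marker: int
    start_coord: int  # anchor coordinates, half-open
    end_coord: int


@dataclass(slots=True)
class LineResult:
    line: str
    line_class: str
    alien_fraction: float
    segments: List[Segment] = field(default_factory=list)


@dataclass(slots=True)
class IntrogressionReport:
    lines: List[LineResult]

    def by_line(self) -> Dict[str, LineResult]:
        return {r.line: r for r in self.lines}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("line\tclass\talien_fraction\tn_segments\tsegments\n")
            for r in self.lines:
                segs = ";".join(f"{s.start_marker}-{s.end_marker}" for s in r.segments)
                frac = "NA" if np.isnan(r.alien_fraction) else f"{r.alien_fraction:.4f}"
                fh.write(f"{r.line}\t{r.line_class}\t{frac}\t{len(r.segments)}\t{segs}\n")

    def to_bed(self, path: str | Path, anchor_ref: str = "anchor") -> None:
        with open(path, "w") as fh:
            for r in self.lines:
                for s in r.segments:
                    fh.write(f"{anchor_ref}\t{s.start_coord}\t{s.end_coord}\t{r.line}\n")


def genotype_from_counts(
    wheat_counts: pd.DataFrame,
    alien_counts: pd.DataFrame,
    coords: Sequence[int],
    min_depth: int = 4,
    het_band: Tuple[float, float] = (0.2, 0.8),
) -> GenotypeTable:
    """Call genotypes from per-(line, marker) wheat/alien allele read counts.

    MISSING below ``min_depth`` total reads; WHEAT_HOM at alien fraction
    <= ``het_band[0]``; ALIEN_HOM at >= ``het_band[1]``; HET between.
    """
    if not wheat_counts.index.equals(alien_counts.index) or \
       not wheat_counts.columns.equals(alien_counts.columns):
        raise ValueError("wheat and alien count tables must share lines and markers")
    total = wheat_counts.values + alien_counts.values
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, alien_counts.values / np.maximum(total, 1), 0.0)
    calls = np.full(total.shape, "HET", dtype=object)
    calls[frac <= het_band[0]] = "WHEAT_HOM"
    calls[frac >= het_band[1]] = "ALIEN_HOM"
    calls[total < min_depth] = "MISSING"
    df = pd.DataFrame(calls, index=wheat_counts.index, columns=wheat_counts.columns)
    return GenotypeTable(list(df.index), list(df.columns), list(coords), df)


def _segments_for_line(calls: Sequence[str], coords: Sequence[int],
                       noise_tolerance: int) -> List[Segment]:
    positives = [i for i, c in enumerate(calls) if c in _ALIEN_POSITIVE]
    if not positives:
        return []
    runs: List[Tuple[int, int]] = []
    run_start = prev = positives[0]
    used = 0
    for i in positives[1:]:
        gap_cost = sum(1 for j in range(prev + 1, i) if calls[j] == "WHEAT_HOM")
        if used + gap_cost <= noise_tolerance:
            used += gap_cost
            prev = i
        else:
            runs.append((run_start, prev))
            run_start = prev = i
            used = 0
    runs.append((run_start, prev))
    m = len(calls)
    segments = []
    for a, b in runs:
        end_coord = coords[b + 1] if b + 1 < m else coords[b] + 1
        segments.append(Segment(a, b, coords[a], end_coord))
    return segments


def classify_lines(table: GenotypeTable, whole_arm_min: float = 0.9,
                   noise_tolerance: int = 0) -> IntrogressionReport:
    """Classify each line and delineate its alien segments.

    NO_ALIEN at alien fraction 0; WHOLE_ARM at fraction >= ``whole_arm_min``
    (addition/substitution-like); PARTIAL otherwise (translocation-like);
    UNCALLED when every call is MISSING. The alien fraction is computed over
    non-missing calls only.
    """
    results: List[LineResult] = []
    for line in table.lines:
        calls = list(table.calls.loc[line])
        non_missing = [c for c in calls if c != "MISSING"]
        if not non_missing:
            results.append(LineResult(line, CLASS_UNCALLED, float("nan")))
            continue
        n_pos = sum(1 for c in non_missing if c in _ALIEN_POSITIVE)
        frac = n_pos / len(non_missing)
        if n_pos == 0:
            cls = CLASS_NO_ALIEN
        elif frac >= whole_arm_min:
            cls = CLASS_WHOLE_ARM
        else:
            cls = CLASS_PARTIAL
        segments = _segments_for_line(calls, table.coords, noise_tolerance)
        results.append(LineResult(line, cls, frac, segments))
    return IntrogressionReport(results)


@dataclass(slots=True)
class PanelComparison:
    line: str
    exact_match: bool
    breakpoint_error: float  # marker intervals; inf when segment counts differ


def compare_panels(report: IntrogressionReport,
                   truth_segments: Dict[str, Optional[Tuple[int, int]]]
                   ) -> List[PanelComparison]:
    """Evaluate inferred segments against truth (inclusive marker-index pairs).

    Breakpoint error is the largest distance, in marker intervals, between
    an inferred segment end and its true counterpart; lines whose inferred
    and true segment counts differ get error inf.
    """
    out: List[PanelComparison] = []
    for r in report.lines:
        truth = truth_segments.get(r.line)
        true_list = [] if truth is None else [truth]
        if len(r.segments) != len(true_list):
            out.append(PanelComparison(r.line, False, float("inf")))
            continue
        if not true_list:
            out.append(PanelComparison(r.line, True, 0.0))
            continue
        err = 0
        for seg, (ts, te) in zip(r.segments, true_list):
            err = max(err, abs(seg.start_marker - ts), abs(seg.end_marker - te))
        out.append(PanelComparison(r.line, err == 0, float(err)))
    return out


def read_genotype_table(path: str | Path, marker_coords: Dict[str, int]
                        ) -> GenotypeTable:
    """Read a wide genotype TSV (first column line id, one column per marker).

    Marker columns are reordered by anchor coordinate; NA/./empty cells
    become MISSING. Markers without a coordinate in ``marker_coords`` are
    rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    unknown = [m for m in df.columns if m not in marker_coords]
    if unknown:
        raise ValueError(f"markers without coordinates: {unknown}")
    ordered = sorted(df.columns, key=lambda m: marker_coords[m])
    df = df[ordered]
    df = df.apply(lambda col: col.map(
        lambda v: "MISSING" if v.strip() in _MISSING_TOKENS else v.strip()))
    return GenotypeTable(list(df.index), ordered,
                         [marker_coords[m] for m in ordered], df)


def table_from_calls(calls: pd.DataFrame, coords: Sequence[int]) -> GenotypeTable:
    """Wrap a wide calls DataFrame (e.g. from the panel simulator) as a GenotypeTable."""
    return GenotypeTable(list(calls.index), list(calls.columns), list(coords), calls)
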
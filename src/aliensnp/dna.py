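"""Small DNA sequence helpers shared across the pipeline.

Sequences are plain upper-case strings over the alphabet ACGTN; for numeric
work they are encoded as ``numpy`` ``uint8`` code arrays (A=0, C=1, G=2,
T=3, N=4). All coordinates in this package are 0-based half-open; conversion
to 1-based happens only when writing VCF, BED neighbours or marker sheets.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
N_CODE = 4

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# 256-entry lookup so byte buffers can be translated in one vector op
_CODE_LUT = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i

_CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 code array (A=0..T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[raw]


def codes_to_seq(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Load a FASTA file into an ordered {record id: upper-case sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, dict) else records
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(recs, str(path), "fasta")
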
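"""Small DNA-sequence utilities shared by the motif and homology stages."""

from __future__ import annotations

from typing import Sequence

import numpy as np
from pyfaidx import Fasta

from .intervals import GenomicInterval

BASES = "ACGT"
_ENC = np.full(256, 4, dtype=np.uint8)  # everything unknown -> 4 (N)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> 4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def extract_sequences(fasta_path, intervals: Sequence[GenomicInterval]) -> dict[str, str]:
    """Uppercase sequences of intervals from an indexed FASTA, keyed by name."""
    fa = Fasta(str(fasta_path))
    out = {}
    for iv in intervals:
        out[iv.name] = str(fa[iv.chrom][iv.start:iv.end]).upper()
    return out
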
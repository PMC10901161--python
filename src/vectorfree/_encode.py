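"""2-bit DNA encoding shared by the simulator and the k-mer scanner.

Bases map A=0, C=1, G=2, T=3; anything else maps to the sentinel 4 so that
k-mers containing ambiguous bases can be invalidated cheaply.
"""
from __future__ import annotations

import numpy as np

SENTINEL = 4

_ENC = np.full(256, SENTINEL, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENC[b] = i
    _ENC[b + 32] = i  # lower case

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 array (A=0,C=1,G=2,T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC[raw]


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (non-ACGT characters unchanged)."""
    return seq.translate(_COMP)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement on the 2-bit encoding; the sentinel stays sentinel."""
    out = (3 - codes[..., ::-1]).astype(np.uint8)
    out[codes[..., ::-1] == SENTINEL] = SENTINEL
    return out
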
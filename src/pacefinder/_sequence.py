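"""Low-level DNA encoding helpers shared by the simulation, discovery and
scanning modules.

Bases are coded A=0, C=1, G=2, T=3; anything else (N, soft-mask leftovers
after upper-casing, IUPAC ambiguity codes) is coded 4 and poisons every
window that covers it.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as an int8 array (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case-insensitively to uppercase-like map."""
    return seq.translate(_COMPLEMENT)[::-1]


def require_acgt(seq: str, *, what: str = "sequence") -> np.ndarray:
    codes = encode(seq)
    if (codes > 3).any():
        raise ValueError(f"{what} contains non-ACGT characters")
    return codes


def window_codes(codes: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """All length-w windows of a coded sequence.

    Returns (windows, valid): windows is an (m, w) int8 view, valid a boolean
    mask flagging windows free of non-ACGT codes. m = len - w + 1 (empty for
    sequences shorter than w).
    """
    n = codes.shape[0]
    if n < w:
        return (np.empty((0, w), dtype=np.int8), np.empty(0, dtype=bool))
    win = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = ~(win > 3).any(axis=1)
    return win, valid
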
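"""Nucleotide encoding helpers shared across modules.

Bases A, C, G, T are coded 0..3 (lexicographic, so integer order of k-mer
codes equals lexicographic order of the k-mers); the ambiguity code N is
kept as 4 and invalidates any window it falls in.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

BASES = "ACGT"
N_CODE = 4

_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i
_LUT[ord("N")] = N_CODE
_LUT[ord("n")] = N_CODE


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes (A,C,G,T -> 0..3; N -> 4).

    Raises ValueError naming the offending character for anything else.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _LUT[raw]
    if (codes < 0).any():
        bad = seq[int(np.argmax(codes < 0))]
        raise ValueError(f"invalid nucleotide character {bad!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    out = np.empty(codes.size, dtype=np.uint8)
    for i, b in enumerate(BASES + "N"):
        out[codes == i] = ord(b)
    return out.tobytes().decode("ascii")


def kmer_to_code(word: str) -> int:
    """Integer code of an N-free k-mer (base-4, A=0..T=3)."""
    code = 0
    for ch in word:
        v = _LUT[ord(ch)]
        if v < 0 or v == N_CODE:
            raise ValueError(f"k-mer {word!r} is not over {{A,C,G,T}}")
        code = code * 4 + int(v)
    return code


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 codes and validity of every length-k window of a coded sequence.

    Returns (vals, valid) of length len(codes)-k+1; vals are meaningful only
    where valid (no N in the window).  Empty arrays when the sequence is
    shorter than k.
    """
    if codes.size < k:
        e = np.empty(0, dtype=np.int64)
        return e, np.empty(0, dtype=bool)
    win = sliding_window_view(codes, k)
    valid = (win != N_CODE).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = win.astype(np.int64) @ powers
    return vals, valid


def kmer_counts(codes: np.ndarray, k: int) -> np.ndarray:
    """Counts of all 4**k k-mers over valid (N-free) windows."""
    vals, valid = window_codes(codes, k)
    if vals.size == 0:
        return np.zeros(4**k, dtype=np.int64)
    return np.bincount(vals[valid], minlength=4**k)


def valid_window_count(codes: np.ndarray, k: int) -> int:
    """Number of N-free length-k windows."""
    _, valid = window_codes(codes, k)
    return int(valid.sum())
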
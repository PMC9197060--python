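"""Low-level DNA sequence utilities shared across the pipeline.

Sequences travel as Python strings at module boundaries and as uint8 code
arrays (A=0, C=1, G=2, T=3, N=4) inside the numeric kernels.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 code array (A=0 C=1 G=2 T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def rotate(seq: str, offset: int) -> str:
    """Circular left rotation: ``rotate(s, k)[0] == s[k % len(s)]``."""
    if not seq:
        return seq
    offset %= len(seq)
    return seq[offset:] + seq[:offset]


def homopolymer_runs(codes: np.ndarray, min_len: int = 3) -> np.ndarray:
    """Boolean mask of positions inside a homopolymer run of >= min_len."""
    n = codes.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    # run-length encode
    change = np.empty(n, dtype=bool)
    change[0] = True
    np.not_equal(codes[1:], codes[:-1], out=change[1:])
    run_id = np.cumsum(change) - 1
    run_len = np.bincount(run_id)
    return run_len[run_id] >= min_len
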
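"""Small sequence/encoding helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_LOOKUP = np.frombuffer(b"ACGT", dtype=np.uint8)


def seq_to_u8(seq: str) -> np.ndarray:
    """ASCII byte view of a sequence (no copy of semantics, cheap compares)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def u8_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer codes (base-4) -> (n, k) uint8 ASCII matrix, 5'-first digits."""
    codes = np.asarray(codes, dtype=np.uint64)
    out = np.empty((codes.size, k), dtype=np.uint8)
    for j in range(k - 1, -1, -1):
        out[:, j] = _BASE_LOOKUP[(codes & np.uint64(3)).astype(np.intp)]
        codes = codes >> np.uint64(2)
    return out


def kmer_strings(codes: np.ndarray, k: int) -> np.ndarray:
    mat = encode_kmers(codes, k)
    return mat.view(f"S{k}").ravel().astype(str)


def decode_kmer(kmer: str) -> int:
    code = 0
    for ch in kmer:
        code = (code << 2) | "ACGT".index(ch)
    return code
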
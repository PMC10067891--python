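"""Lossless binary <-> DNA payload mapping.

Each byte maps to four quaternary digits, most-significant bit pair
first, and each digit to a base under A-0, T-1, C-2, G-3; so output
length is exactly 4x the byte count and the round trip is exact.  The
codec performs *raw* payload mapping only: it does not enforce coding
constraints, and packaging payloads onto constraint-satisfying codeword
sets is out of scope.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .code_search import DIGIT_BASES

__all__ = ["encode_bytes", "decode_bases", "encode_file", "decode_file"]

_BASE_OF_DIGIT = np.frombuffer(DIGIT_BASES.encode(), dtype=np.uint8)
_DIGIT_OF_BASE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(DIGIT_BASES):
    _DIGIT_OF_BASE[ord(_b)] = _i


def encode_bytes(data: bytes) -> str:
    """DNA representation of a byte string (4 bases per byte)."""
    if not data:
        return ""
    b = np.frombuffer(bytes(data), dtype=np.uint8)
    digits = np.empty((len(b), 4), dtype=np.uint8)
    digits[:, 0] = (b >> 6) & 3
    digits[:, 1] = (b >> 4) & 3
    digits[:, 2] = (b >> 2) & 3
    digits[:, 3] = b & 3
    return _BASE_OF_DIGIT[digits.ravel()].tobytes().decode()


def decode_bases(x: str) -> bytes:
    """Exact inverse of :func:`encode_bytes`."""
    if not x:
        return b""
    if len(x) % 4:
        raise ValueError(
            f"sequence length {len(x)} is not a multiple of 4 "
            "(framing error: each byte spans 4 bases)"
        )
    arr = np.frombuffer(x.upper().encode(), dtype=np.uint8)
    digits = _DIGIT_OF_BASE[arr]
    if np.any(digits == 255):
        bad = x[int(np.argmax(digits == 255))]
        raise ValueError(f"invalid DNA symbol {bad!r} in payload")
    d = digits.reshape(-1, 4).astype(np.uint8)
    b = (d[:, 0] << 6) | (d[:, 1] << 4) | (d[:, 2] << 2) | d[:, 3]
    return b.tobytes()


def encode_file(in_path: str | Path, out_path: str | Path) -> int:
    """Encode an arbitrary file to a single wrapped FASTA record.

    Returns the number of bases written.
    """
    data = Path(in_path).read_bytes()
    seq = encode_bytes(data)
    rec = SeqRecord(
        Seq(seq),
        id=Path(in_path).name,
        description=f"payload_bytes={len(data)}",
    )
    SeqIO.write([rec], str(out_path), "fasta")
    return len(seq)


def decode_file(in_path: str | Path, out_path: str | Path) -> int:
    """Decode a FASTA payload (records concatenated in order) to bytes.

    Returns the number of bytes written.
    """
    seq = "".join(
        str(rec.seq) for rec in SeqIO.parse(str(in_path), "fasta")
    )
    data = decode_bases(seq)
    Path(out_path).write_bytes(data)
    return len(data)
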
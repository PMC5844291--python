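"""Low-level DNA encoding helpers shared across the package.

Sequences are held as numpy uint8 code arrays (A=0, C=1, G=2, T=3) so that
read simulation, Hamming scoring and pileup accumulation vectorise.
"""

from __future__ import annotations

import numpy as np

BASES = b"ACGT"
_BASE_ARR = np.frombuffer(BASES, dtype=np.uint8)

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i  # lower case

# complement of code i is 3 - i under the A,C,G,T ordering
COMPLEMENT_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)

STOP_CODONS = ("TAA", "TAG", "TGA")


def encode(seq: str | bytes) -> np.ndarray:
    """Encode an ACGT string into a uint8 code array."""
    raw = seq.encode() if isinstance(seq, str) else seq
    codes = _ENC[np.frombuffer(raw, dtype=np.uint8)]
    if codes.size and codes.max() > 3:
        bad = chr(raw[int(np.argmax(codes > 3))])
        raise ValueError(f"non-ACGT character in sequence: {bad!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into an ACGT string."""
    return _BASE_ARR[codes].tobytes().decode()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return COMPLEMENT_CODE[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))
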
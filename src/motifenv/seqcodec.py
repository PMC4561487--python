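"""Integer encoding of DNA sequences.

The alphabet order A, C, G, T (codes 0..3) is fixed throughout the
package; code 4 marks an undefined base (N in genomic input, or a
position outside a probe in a padded alignment frame).
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
N_CODE = 4

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement of A,C,G,T is T,G,C,A; N stays N
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 array (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; undefined codes render as N."""
    return _DECODE[np.minimum(codes, N_CODE)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of an encoded sequence (last axis)."""
    return _COMPLEMENT[codes][..., ::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def gc_indicator(codes: np.ndarray) -> np.ndarray:
    """Float array: 1.0 where base is G or C, 0.0 for A/T, NaN where undefined."""
    out = np.where((codes == 1) | (codes == 2), 1.0, 0.0)
    return np.where(codes == N_CODE, np.nan, out)
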
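"""Small shared helpers."""

from __future__ import annotations

import math

import numpy as np

#: Alignment alphabet, in the internal code order used by the decomposer.
STATES = "ACGT-N"
_CODE_OF = {ord(c): i for i, c in enumerate(STATES)}

_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in _CODE_OF.items():
    _LUT[_b] = _i


def encode_alignment(seqs) -> np.ndarray:
    """Encode equal-length gapped sequences as a (n, width) uint8 code matrix.

    Codes follow :data:`STATES` (A=0, C=1, G=2, T=3, '-'=4, N=5).
    """
    if len(seqs) == 0:
        return np.empty((0, 0), dtype=np.uint8)
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    mat = _LUT[raw].reshape(len(seqs), -1)
    if (mat == 255).any():
        bad = sorted({chr(b) for b in raw[_LUT[raw] == 255]})
        raise ValueError(f"sequence contains characters outside {STATES!r}: {bad}")
    return mat


def decode_row(row: np.ndarray) -> str:
    return "".join(STATES[c] for c in row)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (report convention; Python's round is half-even)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def spawn_rngs(seed: int | None, n: int) -> list[np.random.Generator]:
    """Deterministically derive n independent generators from one seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]
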
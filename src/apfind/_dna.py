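"""Low-level nucleotide helpers shared by the simulator, forge, and toy aligner.

Sequences are plain Python strings over {A,C,G,T,N} at the API surface and
numpy uint8 code arrays (A=0, C=1, G=2, T=3, N=4) internally.
"""

from __future__ import annotations

import numpy as np

BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

# ASCII -> code lookup; anything unexpected maps to the N code.
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _ENC[_b] = _i
for _i, _b in enumerate(b"acgtn"):
    _ENC[_b] = _i

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """String -> uint8 code array."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """uint8 code array -> string."""
    return _DEC[codes].tobytes().decode("ascii")


def random_sequence(length: int, gc_content: float, rng: np.random.Generator) -> str:
    """I.i.d. sequence with the requested expected GC fraction."""
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at]).astype(np.uint8)
    return decode(codes)


def gc_fraction(seq: str) -> float:
    codes = encode(seq)
    return float(np.mean((codes == 1) | (codes == 2)))
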
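"""Tiny shared sequence helpers (kept dependency-light; hot paths use numpy)."""

from __future__ import annotations

import numpy as np

DNA = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# numeric encoding used by the word scanners: A=0 C=1 G=2 T=3, anything else = 4
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(DNA):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A0 C1 G2 T3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return "".join(DNA[c] for c in codes)


def mutate(rng: np.random.Generator, seq: str, rate: float,
           protect: tuple[int, int] | None = None) -> str:
    """Apply i.i.d. substitutions at `rate` per nt; `protect` is a half-open
    interval left untouched (used for the conserved transcript window)."""
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    if protect is not None:
        hit[protect[0]:protect[1]] = False
    idx = np.nonzero(hit)[0]
    for i in idx:
        old = chr(arr[i])
        choices = [b for b in DNA if b != old]
        arr[i] = ord(choices[rng.integers(3)])
    return arr.tobytes().decode("ascii")
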
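"""Small sequence utilities shared by layout design and index counting."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest single-base run in ``seq``."""
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best if seq else 0


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    """Apply independent per-base substitution errors at ``error_rate``."""
    if error_rate <= 0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
    for i in hits:
        alt = BASES.replace(out[i], "")
        out[i] = alt[rng.integers(0, 3)]
    return "".join(out)
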
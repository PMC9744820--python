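"""Small sequence/RNG helpers shared across the package."""

from __future__ import annotations

import numpy as np

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_RC)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def mismatch_positions(a: str, b: str) -> list[int]:
    """1-based positions where ``a`` and ``b`` differ (5'->3')."""
    if len(a) != len(b):
        raise ValueError("mismatch_positions requires equal-length strings")
    return [i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y]


def spawn_rng(seed: int, *key: str) -> np.random.Generator:
    """Derive an independent generator from a root seed and a string key.

    Keys keep sub-streams decoupled, so e.g. adding reads to the edited
    library cannot shift the wild-type control stream.
    """
    child = [abs(hash_str(k)) % (2**31) for k in key]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *child]))


def hash_str(s: str) -> int:
    # stable across processes (builtin hash() is salted)
    h = 2166136261
    for ch in s.encode():
        h = (h ^ ch) * 16777619 % (2**32)
    return h


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    idx = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return "".join(BASES[i] for i in idx)


def apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute bases independently at ``rate``; never emits the original base."""
    if rate <= 0.0 or not seq:
        return seq
    n = len(seq)
    hits = np.flatnonzero(rng.random(n) < rate)
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        alt = [b for b in BASES if b != out[i]]
        out[i] = alt[rng.integers(3)]
    return "".join(out)
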
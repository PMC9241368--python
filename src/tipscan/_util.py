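"""Small shared helpers: DNA utilities and deterministic RNG spawning."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")

DNA_ALPHABET = b"ACGT"


def revcomp(seq: str | bytes) -> str | bytes:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    if isinstance(seq, str):
        return seq.encode()[::-1].translate(_COMPLEMENT).decode()
    return seq[::-1].translate(_COMPLEMENT)


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform-random ACGT string of the given length."""
    return rng.choice(np.frombuffer(DNA_ALPHABET, dtype=np.uint8), size=length).tobytes().decode()


def mutate_substitutions(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Apply i.i.d. substitutions at the given per-base rate.

    Every substituted base is drawn from the three alternatives, so ``rate``
    is the realized per-base divergence in expectation.
    """
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    idx = np.flatnonzero(hit)
    if idx.size:
        bases = np.frombuffer(DNA_ALPHABET, dtype=np.uint8)
        # pick one of the 3 bases different from the current one
        offsets = rng.integers(1, 4, size=idx.size)
        cur = np.searchsorted(bases, arr[idx])
        # non-ACGT characters (e.g. N) are left untouched
        ok = (cur < 4) & (bases[np.clip(cur, 0, 3)] == arr[idx])
        arr[idx[ok]] = bases[(cur[ok] + offsets[ok]) % 4]
    return arr.tobytes().decode()


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators deterministically from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
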
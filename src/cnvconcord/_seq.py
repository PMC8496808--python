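"""Low-level sequence helpers: random DNA, reverse complement, GC, mutation.

All sequences are plain Python ``str`` over the alphabet {A,C,G,T,N}.
"""

from __future__ import annotations

import zlib

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent RNG stream for one named pipeline stage.

    The stream depends only on (seed, stage), so adding a stage never
    perturbs the draws of existing ones.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    )


def random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def mutate(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    protected: list[tuple[int, int]] | None = None,
) -> str:
    """Apply i.i.d. substitutions at ``rate`` per base, skipping protected windows.

    A substituted base is always different from the original.
    """
    if rate <= 0 or not seq:
        return seq
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(seq)) < rate
    if protected:
        for lo, hi in protected:
            hit[max(lo, 0) : min(hi, len(seq))] = False
    idx = np.nonzero(hit)[0]
    if idx.size == 0:
        return seq
    lut = np.zeros(256, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    old = lut[codes[idx]]
    new = (old + rng.integers(1, 4, size=idx.size)) % 4
    codes[idx] = _BASES.view(np.uint8)[new]
    return codes.tobytes().decode("ascii")
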
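"""Small sequence utilities used by the simulator and the breakpoint genotyper."""

from __future__ import annotations

import numpy as np

_BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_sequence(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, 4, size=length)
    return _BASE_BYTES[idx].tobytes().decode("ascii")


def seq_to_array(seq: str) -> np.ndarray:
    """Sequence as a uint8 array of ASCII codes (vectorised comparisons)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def mutate_bases(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Apply i.i.d. substitutions at the given per-base rate.

    Each hit base is replaced by one of the three other bases uniformly, so a
    mutated position always differs from the original.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"substitution rate must be in [0,1], got {rate}")
    if rate == 0.0 or not seq:
        return seq
    arr = seq_to_array(seq).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    if hits.size:
        # shift 1..3 positions within ACGT, guaranteed != original
        cur = np.searchsorted(_BASE_BYTES, arr[hits])
        shift = rng.integers(1, 4, size=hits.size)
        arr[hits] = _BASE_BYTES[(cur + shift) % 4]
    return array_to_seq(arr)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return int(np.count_nonzero(seq_to_array(a) != seq_to_array(b)))
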
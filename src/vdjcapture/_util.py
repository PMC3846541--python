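"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def count_mismatches(a: str, b: str, limit: int | None = None) -> int:
    """Hamming distance between equal-length strings; N never matches.

    Stops early once ``limit`` is exceeded (returns limit + 1).
    """
    if len(a) != len(b):
        raise ValueError("count_mismatches requires equal-length strings")
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if limit is not None and mm > limit:
                return mm
    return mm


def validate_dna(seq: str, allow_n: bool = True) -> None:
    allowed = set("ACGTN" if allow_n else "ACGT")
    bad = set(seq.upper()) - allowed
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")


_DNA_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA of length n."""
    if n <= 0:
        return ""
    return _DNA_BYTES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def longest_common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def longest_common_suffix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or book-ended half-open intervals."""
    if not intervals:
        return []
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out
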
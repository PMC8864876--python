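"""Shared fixtures and the independent alignment oracle."""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path

import numpy as np
import pytest

from ccsfilt.adapters import builtin_adapters
from ccsfilt.io_formats import SeqRead


def brute_force_local_score(
    query: str,
    target: str,
    match: int = 1,
    mismatch: int = -5,
    gap_open: int = 3,
    gap_ext: int = 3,
):
    """Exhaustive maximum local-alignment score, or None if <= 0.

    Independent of the DP implementation: every local alignment is a
    monotone chain of aligned (match/mismatch) column pairs with affine
    gap runs between consecutive pairs (a gap of length k costs
    gap_open + k * gap_ext); terminal gaps never raise a local score.
    The recursion enumerates all chains.
    """

    def gap(k: int) -> int:
        return 0 if k == 0 else gap_open + gap_ext * k

    n, m = len(query), len(target)

    @lru_cache(maxsize=None)
    def from_pair(i: int, j: int) -> int:
        s = match if (query[i] == target[j] and query[i] in "ACGT") else mismatch
        best_ext = 0
        for i2 in range(i + 1, n):
            for j2 in range(j + 1, m):
                c = from_pair(i2, j2) - gap(i2 - i - 1) - gap(j2 - j - 1)
                if c > best_ext:
                    best_ext = c
        return s + best_ext

    best = max((from_pair(i, j) for i in range(n) for j in range(m)), default=0)
    from_pair.cache_clear()
    return best if best > 0 else None


def random_read(rng: np.random.Generator, length: int, read_id: str = "read") -> SeqRead:
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return SeqRead(read_id, seq, quality="U" * length)


_SWAP = {"A": "C", "C": "A", "G": "T", "T": "G"}


def embed_fragment(read_seq: str, fragment: str, offset: int, adapter_seq: str) -> str:
    """Replace read bases with an adapter prefix fragment, forcing the two
    bases after it to mismatch the adapter's continuation so the local
    alignment cannot be extended past the intended fragment by chance."""
    seq = read_seq[:offset] + fragment + read_seq[offset + len(fragment):]
    for k in (0, 1):
        apos, rpos = len(fragment) + k, offset + len(fragment) + k
        if apos < len(adapter_seq) and rpos < len(seq):
            guard = _SWAP[adapter_seq[apos]]
            seq = seq[:rpos] + guard + seq[rpos + 1:]
    return seq


@pytest.fixture(scope="session")
def adapters():
    return builtin_adapters()


@pytest.fixture(scope="session")
def blunt(adapters):
    return adapters[0]


@pytest.fixture(scope="session")
def c2(adapters):
    return adapters[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
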
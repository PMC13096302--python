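"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import functools

import numpy as np
import pytest

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


@pytest.fixture
def rng():
    return np.random.default_rng(20260401)


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])


def max_pairs_exhaustive(seq: str) -> int:
    """Exhaustive maximum-matching count (min hairpin loop 3), independent
    of the package's dynamic program: plain interval recursion with memo."""

    @functools.lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:  # half-open [i, j)
        if j - i < 5:
            return 0
        best = rec(i + 1, j)
        for k in range(i + 4, j):
            if (seq[i], seq[k]) in _PAIRS:
                best = max(best, 1 + rec(i + 1, k) + rec(k + 1, j))
        return best

    return rec(0, len(seq))


def linear_orf_scan(seq: str, min_aa: int, revcomp, translate):
    """Brute-force 6-frame start-stop scan of a linear string: per frame,
    split into codons, locate stops, and take the first ATG after each
    previous stop."""
    found = []
    for strand, w in (("+", seq), ("-", revcomp(seq))):
        for f in range(3):
            codons = [w[p : p + 3] for p in range(f, len(w) - 2, 3)]
            stops = [k for k, c in enumerate(codons) if c in ("TAA", "TAG", "TGA")]
            prev = -1
            for st in stops:
                starts = [k for k, c in enumerate(codons[prev + 1 : st], prev + 1)
                          if c == "ATG"]
                if starts:
                    k0 = starts[0]
                    aa_len = st - k0
                    if aa_len >= min_aa:
                        s = f + 3 * k0
                        e = f + 3 * (st + 1)
                        found.append((strand, s, e, translate(w[s : e - 3])))
                prev = st
    return sorted(found)
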
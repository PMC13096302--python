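"""Circular-contig detection via terminal redundancy, and circle identity.

An assembler walking around a circular template overshoots the origin, so a
contig deriving from a circle carries a copy of its 5' end at its 3' end
("terminal redundancy").  Detection anchors a seed of ``min_seed`` nt near
the 5' terminus, looks for its recurrence downstream, and requires the match
to extend to the contig's final base.  Removing the redundant 3' copy yields
the monomer, one full copy of the underlying circle.

Because a circle has no origin and no strand, monomers are canonicalized to
the lexicographically smallest rotation over both strands before
deduplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .seqio import Contig, revcomp


class NotEvaluable(ValueError):
    """Contig too short for the terminal-redundancy test (distinct from
    'not circular')."""


@dataclass(frozen=True)
class CircularCandidate:
    """A monomerized putative cccRNA with provenance."""

    monomer: str
    source_id: str
    repeat_len: int
    monomer_len: int
    canonical_rotation_offset: int = 0
    canonical_strand: str = "+"
    merged_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.monomer_len != len(self.monomer):
            raise ValueError("monomer_len does not match sequence")


def detect_terminal_redundancy(
    contig: Contig,
    min_seed: int = 30,
    terminal_window: int = 130,
    max_mismatch: int = 0,
) -> CircularCandidate | None:
    """Detect terminal redundancy and monomerize.

    A seed of ``min_seed`` nt anchored at each offset within the first
    ``terminal_window`` nt is sought downstream; a hit qualifies when the
    alignment from the hit extends through the contig's final base with at
    most ``max_mismatch`` mismatches.  When several hits qualify the one
    giving the longest repeat (shortest monomer) wins, so full multimers
    collapse to a single copy.

    Returns None when the contig shows no qualifying redundancy.  Raises
    :class:`NotEvaluable` for contigs shorter than ``2 * min_seed``.
    """
    seq = contig.seq
    n = len(seq)
    if n < 2 * min_seed:
        raise NotEvaluable(
            f"{contig.id}: length {n} < 2*min_seed={2 * min_seed}"
        )
    best: tuple[int, int] | None = None  # (monomer_len, anchor)
    max_anchor = max(0, min(terminal_window - min_seed, n - 2 * min_seed))
    for a in range(max_anchor + 1):
        seed = seq[a : a + min_seed]
        # scan for downstream recurrences of the seed
        p = seq.find(seed, a + 1)
        while p != -1:
            tail_len = n - p
            if tail_len >= min_seed and p - a >= min_seed:
                tail = seq[p:]
                ref = seq[a : a + tail_len]
                if len(ref) == tail_len:
                    mm = sum(x != y for x, y in zip(tail, ref))
                    if mm <= max_mismatch:
                        mono_len = p
                        if best is None or mono_len < best[0]:
                            best = (mono_len, a)
            p = seq.find(seed, p + 1)
    if best is None:
        return None
    mono_len, _ = best
    return CircularCandidate(
        monomer=seq[:mono_len],
        source_id=contig.id,
        repeat_len=n - mono_len,
        monomer_len=mono_len,
        merged_ids=(contig.id,),
    )


def _min_rotation(s: str) -> tuple[str, int]:
    """Lexicographically minimal rotation of s and its offset (Booth)."""
    ss = s + s
    n = len(s)
    best = 0
    for i in range(1, n):
        if ss[i : i + n] < ss[best : best + n]:
            best = i
    return ss[best : best + n], best


def canonical_form(seq: str, both_strands: bool = True) -> tuple[str, int, str]:
    """Minimal rotation over both strands: (canonical, offset, strand)."""
    fwd, off_f = _min_rotation(seq)
    if not both_strands:
        return fwd, off_f, "+"
    rc = revcomp(seq)
    rev, off_r = _min_rotation(rc)
    if rev < fwd:
        return rev, off_r, "-"
    return fwd, off_f, "+"


def canonicalize(candidate: CircularCandidate, both_strands: bool = True) -> CircularCandidate:
    """Rotate the monomer to its canonical (minimal) rotation.  Idempotent."""
    canon, offset, strand = canonical_form(candidate.monomer, both_strands)
    return replace(
        candidate,
        monomer=canon,
        canonical_rotation_offset=offset,
        canonical_strand=strand,
    )


def rotate(seq: str, offset: int) -> str:
    offset %= len(seq)
    return seq[offset:] + seq[:offset]


def permute_to_orf(candidate: CircularCandidate, orf) -> CircularCandidate:
    """Rotate the monomer so the given ORF is contiguous (no origin wrap).

    The emitted linear representation starts at the ORF start codon for
    plus-strand ORFs; minus-strand ORFs are placed so that the full ORF
    footprint is contiguous.
    """
    L = candidate.monomer_len
    iv = orf.interval
    if len(iv) > L:
        raise ValueError("ORF longer than monomer cannot be made contiguous")
    offset = iv.start % L
    return replace(
        candidate,
        monomer=rotate(candidate.monomer, offset),
        canonical_rotation_offset=offset,
    )


def dedup_candidates(candidates: list[CircularCandidate]) -> list[CircularCandidate]:
    """One representative per identical canonical monomer.

    Inputs must already be canonicalized.  Provenance of merged records is
    retained in ``merged_ids`` of the surviving representative.
    """
    seen: dict[str, CircularCandidate] = {}
    order: list[str] = []
    for c in candidates:
        key = c.monomer
        if key not in seen:
            seen[key] = c
            order.append(key)
        else:
            keep = seen[key]
            merged = keep.merged_ids + (c.merged_ids or (c.source_id,))
            seen[key] = replace(keep, merged_ids=merged)
    return [seen[k] for k in order]
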
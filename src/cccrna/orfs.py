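"""Circularity-aware ORF calling, leucine-zipper scanning, and ribozyme
position classification.

ORFs on a circular genome may run through the origin, and on a circle whose
length is not a multiple of 3 a reading frame without a stop codon cycles
through all three frames; translation is therefore scanned on a tripled
copy of the monomer and aborted after three wrappings when no stop codon is
met (such ORFs are flagged truncated).

Protein of at least 60 aa is the working threshold for the Oblin-1 search;
40 aa for the remaining proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqio import IntervalC, revcomp, translate_dna

ORF_MIN_AA_OBLIN = 60
ORF_MIN_AA_OTHER = 40

_STOPS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class OrfAnnotation:
    """A start-to-stop ORF on a (circular) sequence.

    ``interval`` is on forward-strand monomer coordinates (the footprint of
    the ORF); for minus-strand ORFs the start codon sits at the interval's
    3' end on the forward strand.  ``wraps`` counts origin crossings.
    """

    interval: IntervalC
    frame: int
    strand: str
    aa_seq: str
    aa_len: int
    wraps: int
    truncated_no_stop: bool = False


def _scan_strand(work: str, L: int, circular: bool, start_codons: frozenset[str]):
    """Yield (s, e, aa_seq, truncated) in scanned-strand nt coordinates.

    ``s`` is the start-codon position (< L), ``e`` the exclusive end
    (including the stop codon when found); e - s <= 3 L.  Every start codon
    is walked to its first in-frame stop, and only the longest ORF per stop
    codon instance (per frame chain for stop-free frames) is kept, making
    the result independent of where the circle was linearized.
    """
    import math

    ext = work * 4 if circular else work
    n = len(ext)
    best: dict[object, tuple[int, int, str, bool]] = {}
    for s in range(0, min(L, n - 2)):
        if ext[s : s + 3] not in start_codons:
            continue
        limit = s + 3 * L if circular else n - (n - s) % 3
        p = s
        while p + 3 <= min(limit, n):
            if ext[p : p + 3] in _STOPS:
                break
            p += 3
        if p + 3 <= min(limit, n) and ext[p : p + 3] in _STOPS:
            e = p + 3
            key = ((e - 3) % L) if circular else e
            cand = (s, e, translate_dna(ext[s:p]), False)
        elif circular:
            e = s + 3 * L
            # stop-free frame chain; one chain per gcd(3, L) residue class
            key = ("trunc", s % math.gcd(3, L))
            cand = (s, e, translate_dna(ext[s:e]), True)
        else:
            continue  # linear ORFs require a stop codon
        if key not in best or (cand[1] - cand[0]) > (best[key][1] - best[key][0]):
            best[key] = cand
    for s, e, aa, trunc in best.values():
        yield s, e, aa, trunc


def _rev_to_fwd_interval(s: int, e: int, L: int) -> IntervalC:
    """Map an interval on the reverse-complement strand to the forward
    footprint (contiguous circular interval of the same length)."""
    length = e - s
    f0 = (L - e) % L
    return IntervalC(start=f0, end=f0 + length, strand="-", ref_len=L)


def find_orfs_circular(
    seq: str,
    min_aa: int = ORF_MIN_AA_OBLIN,
    max_wraps: int = 3,
    start_codons: Iterable[str] = ("ATG",),
    circular: bool = True,
) -> list[OrfAnnotation]:
    """All start-to-stop ORFs in 6 frames, circularity-aware.

    Per frame, ORFs open at the first start codon after the previous stop
    (longest ORF per stop).  For non-circular input this reduces to a plain
    6-frame scan of the raw string.  Results are filtered to
    ``aa_len >= min_aa`` and sorted by descending length.
    """
    L = len(seq)
    if L < 3:
        return []
    starts = frozenset(c.upper().replace("U", "T") for c in start_codons)
    out: list[OrfAnnotation] = []
    for strand in ("+", "-"):
        work = seq if strand == "+" else revcomp(seq)
        for s, e, aa, truncated in _scan_strand(work, L, circular, starts):
            aa_len = len(aa)
            if aa_len < min_aa:
                continue
            if strand == "+":
                iv = IntervalC(start=s, end=e, strand="+", ref_len=L)
            else:
                iv = _rev_to_fwd_interval(s, e, L)
            wraps = iv.end // L
            if wraps > max_wraps:
                continue
            out.append(
                OrfAnnotation(
                    interval=iv,
                    frame=s % 3,
                    strand=strand,
                    aa_seq=aa,
                    aa_len=aa_len,
                    wraps=wraps,
                    truncated_no_stop=truncated,
                )
            )
    out.sort(key=lambda o: (-o.aa_len, o.interval.start, o.strand))
    return out


def orf_coverage(orf: OrfAnnotation, ref_len: int) -> float:
    """ORF footprint length over monomer length; > 1 for wrapped truncated
    ORFs (up to 3.0 for a full three-wrap no-stop ORF)."""
    return len(orf.interval) / ref_len


@dataclass(frozen=True)
class HeptadCall:
    """A qualifying leucine-zipper run of consecutive heptads."""

    region_start: int  # aa coordinate of the run's first heptad
    region_end: int  # exclusive aa coordinate
    frame_offset: int  # 0-6 heptad register within the scanned region
    n_heptads: int
    a_leu_frac: float
    d_leu_ile_frac: float
    n_matches: int
    verdict: bool


def scan_leucine_zipper(
    aa_seq: str,
    regions: Sequence[tuple[int, int]] | None = None,
    min_heptads: int = 3,
    frac: float = 0.5,
    min_matches: int = 3,
) -> list[HeptadCall]:
    """Scan coiled-coil regions for leucine-zipper heptad runs.

    Heptads follow the abcdefg register: a zipper is called when at least
    ``min_heptads`` consecutive heptads carry Leu at the "a" position in at
    least ``frac`` of the heptads AND Leu/Ile at the "d" position in at
    least ``frac`` of the heptads AND at least ``min_matches`` matches at
    "a" or "d" combined.  All 7 heptad registers are tried; maximal
    qualifying runs (not contained in a longer qualifying run) are
    reported.  Regions shorter than 21 aa are skipped.
    """
    if regions is None:
        regions = [(0, len(aa_seq))]
    calls: list[HeptadCall] = []
    for rs, re_ in regions:
        region = aa_seq[rs:re_]
        if len(region) < 7 * min_heptads:
            continue
        for off in range(7):
            n_hept = (len(region) - off) // 7
            if n_hept < min_heptads:
                continue
            a_hits = []
            d_hits = []
            for h in range(n_hept):
                base = off + 7 * h
                a_hits.append(region[base] == "L")
                d_hits.append(region[base + 3] in ("L", "I"))
            qualifying: list[tuple[int, int]] = []
            for i in range(n_hept - min_heptads + 1):
                for j in range(i + min_heptads, n_hept + 1):
                    na = sum(a_hits[i:j])
                    nd = sum(d_hits[i:j])
                    span = j - i
                    if na / span >= frac and nd / span >= frac and na + nd >= min_matches:
                        qualifying.append((i, j))
            maximal = [
                (i, j)
                for (i, j) in qualifying
                if not any(
                    (x <= i and j <= y and (x, y) != (i, j)) for (x, y) in qualifying
                )
            ]
            for i, j in maximal:
                na = sum(a_hits[i:j])
                nd = sum(d_hits[i:j])
                calls.append(
                    HeptadCall(
                        region_start=rs + off + 7 * i,
                        region_end=rs + off + 7 * j,
                        frame_offset=off,
                        n_heptads=j - i,
                        a_leu_frac=na / (j - i),
                        d_leu_ile_frac=nd / (j - i),
                        n_matches=na + nd,
                        verdict=True,
                    )
                )
    calls.sort(key=lambda c: (c.region_start, -c.n_heptads))
    return calls


@dataclass(frozen=True)
class RibozymePosition:
    hit: IntervalC
    strand_relative_to_orf: str  # sense | antisense
    category: str  # nested | overlapping | non_overlapping
    dist_to_orf_start_nt: int


def _circ_dist(x: int, y: int, L: int) -> int:
    d = (x - y) % L
    return min(d, L - d)


def classify_ribozyme_position(
    hit: IntervalC, orf: OrfAnnotation, ref_len: int
) -> RibozymePosition:
    """Classify a ribozyme hit relative to an ORF on the same circle.

    nested: hit footprint entirely inside the ORF footprint (mod L);
    non_overlapping: disjoint footprints; overlapping otherwise.  The
    distance is the minimal circular distance from either hit boundary to
    the ORF start codon.
    """
    hit_set = hit.position_set()
    orf_set = orf.interval.position_set()
    if hit_set <= orf_set:
        category = "nested"
    elif hit_set.isdisjoint(orf_set):
        category = "non_overlapping"
    else:
        category = "overlapping"
    rel = "sense" if hit.strand == orf.strand else "antisense"
    if orf.strand == "+":
        orf_start = orf.interval.start % ref_len
    else:
        orf_start = (orf.interval.end - 1) % ref_len
    dist = min(
        _circ_dist(hit.start % ref_len, orf_start, ref_len),
        _circ_dist(hit.end % ref_len, orf_start, ref_len),
    )
    return RibozymePosition(
        hit=hit,
        strand_relative_to_orf=rel,
        category=category,
        dist_to_orf_start_nt=dist,
    )


def orfs_to_gff3(
    orfs: Sequence[OrfAnnotation], seq_id: str, source: str = "cccrna"
) -> str:
    """GFF3 text for a set of ORFs; wrapped ORFs become multi-part CDS
    features sharing one ID (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for k, orf in enumerate(orfs, 1):
        L = orf.interval.ref_len
        oid = f"orf{k:03d}"
        attrs = (
            f"ID={oid};aa_len={orf.aa_len};wraps={orf.wraps};"
            f"truncated={'true' if orf.truncated_no_stop else 'false'}"
        )
        # split the (possibly wrapped) footprint into monomer segments
        s, e = orf.interval.start, orf.interval.end
        segs = []
        while s < e:
            seg_end = min(e, (s // L + 1) * L)
            segs.append((s % L + 1, (seg_end - 1) % L + 1))
            s = seg_end
        for a, b in segs:
            lines.append(
                "\t".join(
                    [
                        seq_id,
                        source,
                        "CDS",
                        str(a),
                        str(b),
                        ".",
                        orf.strand,
                        "0",
                        attrs,
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def read_intervals_tsv(path) -> list[dict]:
    """Read `seq_id start end strand` TSV rows (0-based half-open) used for
    coiled-coil regions and ribozyme hits."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"seq_id", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"interval TSV must have columns {sorted(required)}")
    return df.to_dict("records")
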
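"""Sequence and alignment I/O shared by the whole pipeline.

Sequences are handled internally as uppercase DNA (U is normalized to T at
ingest) so that circular-coordinate arithmetic and reverse complementation
are uniform regardless of whether the input was an RNA or DNA FASTA.
Coordinates are 0-based half-open; intervals on circular references may have
``end > ref_len`` to denote wrapping past the origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq

log = logging.getLogger("cccrna")

_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaParseError(ValueError):
    """Raised when a FASTA record cannot be parsed or validated."""


def normalize_seq(seq: str) -> str:
    """Uppercase and convert U to T."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Contig:
    """An assembled contig (DNA alphabet, uppercase)."""

    id: str
    seq: str
    sample: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise FastaParseError(f"contig {self.id!r}: empty sequence")
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise FastaParseError(
                f"contig {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class IntervalC:
    """A (possibly origin-wrapping) interval on a circular reference.

    ``start`` is 0-based inclusive and must lie on the monomer;
    ``end`` is exclusive and may exceed ``ref_len`` (up to three wraps)
    to represent features that run past the origin.
    """

    start: int
    end: int
    strand: str
    ref_len: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.ref_len):
            raise ValueError(f"start {self.start} outside [0, {self.ref_len})")
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.end - self.start > 3 * self.ref_len:
            raise ValueError("interval longer than three wraps")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def wraps(self) -> int:
        return self.end // self.ref_len

    def positions(self) -> np.ndarray:
        """Monomer positions covered, in order (mod ref_len)."""
        return np.arange(self.start, self.end) % self.ref_len

    def position_set(self) -> frozenset[int]:
        return frozenset(int(p) for p in self.positions())


def read_fasta(path: str | Path, sample: str | None = None) -> list[Contig]:
    """Read a FASTA file into a list of :class:`Contig`.

    Order-preserving; sequences are uppercased and U-normalized.
    """
    path = Path(path)
    contigs: list[Contig] = []
    try:
        for rec in _BioSeqIO.parse(str(path), "fasta"):
            seq = normalize_seq(str(rec.seq))
            contigs.append(Contig(id=rec.id, seq=seq, sample=sample))
    except (ValueError, FastaParseError) as exc:
        raise FastaParseError(f"{path}: {exc}") from exc
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.seq), width):
                fh.write(c.seq[i : i + width] + "\n")


def seq_stats(seq: str) -> tuple[int, float | None]:
    """Return (length in nt, GC fraction).

    GC fraction excludes N from the denominator; an all-N sequence has
    undefined GC, returned as None.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = normalize_seq(seq)
    counts = {b: s.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return len(s), None
    return len(s), (counts["G"] + counts["C"]) / denom


@dataclass
class DepthProfile:
    """Per-position read depth and read-start counts on one reference."""

    ref_id: str
    L: int
    depth: np.ndarray
    starts: np.ndarray
    n_reads: int = field(default=0)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        if self.L < 1:
            raise ValueError("reference length must be >= 1")
        if len(self.depth) != self.L or len(self.starts) != self.L:
            raise ValueError("depth/starts length must equal L")
        if self.n_reads == 0:
            self.n_reads = int(self.starts.sum())
        elif self.n_reads != int(self.starts.sum()):
            raise ValueError("n_reads inconsistent with starts")

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean())


def _add_segment(depth: np.ndarray, L: int, start: int, length: int, circular: bool) -> None:
    """Add +1 depth over [start, start+length), wrapping if circular."""
    end = start + length
    if end <= L:
        depth[start:end] += 1
    elif circular:
        depth[start:L] += 1
        depth[: end - L] += 1
    else:
        depth[start:L] += 1


def ingest_alignments(
    path: str | Path,
    fmt: str,
    ref_len: int,
    circular: bool = True,
    ref_id: str | None = None,
) -> DepthProfile:
    """Build a :class:`DepthProfile` from SAM, PAF, or a depth TSV.

    All alignments must target a single reference.  On circular targets,
    coordinates are reduced modulo ``ref_len``; alignments starting at or
    beyond ``2 * ref_len`` are rejected and logged.  Secondary and unmapped
    SAM records are ignored; supplementary alignments contribute to depth
    but not to start counts (start entropy measures fragment origins, not
    split mappings).
    """
    if ref_len < 1:
        raise ValueError("ref_len must be positive")
    fmt = fmt.lower()
    if fmt == "sam":
        return _ingest_sam(path, ref_len, circular, ref_id)
    if fmt == "paf":
        return _ingest_paf(path, ref_len, circular, ref_id)
    if fmt == "tsv":
        return _ingest_tsv(path, ref_len, ref_id)
    raise ValueError(f"unknown alignment format {fmt!r}")


def _reduce_start(pos: int, ref_len: int, circular: bool) -> int | None:
    """Reduce an alignment start; None means the record must be rejected."""
    if pos < 0:
        return None
    if circular:
        if pos >= 2 * ref_len:
            return None
        return pos % ref_len
    if pos >= ref_len:
        return None
    return pos


def _ingest_sam(path, ref_len, circular, ref_id) -> DepthProfile:
    import pysam

    depth = np.zeros(ref_len, dtype=np.int64)
    starts = np.zeros(ref_len, dtype=np.int64)
    rid = ref_id
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            if rid is None:
                rid = rec.reference_name
            pos = _reduce_start(rec.reference_start, ref_len, circular)
            if pos is None:
                log.warning("rejected SAM record %s at %d (beyond %d)",
                            rec.query_name, rec.reference_start, 2 * ref_len)
                continue
            aln_len = rec.reference_length or 0
            _add_segment(depth, ref_len, pos, aln_len, circular)
            if not rec.is_supplementary:
                starts[pos] += 1
    return DepthProfile(ref_id=rid or "ref", L=ref_len, depth=depth, starts=starts)


def _ingest_paf(path, ref_len, circular, ref_id) -> DepthProfile:
    depth = np.zeros(ref_len, dtype=np.int64)
    starts = np.zeros(ref_len, dtype=np.int64)
    rid = ref_id
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: PAF needs >= 12 columns")
            if rid is None:
                rid = f[5]
            tstart, tend = int(f[7]), int(f[8])
            pos = _reduce_start(tstart, ref_len, circular)
            if pos is None:
                log.warning("rejected PAF record %s at %d", f[0], tstart)
                continue
            _add_segment(depth, ref_len, pos, tend - tstart, circular)
            starts[pos] += 1
    return DepthProfile(ref_id=rid or "ref", L=ref_len, depth=depth, starts=starts)


def _ingest_tsv(path, ref_len, ref_id) -> DepthProfile:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"pos", "depth", "starts"}
    if not required.issubset(df.columns):
        raise ValueError(f"depth TSV must have columns {sorted(required)}")
    depth = np.zeros(ref_len, dtype=np.int64)
    starts = np.zeros(ref_len, dtype=np.int64)
    pos = df["pos"].to_numpy()
    if (pos < 0).any() or (pos >= ref_len).any():
        raise ValueError("TSV positions outside [0, ref_len)")
    depth[pos] = df["depth"].to_numpy()
    starts[pos] = df["starts"].to_numpy()
    return DepthProfile(ref_id=ref_id or "ref", L=ref_len, depth=depth, starts=starts)


def write_depth_tsv(profile: DepthProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\tdepth\tstarts\n")
        for i in range(profile.L):
            fh.write(f"{i}\t{profile.depth[i]}\t{profile.starts[i]}\n")


def translate_dna(seq: str) -> str:
    """Translate a DNA string (standard code); trailing partial codon dropped."""
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())
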
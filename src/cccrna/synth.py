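"""Seeded generators for synthetic circular replicons and read data.

The generator emulates the signal the detection cascade looks for:

* a circular monomer folding into a rod — two complementary arms covering
  ``stem_fraction`` of the circle, separated by terminal loops.  Loops are
  drawn from an A/C alphabet that cannot base-pair with itself, so the
  designed stem is (up to arm mutations) the only pairing and the designed
  paired fraction is a tight ground truth.  ``stem_fraction = 0`` yields an
  unstructured control that cannot pass a paired-base filter.
* an optional protein-coding ORF (ATG, stop-free codons, one stop) written
  into the 5' arm and rotated to span the origin, exercising wrap-aware
  ORF calling.
* assembler overshoot — concatemer contigs carrying a fractional number of
  copies of the circle, i.e. terminal redundancy.
* dsRNA-seq read mapping — read start positions drawn uniformly or from a
  circular von-Mises-like peak, with wrap-around reads split into primary
  plus supplementary alignments.

All randomness flows from a numpy Generator so fixtures are reproducible
from one integer seed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .circles import rotate
from .seqio import Contig, DepthProfile, IntervalC, revcomp

log = logging.getLogger("cccrna")

_NT = np.array(list("ACGT"))
_LOOP_NT = np.array(list("AC"))  # cannot pair with itself (no G/T partner)
_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic replicon and its read set."""

    L: int = 900
    stem_fraction: float = 0.8
    mutation_rate: float = 0.02
    orf_aa_len: int | None = 100
    orf_origin_overhang: int = 30  # nt of the ORF lying before the origin
    n_reads: int = 2000
    read_len: int = 100
    start_distribution: str = "uniform"  # uniform | peaked
    kappa: float = 50.0  # concentration of the peaked start distribution
    concatemer_copies: float = 1.3
    seed: int = 0


def _random_seq(rng: np.random.Generator, n: int, alphabet=_NT) -> str:
    return "".join(alphabet[rng.integers(0, len(alphabet), size=n)])


def _random_orf_nt(rng: np.random.Generator, aa_len: int) -> str:
    """ATG + (aa_len - 1) random stop-free codons + one stop codon."""
    codons = ["ATG"]
    while len(codons) < aa_len:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        alts = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alts[rng.integers(0, 3)]
    return "".join(chars)


def generate_rod_replicon(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[str, dict]:
    """Generate a circular monomer with a designed rod structure.

    Layout before rotation: arm1 | loop1 | revcomp(mutated arm1) | loop2.
    Position i of arm1 is designed to pair with its mirror position in
    arm2.  When an ORF is requested it occupies the start of arm1 (it may
    run into loop1 but not into arm2) and the monomer is rotated so the
    ORF spans the origin by ``orf_origin_overhang`` nt.

    Returns (monomer, truth) where truth records the designed pair list,
    designed paired fraction, and the ORF interval (or None).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    L = spec.L
    stem_nt = spec.stem_fraction * L
    if abs(stem_nt - round(stem_nt)) > 1e-9 or int(round(stem_nt)) % 2:
        raise ValueError("stem_fraction * L must be an even integer")
    arm = int(round(stem_nt)) // 2
    rest = L - 2 * arm
    loop1 = rest // 2
    loop2 = rest - loop1

    orf_nt = 0
    if spec.orf_aa_len is not None:
        orf_nt = 3 * (spec.orf_aa_len + 1)
        if orf_nt >= L:
            raise ValueError("ORF does not fit on the circle")
        if orf_nt > arm + loop1:
            raise ValueError(
                "ORF must fit in the 5' arm plus terminal loop "
                f"({arm + loop1} nt available, {orf_nt} requested)"
            )

    if spec.orf_aa_len is not None:
        orf_seq = _random_orf_nt(rng, spec.orf_aa_len)
        head = orf_seq[: min(orf_nt, arm)]
        arm1 = head + _random_seq(rng, arm - len(head))
        loop1_orf_part = orf_seq[arm:] if orf_nt > arm else ""
        loop1_seq = loop1_orf_part + _random_seq(
            rng, loop1 - len(loop1_orf_part), _LOOP_NT
        )
    else:
        arm1 = _random_seq(rng, arm)
        loop1_seq = _random_seq(rng, loop1, _LOOP_NT)
    arm2 = revcomp(_mutate(rng, arm1, spec.mutation_rate))
    loop2_seq = _random_seq(rng, loop2, _LOOP_NT)
    monomer = arm1 + loop1_seq + arm2 + loop2_seq
    assert len(monomer) == L

    # designed pairing: arm1[i] <-> arm2 mirror position
    pairs = [(i, arm + loop1 + (arm - 1 - i)) for i in range(arm)]

    offset = 0
    orf_interval = None
    if spec.orf_aa_len is not None:
        offset = spec.orf_origin_overhang % L
        monomer = rotate(monomer, offset)
        pairs = [
            tuple(sorted((((i - offset) % L), ((j - offset) % L))))
            for i, j in pairs
        ]
        orf_start = (0 - offset) % L
        orf_interval = IntervalC(
            start=orf_start, end=orf_start + orf_nt, strand="+", ref_len=L
        )
    truth = {
        "pairs": sorted(pairs),
        "designed_paired_fraction": 2 * arm / L,
        "orf": orf_interval,
        "orf_aa_len": spec.orf_aa_len,
        "rotation_offset": offset,
        "seed": spec.seed,
    }
    return monomer, truth


def generate_concatemer_contig(
    monomer: str,
    copies: float,
    offset: int = 0,
    contig_id: str = "contig",
    min_seed: int = 30,
) -> Contig:
    """Contig covering ``copies`` copies of the circle starting at a
    rotation ``offset`` — the assembly signature of a circular template.

    Fractional copies are allowed; below 1 + min_seed/L the terminal
    redundancy is too short to detect (emitted anyway, with a warning, as
    a negative-control fixture)."""
    if copies < 1:
        raise ValueError("copies must be >= 1")
    L = len(monomer)
    if copies < 1 + min_seed / L:
        warnings.warn(
            f"{contig_id}: {copies} copies gives < {min_seed} nt terminal "
            "redundancy; circularity will not be detectable",
            stacklevel=2,
        )
    rot = rotate(monomer, offset)
    n_nt = int(round(copies * L))
    reps = math.ceil(n_nt / L) + 1
    return Contig(id=contig_id, seq=(rot * reps)[:n_nt])


def simulate_read_starts(
    spec: SyntheticSpec, rng: np.random.Generator | None = None, peak_pos: int = 0
) -> np.ndarray:
    """Draw read start positions on the circle.

    ``uniform`` draws each start independently over [0, L); ``peaked``
    draws from a von Mises distribution of concentration ``kappa`` wrapped
    onto the circle and centred at ``peak_pos`` (kappa = inf collapses to
    a single origin).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    L = spec.L
    if spec.start_distribution == "uniform":
        return rng.integers(0, L, size=spec.n_reads)
    if spec.start_distribution == "peaked":
        if math.isinf(spec.kappa):
            return np.full(spec.n_reads, peak_pos % L, dtype=np.int64)
        angles = rng.vonmises(0.0, spec.kappa, size=spec.n_reads)
        pos = (np.floor((angles + math.pi) / (2 * math.pi) * L).astype(np.int64)
               + peak_pos - L // 2) % L
        return pos
    raise ValueError(f"unknown start distribution {spec.start_distribution!r}")


def profile_from_starts(
    starts: np.ndarray, L: int, read_len: int, ref_id: str = "ref"
) -> DepthProfile:
    """Depth/start profile of fixed-length reads on a circular reference."""
    s = np.zeros(L, dtype=np.int64)
    np.add.at(s, np.asarray(starts) % L, 1)
    # depth via circular difference array
    diff = np.zeros(L + 1, dtype=np.int64)
    for st in np.asarray(starts) % L:
        end = st + read_len
        if end <= L:
            diff[st] += 1
            diff[end] -= 1
        else:
            diff[st] += 1
            diff[L] -= 1
            diff[0] += 1
            diff[end - L] -= 1
    depth = np.cumsum(diff[:L])
    return DepthProfile(ref_id=ref_id, L=L, depth=depth, starts=s)


def emit_sam(
    starts: np.ndarray, monomer: str, read_len: int, path, ref_id: str = "ref"
) -> None:
    """Write the simulated reads as SAM against the monomer.

    Wrap-around reads are split into a primary alignment to the 3' end of
    the reference plus a supplementary alignment starting at the origin."""
    L = len(monomer)
    doubled = monomer + monomer
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{ref_id}\tLN:{L}\n")
        for k, st in enumerate(np.asarray(starts) % L):
            seq = doubled[st : st + read_len]
            name = f"read{k:06d}"
            if st + read_len <= L:
                fh.write(
                    f"{name}\t0\t{ref_id}\t{st + 1}\t60\t{read_len}M\t*\t0\t0\t"
                    f"{seq}\t*\n"
                )
            else:
                part1 = L - st
                part2 = read_len - part1
                fh.write(
                    f"{name}\t0\t{ref_id}\t{st + 1}\t60\t{part1}M{part2}S\t*\t0\t0\t"
                    f"{seq}\t*\n"
                )
                fh.write(
                    f"{name}\t2048\t{ref_id}\t1\t60\t{part1}S{part2}M\t*\t0\t0\t"
                    f"{seq}\t*\n"
                )


@dataclass
class FixtureCase:
    """One synthetic contig with its ground-truth label and read profile."""

    contig: Contig
    profile: DepthProfile | None
    is_positive: bool
    violation: str | None = None  # which single criterion a negative breaks
    monomer: str | None = None
    truth: dict | None = None


def fixture_suite(
    n_positive: int = 20,
    seed: int = 0,
    lengths: tuple[int, int] = (300, 1500),
    read_len: int = 60,
) -> list[FixtureCase]:
    """A labelled suite for end-to-end cascade testing.

    Positives are rod-structured, uniformly covered circles (>= 200 nt,
    mean depth >= 10) presented as terminally redundant concatemers.
    Negatives each violate exactly one criterion: not circular, too short,
    low depth, unstructured, or single-peak coverage.
    """
    rng = np.random.default_rng(seed)
    cases: list[FixtureCase] = []

    def pick_L() -> int:
        # divisible by 10 so stem_fraction 0.8 gives an even stem
        return int(rng.integers(lengths[0] // 10, lengths[1] // 10 + 1)) * 10

    for i in range(n_positive):
        L = pick_L()
        spec = SyntheticSpec(
            L=L,
            stem_fraction=0.8,
            orf_aa_len=None,
            n_reads=max(1200, 20 * L // read_len),
            read_len=read_len,
            seed=int(rng.integers(0, 2**31)),
        )
        monomer, truth = generate_rod_replicon(spec, rng)
        contig = generate_concatemer_contig(
            monomer, 1.0 + max(40, int(0.1 * L)) / L,
            offset=int(rng.integers(0, L)), contig_id=f"pos{i:03d}",
        )
        starts = simulate_read_starts(spec, rng)
        prof = profile_from_starts(starts, L, read_len, ref_id=contig.id)
        cases.append(FixtureCase(contig, prof, True, None, monomer, truth))

    neg_kinds = ["linear", "short", "low_depth", "unstructured", "peaked"]
    for i in range(n_positive):
        kind = neg_kinds[i % len(neg_kinds)]
        L = pick_L()
        spec = SyntheticSpec(
            L=L, stem_fraction=0.8, orf_aa_len=None,
            n_reads=max(1200, 20 * L // read_len), read_len=read_len,
            seed=int(rng.integers(0, 2**31)),
        )
        cid = f"neg{i:03d}_{kind}"
        if kind == "linear":
            # structured sequence but no terminal redundancy
            monomer, _ = generate_rod_replicon(spec, rng)
            contig = Contig(id=cid, seq=monomer)
            starts = simulate_read_starts(spec, rng)
            prof = profile_from_starts(starts, L, read_len, ref_id=cid)
        elif kind == "short":
            sspec = SyntheticSpec(
                L=150, stem_fraction=0.8, orf_aa_len=None,
                n_reads=600, read_len=50, seed=spec.seed,
            )
            monomer, _ = generate_rod_replicon(sspec, rng)
            contig = generate_concatemer_contig(
                monomer, 1.3, offset=int(rng.integers(0, 150)), contig_id=cid
            )
            starts = simulate_read_starts(sspec, rng)
            prof = profile_from_starts(starts, 150, 50, ref_id=cid)
        elif kind == "low_depth":
            monomer, _ = generate_rod_replicon(spec, rng)
            contig = generate_concatemer_contig(
                monomer, 1.3, offset=int(rng.integers(0, L)), contig_id=cid
            )
            thin = SyntheticSpec(
                L=L, n_reads=max(1, 5 * L // read_len // 2), read_len=read_len,
                seed=spec.seed,
            )
            starts = simulate_read_starts(thin, rng)
            prof = profile_from_starts(starts, L, read_len, ref_id=cid)
        elif kind == "unstructured":
            uspec = SyntheticSpec(
                L=L, stem_fraction=0.0, orf_aa_len=None,
                n_reads=spec.n_reads, read_len=read_len, seed=spec.seed,
            )
            monomer, _ = generate_rod_replicon(uspec, rng)
            contig = generate_concatemer_contig(
                monomer, 1.3, offset=int(rng.integers(0, L)), contig_id=cid
            )
            starts = simulate_read_starts(uspec, rng)
            prof = profile_from_starts(starts, L, read_len, ref_id=cid)
        else:  # peaked
            monomer, _ = generate_rod_replicon(spec, rng)
            contig = generate_concatemer_contig(
                monomer, 1.3, offset=int(rng.integers(0, L)), contig_id=cid
            )
            pspec = SyntheticSpec(
                L=L, n_reads=spec.n_reads, read_len=read_len,
                start_distribution="peaked", kappa=float("inf"), seed=spec.seed,
            )
            starts = simulate_read_starts(pspec, rng, peak_pos=int(rng.integers(0, L)))
            prof = profile_from_starts(starts, L, read_len, ref_id=cid)
        cases.append(FixtureCase(contig, prof, False, kind, monomer, None))
    return cases
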
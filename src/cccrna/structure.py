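"""Circular RNA secondary-structure prediction and structure statistics.

Viroid-like replicons fold into long, unbranched rods in which most bases
are paired.  Folding is delegated to a pluggable backend:

* ``"vienna"`` — thermodynamic minimum-free-energy folding through the
  ViennaRNA Python bindings, with true circular folding and temperature
  support.  This is the backend of record.
* ``"maxpair"`` — a built-in base-pair-maximization dynamic program
  (Watson-Crick + GU wobble, minimum hairpin loop of 3) on the linearized
  sequence at a configurable cut point.  It reports no free energy and does
  no true circular folding; it exists so every downstream statistic is
  unit-testable without the thermodynamic engine.

Statistics (paired-base fraction, ORF self-complementarity) depend only on
the pair list and are backend-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import IntervalC, revcomp

_CAN_PAIR = frozenset(
    {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
)


class BackendUnavailable(RuntimeError):
    """Raised when the requested folding backend cannot be loaded."""


@dataclass(frozen=True)
class SecondaryStructure:
    seq_id: str
    strand: str  # sense | antisense
    temperature_C: float
    circular: bool
    dotbracket: str
    pairs: tuple[tuple[int, int], ...]
    mfe_kcal_mol: float | None = None
    length: int = field(default=0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "length", len(self.dotbracket))
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.length):
                raise ValueError(f"pair ({i},{j}) out of range")
            if i in seen or j in seen:
                raise ValueError("position in more than one pair")
            seen.update((i, j))


def pairs_from_dotbracket(db: str) -> tuple[tuple[int, int], ...]:
    """Pair list from a (possibly multi-bracket) dot-bracket string."""
    openers = {"(": ")", "[": "]", "{": "}", "<": ">"}
    closers = {v: k for k, v in openers.items()}
    stacks: dict[str, list[int]] = {k: [] for k in openers}
    pairs = []
    for i, ch in enumerate(db):
        if ch in openers:
            stacks[ch].append(i)
        elif ch in closers:
            stack = stacks[closers[ch]]
            if not stack:
                raise ValueError(f"unbalanced bracket at {i}")
            pairs.append((stack.pop(), i))
    for stack in stacks.values():
        if stack:
            raise ValueError("unbalanced dot-bracket string")
    return tuple(sorted(pairs))


def dotbracket_from_pairs(pairs, length: int) -> str:
    db = ["."] * length
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db)


def _fold_vienna(seq: str, temperature_C: float, circular: bool):
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover
        raise BackendUnavailable(
            "ViennaRNA Python bindings not importable; use backend='maxpair'"
        ) from exc
    md = RNA.md()
    md.temperature = float(temperature_C)
    md.circ = 1 if circular else 0
    fc = RNA.fold_compound(seq.replace("T", "U"), md)
    db, mfe = fc.mfe()
    return db, float(mfe)


def _maxpair_table(seq: str) -> np.ndarray:
    """Nussinov-style maximum-matching DP table (min hairpin loop 3)."""
    n = len(seq)
    can = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 4, n):
            if (seq[i], seq[j]) in _CAN_PAIR:
                can[i, j] = 1
    dp = np.zeros((n + 1, n + 1), dtype=np.int64)
    # dp[i, j] over half-open [i, j); fill by increasing span
    for span in range(5, n + 1):
        i_max = n - span
        for i in range(i_max + 1):
            j = i + span
            best = dp[i + 1, j]  # i unpaired
            # i paired with k in [i+4, j)
            ks = np.arange(i + 4, j)
            if ks.size:
                cand = can[i, ks] * (1 + dp[i + 1, ks] + dp[ks + 1, j])
                km = int(cand.max())
                if km > best:
                    best = km
            dp[i, j] = best
    return dp


def _maxpair_traceback(seq: str, dp: np.ndarray) -> list[tuple[int, int]]:
    n = len(seq)
    pairs: list[tuple[int, int]] = []
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < 5 or dp[i, j] == 0:
            continue
        if dp[i, j] == dp[i + 1, j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + 4, j):
            if (seq[i], seq[k]) in _CAN_PAIR and dp[i, j] == 1 + dp[i + 1, k] + dp[k + 1, j]:
                pairs.append((i, k))
                stack.append((i + 1, k))
                stack.append((k + 1, j))
                break
    return pairs


def _fold_maxpair(seq: str, circular: bool, cut: int = 0):
    """Pair-maximization fold; circular input is linearized at ``cut``."""
    n = len(seq)
    if circular and cut % n != 0:
        cut %= n
        lin = seq[cut:] + seq[:cut]
    else:
        cut = 0
        lin = seq
    dp = _maxpair_table(lin)
    raw = _maxpair_traceback(lin, dp)
    # map back to original coordinates
    pairs = sorted(
        tuple(sorted(((i + cut) % n, (j + cut) % n))) for i, j in raw
    )
    return dotbracket_from_pairs(pairs, n), pairs


def fold(
    seq: str,
    seq_id: str = "seq",
    temperature_C: float = 37.0,
    circular: bool = True,
    strand: str = "sense",
    backend: str = "vienna",
    cut: int = 0,
) -> SecondaryStructure:
    """Predict the secondary structure of one strand of a (circular) RNA.

    ``strand="antisense"`` folds the reverse complement; coordinates of the
    returned structure are on the antisense strand itself.
    """
    if len(seq) < 10:
        raise ValueError("sequence shorter than 10 nt")
    if strand not in ("sense", "antisense"):
        raise ValueError("strand must be 'sense' or 'antisense'")
    s = seq if strand == "sense" else revcomp(seq)
    if backend == "vienna":
        db, mfe = _fold_vienna(s, temperature_C, circular)
        pairs = pairs_from_dotbracket(db)
    elif backend == "maxpair":
        db, pairs = _fold_maxpair(s, circular, cut)
        pairs = tuple(pairs)
        mfe = None
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return SecondaryStructure(
        seq_id=seq_id,
        strand=strand,
        temperature_C=temperature_C,
        circular=circular,
        dotbracket=db,
        pairs=tuple(pairs),
        mfe_kcal_mol=mfe,
    )


def paired_fraction(structure: SecondaryStructure) -> float:
    """Fraction of nucleotides that are base-paired, 2|pairs|/L."""
    if structure.length == 0:
        return 0.0
    return 2 * len(structure.pairs) / structure.length


def self_complementarity(
    structure: SecondaryStructure, orf: IntervalC
) -> float | None:
    """ORF self-pairing: among paired bases of pairs touching the ORF, the
    fraction whose base and partner both lie inside the ORF.

    Counts bases, not pairs.  None when no pair touches the ORF.
    """
    inside = orf.position_set()
    num = 0
    den = 0
    for i, j in structure.pairs:
        i_in = i in inside
        j_in = j in inside
        if i_in or j_in:
            den += 2
            if i_in and j_in:
                num += 2
    if den == 0:
        return None
    return num / den


def structure_summary(records: list[dict]) -> "pandas.DataFrame":
    """Per-group, per-strand means of MFE, paired fraction, and ORF
    self-complementarity.

    ``records`` entries carry keys: group, strand, mfe, paired_fraction,
    self_complementarity (the latter two may be None).
    """
    import pandas as pd

    df = pd.DataFrame.from_records(records)
    out = (
        df.groupby(["group", "strand"], sort=True)
        .agg(
            n=("group", "size"),
            mean_mfe=("mfe", "mean"),
            mean_paired_fraction=("paired_fraction", "mean"),
            mean_self_complementarity=("self_complementarity", "mean"),
        )
        .reset_index()
    )
    return out
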
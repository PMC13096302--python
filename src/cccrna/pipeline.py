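"""The end-to-end circular-replicon detection cascade.

Stage order: circularize -> dedup -> known-sequence exclusion (optional,
tabular homology hits at E <= 1e-5) -> length >= 200 nt -> mean depth >= 10
-> paired-base fraction > 0.60 at 37 C -> mapping evenness (normalized CV
< 0.6 and normalized start entropy > 0.7).  Every input contig is accounted
for exactly once; the funnel of per-stage survivor counts is non-increasing
by construction and emitted with every report together with the full
configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

from .circles import (
    CircularCandidate,
    NotEvaluable,
    canonicalize,
    dedup_candidates,
    detect_terminal_redundancy,
)
from .evenness import EvennessMetrics, evenness_verdict
from .orfs import ORF_MIN_AA_OBLIN, find_orfs_circular
from .seqio import Contig, DepthProfile
from .structure import SecondaryStructure, fold, paired_fraction

log = logging.getLogger("cccrna")

STAGES = [
    "input",
    "circular",
    "dedup",
    "known_excluded",
    "length",
    "depth",
    "structure",
    "evenness",
]


@dataclass
class FilterConfig:
    """Thresholds of the detection cascade (recorded in every report)."""

    min_len_nt: int = 200
    min_mean_depth: float = 10.0
    min_paired_frac: float = 0.60  # strict >
    cv_max: float = 0.6
    ent_min: float = 0.7
    fold_temperature_C: float = 37.0
    fold_backend: str = "vienna"
    min_seed: int = 30
    terminal_window: int = 130
    max_mismatch: int = 0
    known_evalue_max: float = 1e-5
    orf_min_aa: int = ORF_MIN_AA_OBLIN

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class CcRnaRecord:
    """A surviving candidate with its metrics, structure, and ORFs."""

    candidate: CircularCandidate
    metrics: EvennessMetrics | None
    structure: SecondaryStructure | None
    paired_fraction: float | None
    orfs: list = field(default_factory=list)


@dataclass
class CascadeResult:
    funnel: dict[str, int]
    records: list[dict]  # per-input-contig verdicts
    survivors: list[CcRnaRecord]
    config: FilterConfig

    def funnel_tsv(self) -> str:
        lines = ["stage\tn"]
        lines += [f"{k}\t{v}" for k, v in self.funnel.items()]
        return "\n".join(lines) + "\n"


def _known_ids(known_hits_table, evalue_max: float) -> set[str]:
    """Ids with at least one homology hit at or below the E-value cutoff."""
    import pandas as pd

    df = known_hits_table
    if not isinstance(df, pd.DataFrame):
        df = pd.DataFrame.from_records(df)
    qcol = "qaccver" if "qaccver" in df.columns else df.columns[0]
    ecol = "evalue"
    if ecol not in df.columns:
        raise ValueError("known-hits table needs an 'evalue' column")
    hit = df[df[ecol] <= evalue_max]
    return set(hit[qcol].astype(str))


def run_cascade(
    contigs: list[Contig],
    alignments: dict[str, DepthProfile] | None = None,
    known_hits_table=None,
    config: FilterConfig | None = None,
) -> CascadeResult:
    """Run the full filter cascade over assembled contigs.

    ``alignments`` maps source contig id to a depth/start profile on the
    monomer coordinate system; a surviving candidate without mapping data
    fails the evenness stage with an explicit no-mapping reason.
    """
    config = config or FilterConfig()
    alignments = alignments or {}
    records: list[dict] = []
    funnel = {s: 0 for s in STAGES}
    funnel["input"] = len(contigs)

    # stage 1: circularize
    candidates: list[CircularCandidate] = []
    for contig in contigs:
        rec = {"id": contig.id, "stage_failed": None, "reason": None}
        try:
            cand = detect_terminal_redundancy(
                contig,
                min_seed=config.min_seed,
                terminal_window=config.terminal_window,
                max_mismatch=config.max_mismatch,
            )
        except NotEvaluable:
            rec["stage_failed"] = "circular"
            rec["reason"] = "too short to evaluate terminal redundancy"
            records.append(rec)
            continue
        if cand is None:
            rec["stage_failed"] = "circular"
            rec["reason"] = "no terminal redundancy"
            records.append(rec)
            continue
        candidates.append(canonicalize(cand))
        records.append(rec)
    funnel["circular"] = len(candidates)

    # stage 2: dedup
    deduped = dedup_candidates(candidates)
    surviving_ids = {c.source_id for c in deduped}
    for rec in records:
        if rec["stage_failed"] is None and rec["id"] not in surviving_ids:
            rec["stage_failed"] = "dedup"
            rec["reason"] = "duplicate of another canonical monomer"
    funnel["dedup"] = len(deduped)

    # stage 3: known-sequence exclusion
    if known_hits_table is not None:
        known = _known_ids(known_hits_table, config.known_evalue_max)
        kept = []
        for c in deduped:
            if c.source_id in known:
                _fail(records, c.source_id, "known_excluded",
                      f"homology hit at E <= {config.known_evalue_max:g}")
            else:
                kept.append(c)
        deduped = kept
    funnel["known_excluded"] = len(deduped)

    # stage 4: length
    kept = []
    for c in deduped:
        if c.monomer_len < config.min_len_nt:
            _fail(records, c.source_id, "length",
                  f"monomer {c.monomer_len} nt < {config.min_len_nt}")
        else:
            kept.append(c)
    deduped = kept
    funnel["length"] = len(deduped)

    # stage 5: mean depth
    kept = []
    for c in deduped:
        prof = alignments.get(c.source_id)
        if prof is not None and prof.mean_depth >= config.min_mean_depth:
            kept.append(c)
        elif prof is None:
            # no mapping: cannot establish coverage; fails here
            _fail(records, c.source_id, "depth", "no mapping data")
        else:
            _fail(records, c.source_id, "depth",
                  f"mean depth {prof.mean_depth:.1f} < {config.min_mean_depth}")
    deduped = kept
    funnel["depth"] = len(deduped)

    # stage 6: secondary structure
    kept: list[tuple[CircularCandidate, SecondaryStructure, float]] = []
    for c in deduped:
        st = fold(
            c.monomer,
            seq_id=c.source_id,
            temperature_C=config.fold_temperature_C,
            circular=True,
            backend=config.fold_backend,
        )
        pf = paired_fraction(st)
        if pf > config.min_paired_frac:
            kept.append((c, st, pf))
        else:
            _fail(records, c.source_id, "structure",
                  f"paired fraction {pf:.2f} <= {config.min_paired_frac}")
    funnel["structure"] = len(kept)

    # stage 7: evenness
    survivors: list[CcRnaRecord] = []
    for c, st, pf in kept:
        prof = alignments.get(c.source_id)
        metrics = evenness_verdict(prof, config.cv_max, config.ent_min)
        if not metrics.passed:
            _fail(records, c.source_id, "evenness",
                  f"CV={metrics.normalized_cv} entropy={metrics.normalized_entropy}")
            continue
        orfs = find_orfs_circular(c.monomer, min_aa=config.orf_min_aa)
        survivors.append(
            CcRnaRecord(
                candidate=c,
                metrics=metrics,
                structure=st,
                paired_fraction=pf,
                orfs=orfs,
            )
        )
    funnel["evenness"] = len(survivors)

    log.info("cascade funnel: %s", funnel)
    return CascadeResult(
        funnel=funnel, records=records, survivors=survivors, config=config
    )


def _fail(records: list[dict], source_id: str, stage: str, reason: str) -> None:
    for rec in records:
        if rec["id"] == source_id and rec["stage_failed"] is None:
            rec["stage_failed"] = stage
            rec["reason"] = reason
            return
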
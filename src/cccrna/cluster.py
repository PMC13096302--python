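"""Profile-score distances, UPGMA dendrograms, tree grafting,
rotation-invariant nucleotide identity, and CRISPR-spacer post-processing.

Profile-profile comparison scores S_AB (with self-scores on the diagonal)
are converted to distances d_AB = -ln(S_AB / min(S_AA, S_BB)); pairs with
no detected relationship receive an artificial low score so they land
beyond the merge radius without infinities.  The UPGMA dendrogram built on
those distances drives iterative cluster merging (merge when d <= 2.2 or
alignment coverage >= 0.66).

Nucleotide identity between circular sequences is rotation-invariant: one
sequence is aligned against the doubled other, over both strands, with the
shorter sequence length as the denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .seqio import revcomp


# ---------------------------------------------------------------------------
# score -> distance


@dataclass
class ScoreMatrix:
    """Symmetric profile-comparison scores with self-scores on the diagonal.

    ``missing`` marks pairs for which no relationship was detected."""

    ids: list[str]
    S: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.ids)
        if self.S.shape != (n, n):
            raise ValueError("score matrix shape mismatch")
        if self.missing is None:
            self.missing = np.zeros((n, n), dtype=bool)


def scores_to_distances(scores: ScoreMatrix, missing_fill: float | None = None):
    """Convert scores to distances d_AB = -ln(S_AB / min(S_AA, S_BB)).

    Missing pairs are first filled with ``missing_fill`` (default: the
    minimum observed off-diagonal score divided by 10).  Ratios above 1
    (a cross-score exceeding the smaller self-score) clamp to distance 0.
    Returns a scikit-bio DistanceMatrix.
    """
    from skbio import DistanceMatrix

    S = scores.S.copy()
    n = len(scores.ids)
    observed = S[~scores.missing & ~np.eye(n, dtype=bool)]
    if scores.missing.any():
        if missing_fill is None:
            if observed.size == 0:
                raise ValueError("all off-diagonal scores missing and no fill given")
            missing_fill = float(observed.min()) / 10.0
        S[scores.missing] = missing_fill
    if (S <= 0).any():
        raise ValueError("scores must be positive")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s_ab = (S[i, j] + S[j, i]) / 2.0
            ratio = s_ab / min(S[i, i], S[j, j])
            d = max(0.0, -math.log(ratio))
            D[i, j] = D[j, i] = d
    return DistanceMatrix(D, ids=scores.ids)


def merge_decision(
    distance: float, coverage: float, d_max: float = 2.2, cov_min: float = 0.66
) -> bool:
    """Merge neighbouring clusters when the distance does not exceed
    ``d_max`` or the alignment coverage is at least ``cov_min``."""
    return distance <= d_max or coverage >= cov_min


# ---------------------------------------------------------------------------
# trees


@dataclass
class DendrogramNode:
    """Rooted tree node; ``length`` is the branch to the parent, ``height``
    the ultrametric merge height for UPGMA-built nodes."""

    name: str | None = None
    length: float = 0.0
    children: list["DendrogramNode"] = field(default_factory=list)
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["DendrogramNode"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    def copy(self) -> "DendrogramNode":
        return DendrogramNode(
            name=self.name,
            length=self.length,
            children=[c.copy() for c in self.children],
            height=self.height,
        )

    def to_newick(self, include_root_length: bool = False) -> str:
        def fmt(node: DendrogramNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:.6g}"

        if self.is_leaf:
            body = f"{self.name}"
        else:
            body = "(" + ",".join(fmt(c) for c in self.children) + ")"
        if include_root_length:
            body += f":{self.length:.6g}"
        return body + ";"


def upgma(dm) -> DendrogramNode:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    ``dm`` is a scikit-bio DistanceMatrix or an (ids, square ndarray) pair.
    Merge heights are half the pair distance at agglomeration (ultrametric
    leaf depth); ties break on the lexicographically smallest member id.
    """
    if isinstance(dm, tuple):
        ids, D = dm
        D = np.asarray(D, dtype=float)
    else:
        ids, D = list(dm.ids), dm.data.copy()
    n = len(ids)
    if n == 0:
        raise ValueError("empty distance matrix")
    nodes = [DendrogramNode(name=i) for i in ids]
    if n == 1:
        return nodes[0]
    active = list(range(n))
    size = {i: 1 for i in range(n)}
    min_id = {i: ids[i] for i in range(n)}
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    node_of = {i: nodes[i] for i in range(n)}
    next_idx = n
    while len(active) > 1:
        best = None
        for a_pos in range(len(active)):
            for b_pos in range(a_pos + 1, len(active)):
                i, j = active[a_pos], active[b_pos]
                d = dist[(min(i, j), max(i, j))]
                tie = tuple(sorted((min_id[i], min_id[j])))
                key = (d, tie)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (_, _), i, j = best[0], best[1], best[2]
        d = dist[(min(i, j), max(i, j))]
        h = d / 2.0
        left, right = node_of[i], node_of[j]
        left.length = h - left.height
        right.length = h - right.height
        parent = DendrogramNode(children=[left, right], height=h)
        k = next_idx
        next_idx += 1
        for other in active:
            if other in (i, j):
                continue
            di = dist[(min(i, other), max(i, other))]
            dj = dist[(min(j, other), max(j, other))]
            dist[(min(k, other), max(k, other))] = (
                size[i] * di + size[j] * dj
            ) / (size[i] + size[j])
        size[k] = size[i] + size[j]
        min_id[k] = min(min_id[i], min_id[j])
        node_of[k] = parent
        active = [a for a in active if a not in (i, j)] + [k]
    return node_of[active[0]]


def _adjacency(root: DendrogramNode):
    """Undirected weighted adjacency of a rooted tree, keyed by node id."""
    adj: dict[int, list[tuple[DendrogramNode, float]]] = {}
    index: dict[int, DendrogramNode] = {}

    def walk(node: DendrogramNode) -> None:
        index[id(node)] = node
        adj.setdefault(id(node), [])
        for c in node.children:
            index[id(c)] = c
            adj.setdefault(id(c), [])
            adj[id(node)].append((c, c.length))
            adj[id(c)].append((node, c.length))
            walk(c)

    walk(root)
    return adj, index


def _paths_from(start: DendrogramNode, adj):
    """Distances and predecessor map from ``start`` over the whole tree."""
    dist = {id(start): 0.0}
    prev: dict[int, DendrogramNode] = {}
    stack = [start]
    while stack:
        u = stack.pop()
        for v, w in adj[id(u)]:
            if id(v) not in dist:
                dist[id(v)] = dist[id(u)] + w
                prev[id(v)] = u
                stack.append(v)
    return dist, prev


def midpoint_root(root: DendrogramNode) -> DendrogramNode:
    """Re-root a branch-length tree at the midpoint of the longest
    leaf-to-leaf path."""
    root = root.copy()
    leaves = root.leaves()
    if len(leaves) < 2:
        return root
    adj, _ = _adjacency(root)
    best = None
    for a in leaves:
        dist, prev = _paths_from(a, adj)
        for b in leaves:
            if b is a:
                continue
            d = dist[id(b)]
            if best is None or d > best[0]:
                best = (d, a, b, prev)
    total, a, b, prev = best
    # walk the path b -> a, find where cumulative distance from a crosses total/2
    path = [b]
    while path[-1] is not a:
        path.append(prev[id(path[-1])])
    path.reverse()  # a ... b
    half = total / 2.0
    cum = 0.0
    wmap = {}
    for u in adj:
        for v, w in adj[u]:
            wmap[(u, id(v))] = w
    for u, v in zip(path, path[1:]):
        w = wmap[(id(u), id(v))]
        if cum + w >= half - 1e-12:
            # midpoint on edge (u, v), at (half - cum) from u
            x = half - cum
            return _reroot_on_edge(u, v, x, w, adj)
        cum += w
    return root  # pragma: no cover


def _reroot_on_edge(u, v, dist_from_u, edge_len, adj) -> DendrogramNode:
    new_root = DendrogramNode()

    def orient(node: DendrogramNode, parent_id: int, length: float) -> DendrogramNode:
        out = DendrogramNode(name=node.name, length=length, height=node.height)
        for nb, w in adj[id(node)]:
            if id(nb) != parent_id:
                out.children.append(orient(nb, id(node), w))
        # suppress unary internal nodes left over from the old root
        if len(out.children) == 1 and out.name is None:
            child = out.children[0]
            child.length += out.length
            return child
        return out

    # children of the new root: u-side and v-side, cutting edge (u, v)
    u_side = orient(u, id(v), dist_from_u)
    v_side = orient(v, id(u), edge_len - dist_from_u)
    new_root.children = [u_side, v_side]
    return new_root


def graft(
    tree: DendrogramNode, leaf_id: str, subtree: DendrogramNode
) -> DendrogramNode:
    """Replace the named leaf with ``subtree``, preserving the leaf's stem
    branch length."""
    tree = tree.copy()
    found = []

    def walk(node: DendrogramNode) -> None:
        for k, c in enumerate(node.children):
            if c.is_leaf and c.name == leaf_id:
                found.append((node, k, c))
            else:
                walk(c)

    if tree.is_leaf and tree.name == leaf_id:
        new = subtree.copy()
        new.length = tree.length
        return new
    walk(tree)
    if not found:
        raise KeyError(f"leaf {leaf_id!r} not in tree")
    parent, k, old = found[0]
    new = subtree.copy()
    new.length = old.length
    parent.children[k] = new
    return tree


# ---------------------------------------------------------------------------
# alignment-column trimming


def trim_gap_columns(
    alignment: list[str], max_gap_frac: float, gap_chars: str = "-."
) -> tuple[list[str], list[int]]:
    """Drop columns whose gap fraction exceeds ``max_gap_frac``.

    Returns the trimmed rows (order preserved) and the indices of the
    surviving columns in the input alignment."""
    if not alignment:
        return [], []
    width = len(alignment[0])
    if any(len(r) != width for r in alignment):
        raise ValueError("ragged alignment")
    n = len(alignment)
    gaps = set(gap_chars)
    kept = [
        c
        for c in range(width)
        if sum(r[c] in gaps for r in alignment) / n <= max_gap_frac
    ]
    trimmed = ["".join(r[c] for c in kept) for r in alignment]
    return trimmed, kept


# ---------------------------------------------------------------------------
# rotation-invariant identity and clustering


def circular_identity(a: str, b: str, both_strands: bool = True) -> float:
    """Best nucleotide identity over all rotations of two circular
    sequences (and optionally both strands).

    Each sequence is aligned against the doubled other (edit-distance
    alignment); identity = matching positions / min(len a, len b), taking
    the max over both orderings and strands.
    """
    import edlib

    if not a or not b:
        raise ValueError("empty sequence")
    min_len = min(len(a), len(b))

    def one(query: str, target: str) -> float:
        res = edlib.align(query, target + target, mode="HW", task="distance")
        return max(0.0, 1.0 - res["editDistance"] / min_len)

    cands = [one(b, a), one(a, b)]
    if both_strands:
        rb = revcomp(b)
        cands += [one(rb, a), one(a, rb)]
    return min(1.0, max(cands))


def _greedy_cluster(items: list[tuple[str, str]], threshold: float) -> list[list[tuple[str, str]]]:
    """Greedy length-descending centroid clustering at a given identity."""
    ordered = sorted(items, key=lambda kv: (-len(kv[1]), kv[0]))
    clusters: list[list[tuple[str, str]]] = []
    for sid, seq in ordered:
        for cl in clusters:
            if circular_identity(cl[0][1], seq) >= threshold:
                cl.append((sid, seq))
                break
        else:
            clusters.append([(sid, seq)])
    return clusters


def cluster_and_name(
    seqs: dict[str, str], t1: float = 0.80, t2: float = 0.95, pad: int = 6
) -> dict[str, str]:
    """Two-level greedy ANI clustering with Obelisk_X_Y_Z nomenclature.

    X numbers the clusters at ``t1`` identity (by descending size, then
    centroid id), Y the sub-clusters at ``t2`` within each X, Z the strain
    within each Y; all 1-based, zero-padded to ``pad`` digits.
    """
    items = list(seqs.items())
    level1 = _greedy_cluster(items, t1)
    level1.sort(key=lambda cl: (-len(cl), cl[0][0]))
    labels: dict[str, str] = {}
    for xi, cl in enumerate(level1, 1):
        level2 = _greedy_cluster(cl, t2)
        level2.sort(key=lambda sub: (-len(sub), sub[0][0]))
        for yi, sub in enumerate(level2, 1):
            for zi, (sid, _) in enumerate(sub, 1):
                labels[sid] = f"Obelisk_{xi:0{pad}d}_{yi:0{pad}d}_{zi:0{pad}d}"
    return labels


# ---------------------------------------------------------------------------
# CRISPR spacer match post-processing


@dataclass(frozen=True)
class SpacerMatch:
    """A spacer-protospacer match mapped back to the monomer circle."""

    spacer_id: str
    obelisk_id: str
    spacer_len: int
    aligned_len: int
    n_mismatch: int
    start: int  # monomer coordinate, 0-based
    end: int  # exclusive; may wrap past L
    strand: str
    host_taxon: str | None = None
    merged_spacers: tuple[str, ...] = ()


BLAST6_COLUMNS = [
    "qaccver", "saccver", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "nident",
    "slen",
]


def read_spacer_table(path, columns: list[str] | None = None):
    """Read a BLAST outfmt-6-style (or MMseqs convertalis m8) spacer match
    table; query = doubled obelisk, subject = spacer."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", header=None, names=columns or BLAST6_COLUMNS)


def filter_and_merge_spacers(
    matches,
    target_lens: dict[str, int],
    preset: str = "local",
    max_non_overlap: int = 10,
    host_taxa: dict[str, str] | None = None,
):
    """Filter spacer matches against doubled Obelisk targets, reduce
    coordinates to the monomer, deduplicate the doubled-copy hits, and
    merge near-coincident protospacer loci.

    ``preset="local"`` keeps matches covering >= 90% of the spacer with
    >= 16 matching nucleotides; ``preset="hq"`` keeps full-coverage matches
    at >= 80% identity.  Matches whose non-overlapping portions total at
    most ``max_non_overlap`` nt are combined into one locus.  Returns
    (survivors, summary) where the summary reports per-obelisk locus counts
    and the fraction of kept matches with <= 1 mismatch.
    """
    import pandas as pd

    if not isinstance(matches, pd.DataFrame):
        matches = pd.DataFrame.from_records(matches)
    host_taxa = host_taxa or {}
    kept: list[SpacerMatch] = []
    n_le1_mismatch = 0
    n_kept_rows = 0
    for _, row in matches.iterrows():
        ob = str(row["qaccver"])
        if ob not in target_lens:
            raise KeyError(f"unknown obelisk id {ob!r}")
        L = target_lens[ob]
        slen = int(row["slen"])
        alen = int(row["length"])
        nident = int(row.get("nident", round(alen * float(row["pident"]) / 100.0)))
        mism = int(row["mismatch"])
        coverage = alen / slen
        if preset == "local":
            if not (coverage >= 0.9 and nident >= 16):
                continue
        elif preset == "hq":
            if not (float(row["pident"]) >= 80.0 and alen >= slen):
                continue
        else:
            raise ValueError(f"unknown preset {preset!r}")
        q0, q1 = int(row["qstart"]) - 1, int(row["qend"])  # to 0-based half-open
        if q0 < 0 or q1 > 2 * L:
            import logging

            logging.getLogger("cccrna").warning(
                "rejected spacer match %s on %s: coords beyond doubled target",
                row["saccver"], ob,
            )
            continue
        strand = "+"
        s0, s1 = int(row["sstart"]), int(row["send"])
        if s0 > s1:
            strand = "-"
        start = q0 % L
        kept.append(
            SpacerMatch(
                spacer_id=str(row["saccver"]),
                obelisk_id=ob,
                spacer_len=slen,
                aligned_len=alen,
                n_mismatch=mism,
                start=start,
                end=start + alen,
                strand=strand,
                host_taxon=host_taxa.get(str(row["saccver"])),
            )
        )
        n_kept_rows += 1
        if mism <= 1:
            n_le1_mismatch += 1

    # deduplicate hits that recur one monomer-length apart on the doubled copy
    uniq: dict[tuple, SpacerMatch] = {}
    for m in kept:
        key = (m.obelisk_id, m.spacer_id, m.start, m.end - m.start, m.strand)
        uniq.setdefault(key, m)
    deduped = list(uniq.values())

    # merge near-coincident loci per obelisk
    merged: list[SpacerMatch] = []
    by_ob: dict[str, list[SpacerMatch]] = {}
    for m in deduped:
        by_ob.setdefault(m.obelisk_id, []).append(m)
    for ob, ms in sorted(by_ob.items()):
        ms.sort(key=lambda m: (m.start, m.end))
        groups: list[list[SpacerMatch]] = []
        for m in ms:
            placed = False
            for g in groups:
                rep = g[0]
                inter = max(
                    0, min(rep.end, m.end) - max(rep.start, m.start)
                )
                non_overlap = (rep.end - rep.start) + (m.end - m.start) - 2 * inter
                if non_overlap <= max_non_overlap:
                    g.append(m)
                    placed = True
                    break
            if not placed:
                groups.append([m])
        for g in groups:
            rep = g[0]
            merged.append(
                replace(
                    rep,
                    merged_spacers=tuple(m.spacer_id for m in g),
                )
            )

    summary = {
        "n_input": int(len(matches)),
        "n_pass_filter": n_kept_rows,
        "n_after_dedup": len(deduped),
        "n_loci": len(merged),
        "per_obelisk_loci": {ob: sum(1 for m in merged if m.obelisk_id == ob)
                             for ob in sorted(by_ob)},
        "frac_le1_mismatch": (n_le1_mismatch / n_kept_rows) if n_kept_rows else None,
    }
    return merged, summary
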
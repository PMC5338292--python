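"""Native-vs-foreign classification of MTPTs by phylogenetic placement.

The chain is: screen by best-hit lineage, build a homolog panel, align it
progressively, infer a distance tree with nonparametric bootstrap, then
read off the smallest well-supported clade containing the focal sequence.
A verdict of "foreign" requires that clade's lineage to be unrelated to
the recipient at the configured rank depth AND bootstrap support above
the threshold (default 70).

Tree inference is neighbor joining on general time-reversible distances
estimated from the pairwise divergence matrix (the -tr(Pi log(Pi^-1 F))
estimator), with supports from column-resampled replicates.  Externally
computed newick trees with support labels can be dropped in instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.cluster import hierarchy

from .genome_io import TaxonomyLineage, read_newick, tree_to_newick
from .mtpt_caller import MtptCall

logger = logging.getLogger("ohgt")

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
_DECODE = "ACGTN-"
GAP = 5
SATURATION_DISTANCE = 5.0


_LUT = np.full(256, GAP, dtype=np.int8)
for ch, code in _CODE.items():
    _LUT[ord(ch)] = code


def seq_to_codes(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return "".join(_DECODE[c] for c in codes)


@dataclass
class PanelMember:
    id: str
    sequence: str
    lineage: TaxonomyLineage | None = None
    compartment: str = "pt"  # pt | mtpt


@dataclass
class HomologPanel:
    """The focal MTPT sequence plus its homologs; ``alignment`` maps
    member id -> aligned row once built."""

    focal_id: str
    members: list[PanelMember]
    alignment: dict[str, str] | None = None

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate panel member ids")
        if self.focal_id not in set(ids):
            raise ValueError("focal sequence missing from panel")

    def member(self, mid: str) -> PanelMember:
        return next(m for m in self.members if m.id == mid)


@dataclass
class PhyloPlacement:
    tree: object  # dendropy.Tree
    focal_tip: str
    sister_group: list[str]
    support: int
    donor_lineage: TaxonomyLineage | None
    verdict: str  # native | foreign | unresolved
    donor_sister_flag: bool = False


# ---------------------------------------------------------------------------
# Progressive alignment
# ---------------------------------------------------------------------------

# column-pair scoring for the profile aligner: +2 match, -3 mismatch,
# N neutral; affine gaps 7 to open (first column) + 2 per extra column
_M5 = np.array(
    [
        [2.0, -3.0, -3.0, -3.0, 0.0],
        [-3.0, 2.0, -3.0, -3.0, 0.0],
        [-3.0, -3.0, 2.0, -3.0, 0.0],
        [-3.0, -3.0, -3.0, 2.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0],
    ]
)
_GO = -7.0
_GE = -2.0


@njit(cache=True)
def _gotoh(S, go, ge):  # pragma: no cover - exercised via build_alignment
    L1, L2 = S.shape
    NEG = -1e30
    M = np.full((L1 + 1, L2 + 1), NEG, dtype=np.float64)
    X = np.full((L1 + 1, L2 + 1), NEG, dtype=np.float64)
    Y = np.full((L1 + 1, L2 + 1), NEG, dtype=np.float64)
    M[0, 0] = 0.0
    for i in range(1, L1 + 1):
        X[i, 0] = go + (i - 1) * ge
    for j in range(1, L2 + 1):
        Y[0, j] = go + (j - 1) * ge
    for i in range(1, L1 + 1):
        for j in range(1, L2 + 1):
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = best + S[i - 1, j - 1]
            a = M[i - 1, j] + go
            b = X[i - 1, j] + ge
            X[i, j] = a if a >= b else b
            a = M[i, j - 1] + go
            b = Y[i, j - 1] + ge
            Y[i, j] = a if a >= b else b
    # traceback; tie rule: diagonal > up(X) > left(Y)
    path = np.empty((L1 + L2, 2), dtype=np.int32)
    k = L1 + L2
    i, j = L1, L2
    state = 0
    if X[i, j] > M[i, j] and X[i, j] >= Y[i, j]:
        state = 1
    elif Y[i, j] > M[i, j] and Y[i, j] > X[i, j]:
        state = 2
    while i > 0 or j > 0:
        k -= 1
        if state == 0 and i > 0 and j > 0:
            path[k, 0] = i - 1
            path[k, 1] = j - 1
            prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > prev and X[i - 1, j - 1] >= Y[i - 1, j - 1]:
                state = 1
            elif Y[i - 1, j - 1] > prev and Y[i - 1, j - 1] > X[i - 1, j - 1]:
                state = 2
            i -= 1
            j -= 1
        elif state == 1 or (state == 0 and j == 0):
            path[k, 0] = i - 1
            path[k, 1] = -1
            if M[i - 1, j] + go >= X[i - 1, j] + ge:
                state = 0
            i -= 1
        else:
            path[k, 0] = -1
            path[k, 1] = j - 1
            if M[i, j - 1] + go >= Y[i, j - 1] + ge:
                state = 0
            j -= 1
    return path[k:]


def _profile_freqs(codes: np.ndarray) -> np.ndarray:
    """(L, 5) letter counts per column; gaps contribute nothing."""
    n, L = codes.shape
    F = np.zeros((L, 5))
    for letter in range(5):
        F[:, letter] = (codes == letter).sum(axis=0)
    return F


def _align_profiles(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    FA = _profile_freqs(A)
    FB = _profile_freqs(B)
    S = (FA @ _M5 @ FB.T) / (A.shape[0] * B.shape[0])
    path = _gotoh(S, _GO, _GE)
    L = path.shape[0]
    outA = np.full((A.shape[0], L), GAP, dtype=np.int8)
    outB = np.full((B.shape[0], L), GAP, dtype=np.int8)
    ia = path[:, 0] >= 0
    ib = path[:, 1] >= 0
    outA[:, ia] = A[:, path[ia, 0]]
    outB[:, ib] = B[:, path[ib, 1]]
    return outA, outB


def _kmer_distance(seqs: list[str], k: int = 6) -> np.ndarray:
    sets = []
    for s in seqs:
        sets.append({s[i : i + k] for i in range(max(1, len(s) - k + 1))})
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j]))
            shared = len(sets[i] & sets[j]) if denom else 0
            d = 1.0 - (shared / denom if denom else 0.0)
            D[i, j] = D[j, i] = d
    return D


def build_alignment(panel: HomologPanel) -> HomologPanel:
    """Progressive alignment guided by a k-mer-distance UPGMA tree.

    Deterministic for a fixed member order; pairwise/profile steps use
    affine-gap global alignment with a diagonal-first tie rule.
    """
    if len(panel.members) < 2:
        raise ValueError("need at least 2 sequences to align")
    seqs = [m.sequence for m in panel.members]
    if len({len(s) for s in seqs}) == 1 and len(set(seqs)) == 1:
        pass  # identical sequences align trivially but go through the same path
    D = _kmer_distance(seqs)
    n = len(seqs)
    if n == 2:
        order: list[tuple[int, int]] = [(0, 1)]
    else:
        cond = D[np.triu_indices(n, k=1)]
        Z = hierarchy.linkage(cond, method="average")
        order = [(int(a), int(b)) for a, b, _, _ in Z]
    profiles: dict[int, tuple[list[int], np.ndarray]] = {
        i: ([i], seq_to_codes(s)[None, :]) for i, s in enumerate(seqs)
    }
    nxt = n
    for a, b in order:
        rows_a, prof_a = profiles.pop(a)
        rows_b, prof_b = profiles.pop(b)
        outA, outB = _align_profiles(prof_a, prof_b)
        profiles[nxt] = (rows_a + rows_b, np.vstack([outA, outB]))
        nxt += 1
    rows, prof = profiles.popitem()[1]
    aligned = {panel.members[r].id: codes_to_seq(prof[k]) for k, r in enumerate(rows)}
    panel.alignment = {m.id: aligned[m.id] for m in panel.members}
    return panel


# ---------------------------------------------------------------------------
# Distances and neighbor joining
# ---------------------------------------------------------------------------


def _pair_tables(codes: np.ndarray) -> list[tuple[int, int, np.ndarray, np.ndarray]]:
    """For each i<j: (i, j, column indices with both states < 4,
    16-state pair codes at those columns)."""
    n = codes.shape[0]
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[i], codes[j]
            valid = np.flatnonzero((a < 4) & (b < 4))
            state = (a[valid].astype(np.int64) * 4 + b[valid]).astype(np.int64)
            out.append((i, j, valid, state))
    return out


def _gtr_distances_from_counts(counts: np.ndarray) -> np.ndarray:
    """counts: (P, 4, 4) pair-state counts -> (P,) GTR distances."""
    # diagonal pseudocount guards absent bases without faking divergence
    counts = counts + 0.03125 * np.eye(4)
    Fs = 0.5 * (counts + counts.transpose(0, 2, 1))
    tot = Fs.sum(axis=(1, 2), keepdims=True)
    F = Fs / tot
    pi = F.sum(axis=2)
    sp = 1.0 / np.sqrt(pi)
    B = sp[:, :, None] * F * sp[:, None, :]
    w, V = np.linalg.eigh(B)
    saturated = w[:, 0] <= 1e-9
    logw = np.log(np.clip(w, 1e-9, None))
    logB_diag = np.einsum("pij,pj,pij->pi", V, logw, V)
    d = -np.einsum("pi,pi->p", pi, logB_diag)
    d = np.where(saturated, SATURATION_DISTANCE, np.maximum(d, 0.0))
    return d


def gtr_distance_matrix(
    codes: np.ndarray, column_weights: np.ndarray | None = None
) -> np.ndarray:
    """Pairwise GTR distances from an encoded alignment (n, L)."""
    n, L = codes.shape
    tables = _pair_tables(codes)
    counts = np.zeros((len(tables), 4, 4))
    for p, (_i, _j, valid, state) in enumerate(tables):
        if column_weights is None:
            c = np.bincount(state, minlength=16)
        else:
            c = np.bincount(state, weights=column_weights[valid], minlength=16)
        counts[p] = c.reshape(4, 4)
    d = _gtr_distances_from_counts(counts)
    D = np.zeros((n, n))
    for p, (i, j, _v, _s) in enumerate(tables):
        D[i, j] = D[j, i] = d[p]
    return D


def neighbor_joining(
    D: np.ndarray,
) -> tuple[list[tuple[int, int, float]], int]:
    """Classic NJ.  Leaves are nodes 0..n-1; internal nodes are appended.

    Returns (edges, total node count); branch lengths clamped at >= 0.
    Deterministic tie-breaking on (Q value, i, j).
    """
    n = D.shape[0]
    if n < 3:
        if n == 2:
            return [(0, 1, max(float(D[0, 1]), 0.0))], 2
        raise ValueError("need >= 2 taxa")
    D = D.copy().astype(float)
    active = list(range(n))
    dist = {(i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)}

    def d(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    edges: list[tuple[int, int, float]] = []
    next_node = n
    while len(active) > 3:
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        m = len(active)
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                i, j = active[ii], active[jj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = d(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        u = next_node
        next_node += 1
        edges.append((u, i, max(li, 0.0)))
        edges.append((u, j, max(lj, 0.0)))
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d(i, k) + d(j, k) - dij)
            dist[(min(u, k), max(u, k))] = max(duk, 0.0)
        active = [k for k in active if k not in (i, j)] + [u]
    i, j, k = active
    u = next_node
    next_node += 1
    li = 0.5 * (d(i, j) + d(i, k) - d(j, k))
    lj = 0.5 * (d(i, j) + d(j, k) - d(i, k))
    lk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
    edges.append((u, i, max(li, 0.0)))
    edges.append((u, j, max(lj, 0.0)))
    edges.append((u, k, max(lk, 0.0)))
    return edges, next_node


def _bipartitions(
    edges: list[tuple[int, int, float]], n_leaves: int
) -> dict[frozenset, tuple[int, int]]:
    """Map each internal edge's bipartition (side not containing leaf 0)
    to the edge (u, v)."""
    adj: dict[int, list[int]] = {}
    for u, v, _l in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    out: dict[frozenset, tuple[int, int]] = {}

    def leaves_under(start: int, avoid: int) -> set[int]:
        seen = set()
        stack = [start]
        visited = {avoid}
        while stack:
            x = stack.pop()
            if x in visited:
                continue
            visited.add(x)
            if x < n_leaves:
                seen.add(x)
            stack.extend(adj.get(x, []))
        return seen

    for u, v, _l in edges:
        side = leaves_under(v, u)
        if 0 in side:
            side = set(range(n_leaves)) - side
        if 2 <= len(side) <= n_leaves - 2:
            out[frozenset(side)] = (u, v)
    return out


def _edges_to_newick(
    edges: list[tuple[int, int, float]],
    names: list[str],
    supports: dict[tuple[int, int], int] | None = None,
) -> str:
    adj: dict[int, list[tuple[int, float]]] = {}
    for u, v, l in edges:
        adj.setdefault(u, []).append((v, l))
        adj.setdefault(v, []).append((u, l))
    root = max(adj)  # last internal node created

    def render(node: int, parent: int, length: float | None) -> str:
        children = [(c, l) for c, l in adj[node] if c != parent]
        if not children:
            body = names[node]
        else:
            inner = ",".join(render(c, node, l) for c, l in children)
            label = ""
            if supports is not None and parent >= 0:
                key = (min(node, parent), max(node, parent))
                if key in supports:
                    label = str(supports[key])
            body = f"({inner}){label}"
        if length is None:
            return body
        return f"{body}:{length:.6f}"

    return render(root, -1, None) + ";"


def infer_tree(
    alignment: dict[str, str],
    n_bootstrap: int = 1000,
    seed: int | None = None,
):
    """NJ tree on GTR distances with bootstrap supports (integer percent).

    Rows are processed in canonical (sorted-by-name) order so supports do
    not depend on input row order; the seed drives column resampling.
    Returns a dendropy tree whose internal nodes carry ``.support``.
    """
    names = sorted(alignment)
    if len(names) < 4:
        raise ValueError("need >= 4 aligned sequences")
    lengths = {len(alignment[x]) for x in names}
    if len(lengths) != 1:
        raise ValueError("aligned rows must have equal length")
    codes = np.vstack([seq_to_codes(alignment[x]) for x in names])
    all_gap = (codes == GAP).all(axis=0) | (codes == 4).all(axis=0)
    if all_gap.any():
        logger.warning("dropping %d uninformative all-gap columns", int(all_gap.sum()))
        codes = codes[:, ~all_gap]
    n, L = codes.shape

    tables = _pair_tables(codes)
    counts = np.zeros((len(tables), 4, 4))
    for p, (_i, _j, _valid, state) in enumerate(tables):
        counts[p] = np.bincount(state, minlength=16).reshape(4, 4)
    d0 = _gtr_distances_from_counts(counts)
    D = np.zeros((n, n))
    for p, (i, j, _v, _s) in enumerate(tables):
        D[i, j] = D[j, i] = d0[p]
    edges, _n_nodes = neighbor_joining(D)
    main_bips = _bipartitions(edges, n)

    rng = np.random.default_rng(seed)
    bip_counts: dict[frozenset, int] = {b: 0 for b in main_bips}
    for _rep in range(n_bootstrap):
        cols = rng.integers(0, L, L)
        w = np.bincount(cols, minlength=L).astype(float)
        counts_rep = np.zeros((len(tables), 4, 4))
        for p, (_i, _j, valid, state) in enumerate(tables):
            counts_rep[p] = np.bincount(
                state, weights=w[valid], minlength=16
            ).reshape(4, 4)
        d_rep = _gtr_distances_from_counts(counts_rep)
        Dr = np.zeros((n, n))
        for p, (i, j, _v, _s) in enumerate(tables):
            Dr[i, j] = Dr[j, i] = d_rep[p]
        rep_edges, _ = neighbor_joining(Dr)
        for bip in _bipartitions(rep_edges, n):
            if bip in bip_counts:
                bip_counts[bip] += 1

    supports = {}
    for bip, (u, v) in main_bips.items():
        pct = int(round(100.0 * bip_counts[bip] / max(n_bootstrap, 1)))
        supports[(min(u, v), max(u, v))] = pct
    newick = _edges_to_newick(edges, names, supports)
    return read_newick(newick)


# ---------------------------------------------------------------------------
# Placement classification
# ---------------------------------------------------------------------------


def screen_best_hit(
    call: MtptCall,
    recipient_lineage: TaxonomyLineage,
    unrelated_rank_depth: int = 2,
) -> bool | None:
    """True iff the best-hit subject lineage diverges from the recipient
    at/above the configured rank depth (putatively foreign); None when the
    lineage is unavailable (ambiguous)."""
    lin = call.best_subject_lineage
    if lin is None:
        logger.warning(
            "%s %d..%d: best-hit subject lineage missing; screen ambiguous",
            call.mt_id,
            call.start,
            call.end,
        )
        call.status = "ambiguous"
        return None
    return not lin.related_at(recipient_lineage, unrelated_rank_depth)


def _midpoint_rooted(tree):
    clone = read_newick(tree_to_newick(tree))
    try:
        clone.reroot_at_midpoint(update_bipartitions=False)
    except Exception:  # zero-length or degenerate trees: keep as-is
        pass
    return clone


def classify_placement(
    tree,
    focal_tip: str,
    recipient_lineage: TaxonomyLineage,
    taxonomy: dict[str, TaxonomyLineage],
    bs_threshold: int = 70,
    unrelated_rank_depth: int = 2,
    compartments: dict[str, str] | None = None,
) -> PhyloPlacement:
    """Walk rootward from the focal tip on the midpoint-rooted tree; the
    smallest clade with support > bs_threshold whose non-focal members
    share a lineage prefix decides the verdict."""
    rooted = _midpoint_rooted(tree)
    leaf = None
    for lf in rooted.leaf_node_iter():
        if lf.taxon and lf.taxon.label == focal_tip:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"focal tip {focal_tip!r} not in tree")

    # immediate sister set (for the donor-MTPT-sister flag)
    parent = leaf.parent_node
    sister_tips: list[str] = []
    if parent is not None:
        for child in parent.child_nodes():
            if child is leaf:
                continue
            for lf in child.leaf_iter():
                if lf.taxon and lf.taxon.label != focal_tip:
                    sister_tips.append(lf.taxon.label)

    node = leaf.parent_node
    verdict = "unresolved"
    donor: TaxonomyLineage | None = None
    support_out = 0
    while node is not None:
        sup = getattr(node, "support", None)
        if sup is not None and sup > bs_threshold:
            companions = [
                lf.taxon.label
                for lf in node.leaf_iter()
                if lf.taxon and lf.taxon.label != focal_tip
            ]
            lineages = [taxonomy.get(t) for t in companions]
            if any(l is None for l in lineages):
                raise ValueError("every non-focal tip needs a lineage")
            shared = lineages[0].ranks
            for l in lineages[1:]:
                shared = TaxonomyLineage(shared).shared_prefix(l)
                if not shared:
                    break
            if shared:
                clade_lineage = TaxonomyLineage(tuple(shared))
                support_out = int(sup)
                if not clade_lineage.related_at(recipient_lineage, unrelated_rank_depth):
                    verdict = "foreign"
                    donor = clade_lineage
                else:
                    verdict = "native"
                break
            # heterogeneous supported clade: keep walking rootward in
            # search of the smallest clade satisfying both conditions
        node = node.parent_node

    donor_sister = False
    if verdict == "foreign" and donor is not None and compartments and sister_tips:
        donor_sister = all(
            compartments.get(t) == "mtpt"
            and t in taxonomy
            and taxonomy[t].related_at(donor, unrelated_rank_depth)
            for t in sister_tips
        )
    return PhyloPlacement(
        tree=rooted,
        focal_tip=focal_tip,
        sister_group=sister_tips,
        support=support_out,
        donor_lineage=donor,
        verdict=verdict,
        donor_sister_flag=donor_sister,
    )


def place_mtpt(
    panel: HomologPanel,
    recipient_lineage: TaxonomyLineage,
    n_bootstrap: int = 1000,
    seed: int | None = None,
    bs_threshold: int = 70,
    unrelated_rank_depth: int = 2,
    tree=None,
) -> PhyloPlacement:
    """Align the panel, infer (or accept) a tree, classify the placement."""
    if tree is None:
        if panel.alignment is None:
            build_alignment(panel)
        tree = infer_tree(panel.alignment, n_bootstrap=n_bootstrap, seed=seed)
    taxonomy = {m.id: m.lineage for m in panel.members if m.lineage is not None}
    compartments = {m.id: m.compartment for m in panel.members}
    return classify_placement(
        tree,
        panel.focal_id,
        recipient_lineage,
        taxonomy,
        bs_threshold=bs_threshold,
        unrelated_rank_depth=unrelated_rank_depth,
        compartments=compartments,
    )
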
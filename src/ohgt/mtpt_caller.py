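"""MTPT calling: filter mt-vs-pt hits, drop ancient-homology loci, merge
nearby hits into calls, and per-genome content statistics.

Filtering precedes merging (a hit must individually exceed 200 bp and 70%
identity before it can contribute to a call), and merging acts on the
mitochondrial coordinate only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .genome_io import Feature, HomologyHit, TaxonomyLineage

logger = logging.getLogger("ohgt")

DEFAULT_BLACKLIST = frozenset({"atp1", "rrn18", "rrn26"})


@dataclass
class MtptCall:
    """A merged plastid-derived region on a mitochondrial genome."""

    mt_id: str
    start: int
    end: int
    supporting_hits: list[HomologyHit] = field(default_factory=list)
    gene_content: list[str] = field(default_factory=list)
    best_subject_lineage: TaxonomyLineage | None = None
    status: str = "ambiguous"  # native | putatively_foreign | foreign | ambiguous

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def best_hit(self) -> HomologyHit:
        return min(
            self.supporting_hits,
            key=lambda h: (-h.bitscore, h.evalue, h.subject_id),
        )


@dataclass(frozen=True)
class GenomeMtptStats:
    mt_id: str
    mtdna_length: int
    n_mtpts: int
    total_mtpt_length: int

    @property
    def pct_mtdna(self) -> float:
        return 100.0 * self.total_mtpt_length / self.mtdna_length


def filter_hits(
    hits: Iterable[HomologyHit],
    min_len: int = 201,
    min_identity: float = 70.0,
) -> list[HomologyHit]:
    """Keep hits with query span strictly >200 bp and identity strictly >70%.

    ``min_len``/``min_identity`` express the strict thresholds: a hit is
    kept iff span >= min_len (i.e. span > min_len - 1) and
    identity > min_identity.
    """
    return [
        h for h in hits if h.q_span >= min_len and h.pct_identity > min_identity
    ]


def exclude_ancient(
    hits: Iterable[HomologyHit],
    mt_features: Sequence[Feature],
    locus_blacklist: Iterable[str] = DEFAULT_BLACKLIST,
) -> list[HomologyHit]:
    """Drop hits whose query interval overlaps (>=1 bp) a blacklisted
    ancient-homology gene feature on the mitochondrial genome."""
    blacklist = set(locus_blacklist)
    black_feats = [f for f in mt_features if f.name in blacklist and f.kind == "gene"]
    missing = blacklist - {f.name for f in black_feats}
    if missing:
        logger.info("blacklist loci absent from annotation: %s", sorted(missing))
    out = []
    for h in hits:
        if any(f.overlaps(h.q_start, h.q_end) for f in black_feats):
            continue
        out.append(h)
    return out


def exclude_annotated_ptmts(
    hits: Iterable[HomologyHit],
    pt_features: dict[str, Sequence[Feature]],
) -> list[HomologyHit]:
    """Drop hits whose plastid subject interval overlaps an annotated
    mitochondrion-derived (ptmt) tract — the mirror image of the
    reverse-direction detector's exclusion, which keeps an mt->pt insert
    from echoing back as a spurious MTPT call."""
    out = []
    for h in hits:
        lo, hi = h.s_interval
        feats = pt_features.get(h.subject_id, ())
        if any(f.kind == "ptmt_annotation" and f.overlaps(lo, hi) for f in feats):
            continue
        out.append(h)
    return out


def _best_lineage(
    hits: Sequence[HomologyHit],
    subject_lineages: dict[str, TaxonomyLineage] | None,
) -> TaxonomyLineage | None:
    if not subject_lineages:
        return None
    best = min(hits, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
    return subject_lineages.get(best.subject_id)


def merge_mtpts(
    hits: Sequence[HomologyHit],
    max_gap: int = 99,
    subject_lineages: dict[str, TaxonomyLineage] | None = None,
    subject_features: dict[str, Sequence[Feature]] | None = None,
) -> list[MtptCall]:
    """Union filtered hits separated by gaps < 100 bp (<= max_gap) into
    MTPT calls on the mitochondrial coordinate.

    gap = next.q_start - prev.q_end - 1; the union is transitive, so the
    result is independent of input order.  Gene content is every plastid
    gene feature overlapped by any supporting hit's subject interval.
    """
    if not hits:
        return []
    mt_ids = {h.query_id for h in hits}
    if len(mt_ids) != 1:
        raise ValueError(f"hits span multiple mt genomes: {sorted(mt_ids)}")
    mt_id = mt_ids.pop()

    ordered = sorted(hits, key=lambda h: (h.q_start, h.q_end))
    groups: list[list[HomologyHit]] = [[ordered[0]]]
    env_end = ordered[0].q_end
    for h in ordered[1:]:
        gap = h.q_start - env_end - 1
        if gap <= max_gap:
            groups[-1].append(h)
            env_end = max(env_end, h.q_end)
        else:
            groups.append([h])
            env_end = h.q_end
    calls = []
    for group in groups:
        start = min(h.q_start for h in group)
        end = max(h.q_end for h in group)
        genes: list[str] = []
        if subject_features:
            seen = set()
            for h in group:
                lo, hi = h.s_interval
                for f in subject_features.get(h.subject_id, []):
                    if f.kind == "gene" and f.overlaps(lo, hi) and f.name not in seen:
                        seen.add(f.name)
                        genes.append(f.name)
        calls.append(
            MtptCall(
                mt_id=mt_id,
                start=start,
                end=end,
                supporting_hits=list(group),
                gene_content=genes,
                best_subject_lineage=_best_lineage(group, subject_lineages),
            )
        )
    return calls


def genome_stats(calls: Sequence[MtptCall], mtdna_length: int) -> GenomeMtptStats:
    """Per-genome MTPT content totals."""
    if not calls:
        return GenomeMtptStats("", mtdna_length, 0, 0)
    ordered = sorted(calls, key=lambda c: c.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise AssertionError(
                f"overlapping calls {a.start}..{a.end} and {b.start}..{b.end}"
            )
    total = sum(c.length for c in ordered)
    return GenomeMtptStats(ordered[0].mt_id, mtdna_length, len(ordered), total)


# ---------------------------------------------------------------------------
# Spearman rank correlation (tie-corrected, t-approximation p-value)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    defined: bool = True
    method: str = "t-approximation"


def _midranks(x: Sequence[float]) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their mid-rank."""
    arr = np.asarray(x, dtype=float)
    order = np.argsort(arr, kind="mergesort")
    ranks = np.empty(len(arr), dtype=float)
    i = 0
    while i < len(arr):
        j = i
        while j + 1 < len(arr) and arr[order[j + 1]] == arr[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        ranks[order[i : j + 1]] = mid
        i = j + 1
    return ranks


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0.0:
        return math.nan
    return float(a @ b) / denom


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    exact: bool | None = None,
) -> SpearmanResult:
    """Spearman rho = Pearson correlation of mid-ranks; two-sided p from
    t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df, or exact enumeration of all
    rank permutations when ``exact`` (allowed only for n <= 10)."""
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4")
    rx, ry = _midranks(x), _midranks(y)
    rho = _pearson(rx, ry)
    if math.isnan(rho):
        return SpearmanResult(math.nan, math.nan, n, defined=False)

    if exact is None:
        exact = False
    if exact:
        if n > 10:
            raise ValueError("exact permutation only supported for n <= 10")
        observed = abs(rho)
        count = total = 0
        for perm in permutations(range(n)):
            r = _pearson(rx, ry[list(perm)])
            total += 1
            if abs(r) >= observed - 1e-12:
                count += 1
        return SpearmanResult(rho, count / total, n, method="exact-permutation")

    if abs(rho) >= 1.0:
        return SpearmanResult(rho, 0.0, n)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return SpearmanResult(rho, min(1.0, p), n)
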
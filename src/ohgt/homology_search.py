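"""Seed-and-extend nucleotide local search producing BLAST-tabular hits.

Desk-scale stand-in for an external BLASTN run: exact-word seeding on both
strands, diagonal clustering, an ungapped x-drop prefilter, then optimal
gapped local alignment of each candidate envelope (affine gaps, Gotoh DP
via Biopython's C pairwise aligner).  Scores are converted to bit scores
and E-values with the standard Karlin-Altschul bookkeeping.

Deliberate divergences from BLASTN, documented here:

* no low-complexity (DUST) masking — synthetic inputs avoid such tracts;
* E-values use raw sequence lengths m, n rather than BLAST's
  edge-corrected effective lengths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import GenomeRecord, HomologyHit, revcomp

logger = logging.getLogger("ohgt")


@dataclass(frozen=True)
class SearchParams:
    """Scoring/seeding knobs; defaults mirror ``-task blastn``."""

    word_size: int = 20
    evalue_max: float = 1e-10
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    lam: float = 0.625
    K: float = 0.41
    x_drop: int = 100

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")

    @classmethod
    def mt2pt(cls) -> "SearchParams":
        """Mitochondrion-vs-plastid preset (word size 20)."""
        return cls(word_size=20)

    @classmethod
    def pt2mt(cls) -> "SearchParams":
        """Plastid-vs-mitochondrion preset (word size 7)."""
        return cls(word_size=7)


def raw_to_bitscore(S: float, params: SearchParams) -> float:
    """Karlin-Altschul normalised score S' = (lambda*S - ln K) / ln 2."""
    return (params.lam * S - math.log(params.K)) / math.log(2.0)


def bitscore_to_evalue(bitscore: float, m: int, n: int) -> float:
    """E = m * n * 2**(-S')."""
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    return float(m) * float(n) * math.pow(2.0, -bitscore)


def min_raw_score(m: int, n: int, params: SearchParams) -> float:
    """Smallest raw score whose E-value can still pass evalue_max."""
    bits = math.log2(m * n / params.evalue_max)
    return (bits * math.log(2.0) + math.log(params.K)) / params.lam


def _aligner(params: SearchParams) -> Align.PairwiseAligner:
    alph = "ACGTN"
    mat = substitution_matrices.Array(alph, dims=2)
    for a in alph:
        for b in alph:
            if a == b and a != "N":
                mat[a, b] = params.match
            else:
                mat[a, b] = params.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    # BLAST charges open+extend for a length-1 gap; Biopython charges the
    # open score for the first gap column only.
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner


_SEED_LUT = np.full(256, 4, dtype=np.int8)
for _ch, _code in zip(b"ACGTN", range(5)):
    _SEED_LUT[_ch] = _code


def _kmer_hashes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions, 2-bit-packed word hashes) for every N-free window."""
    codes = _SEED_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    L = len(codes)
    if L < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)
    n_win = L - k + 1
    H = np.zeros(n_win, dtype=np.uint64)
    for j in range(k):
        H = (H << np.uint64(2)) | codes[j : j + n_win].astype(np.uint64)
    is_n = (codes == 4).astype(np.int32)
    cum = np.concatenate([[0], np.cumsum(is_n)])
    clean = (cum[k:] - cum[:-k]) == 0
    pos = np.flatnonzero(clean)
    return pos, H[pos]


class SubjectIndex:
    """Sorted exact-word index over a subject sequence and its reverse
    complement; build once per (subject, word_size) and reuse."""

    def __init__(self, subject: GenomeRecord, word_size: int):
        if word_size > 31:
            raise ValueError("word_size must be <= 31")
        self.subject = subject
        self.word_size = word_size
        self.rc_seq = revcomp(subject.sequence)
        self.fwd = self._build(subject.sequence, word_size)
        self.rev = self._build(self.rc_seq, word_size)

    @staticmethod
    def _build(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
        pos, hashes = _kmer_hashes(seq, k)
        order = np.argsort(hashes, kind="stable")
        return hashes[order], pos[order]


def _find_seeds(
    qseq: str, index: tuple[np.ndarray, np.ndarray], k: int
) -> tuple[np.ndarray, np.ndarray]:
    """All (query position, subject position) exact word matches."""
    s_hashes, s_pos = index
    q_pos, q_hashes = _kmer_hashes(qseq, k)
    if len(q_hashes) == 0 or len(s_hashes) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    left = np.searchsorted(s_hashes, q_hashes, side="left")
    right = np.searchsorted(s_hashes, q_hashes, side="right")
    counts = right - left
    hit = counts > 0
    if not hit.any():
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    l, c = left[hit], counts[hit]
    total = int(c.sum())
    starts = np.concatenate([[0], np.cumsum(c)[:-1]])
    flat = np.repeat(l, c) + (np.arange(total) - np.repeat(starts, c))
    return np.repeat(q_pos[hit], c), s_pos[flat]


def _filter_sparse_seeds(
    q: np.ndarray, s: np.ndarray, min_run: int = 3, max_gap: int = 40
) -> tuple[np.ndarray, np.ndarray]:
    """Short-word searches drown in isolated random seeds; keep only
    seeds inside same-diagonal runs of >= min_run close neighbours.  Any
    alignment strong enough to pass the E-value cutoff contains exact
    stretches that survive this filter."""
    if len(q) == 0:
        return q, s
    diag = q - s
    order = np.lexsort((q, diag))
    dq, dd = q[order], diag[order]
    new_run = np.ones(len(dq), dtype=bool)
    new_run[1:] = (dd[1:] != dd[:-1]) | (dq[1:] - dq[:-1] > max_gap)
    run_id = np.cumsum(new_run) - 1
    run_len = np.bincount(run_id)
    keep = run_len[run_id] >= min_run
    kept = order[keep]
    return q[kept], s[kept]


@dataclass
class _Cluster:
    q_min: int
    q_max: int
    s_min: int
    s_max: int
    last_q: int
    last_diag: int
    seeds: list[tuple[int, int]] = field(default_factory=list)


def _cluster_seeds(
    seeds: list[tuple[int, int]], word: int, join: int, band: int
) -> list[_Cluster]:
    """Greedy sweep over seeds sorted by query position; a seed joins the
    most recent cluster within ``band`` diagonals and ``join`` bp."""
    clusters: list[_Cluster] = []
    by_bucket: dict[int, list[_Cluster]] = {}
    for q, s in sorted(seeds):
        diag = q - s
        bucket = diag // band
        target = None
        for b in (bucket - 1, bucket, bucket + 1):
            for cl in reversed(by_bucket.get(b, [])):
                if q - cl.last_q > join:
                    break
                if abs(diag - cl.last_diag) <= band and s >= cl.s_min - band:
                    target = cl
                    break
            if target:
                break
        if target is None:
            target = _Cluster(q, q + word - 1, s, s + word - 1, q, diag, [(q, s)])
            clusters.append(target)
            by_bucket.setdefault(bucket, []).append(target)
        else:
            target.q_min = min(target.q_min, q)
            target.q_max = max(target.q_max, q + word - 1)
            target.s_min = min(target.s_min, s)
            target.s_max = max(target.s_max, s + word - 1)
            target.last_q = q
            target.last_diag = diag
            target.seeds.append((q, s))
    return clusters


def _ungapped_score(qseq: str, sseq: str, q: int, s: int, params: SearchParams) -> int:
    """X-drop ungapped extension of a seed match in both directions."""
    match, mismatch, xd = params.match, params.mismatch, params.x_drop
    k = params.word_size
    score = best = match * k
    i, j = q + k, s + k
    while i < len(qseq) and j < len(sseq):
        score += match if (qseq[i] == sseq[j] and qseq[i] != "N") else mismatch
        if score > best:
            best = score
        if best - score > xd:
            break
        i += 1
        j += 1
    right_best = best
    score = right_best
    best = right_best
    i, j = q - 1, s - 1
    while i >= 0 and j >= 0:
        score += match if (qseq[i] == sseq[j] and qseq[i] != "N") else mismatch
        if score > best:
            best = score
        if best - score > xd:
            break
        i -= 1
        j -= 1
    return best


@dataclass
class _RawHit:
    q0: int  # 0-based inclusive on the query
    q1: int
    s0: int  # 0-based inclusive on the searched (possibly revcomp) subject
    s1: int
    score: float
    matches: int
    mismatches: int
    gap_opens: int
    aln_len: int


def _align_envelope(
    qseq: str,
    sseq: str,
    q_lo: int,
    q_hi: int,
    s_lo: int,
    s_hi: int,
    aligner: Align.PairwiseAligner,
) -> _RawHit | None:
    """Optimal gapped local alignment of an envelope slice."""
    qs = qseq[q_lo : q_hi + 1]
    ss = sseq[s_lo : s_hi + 1]
    if not qs or not ss:
        return None
    alns = aligner.align(qs, ss)
    if alns.score <= 0:
        return None
    try:
        aln = alns[0]
    except IndexError:
        return None
    blocks_q, blocks_s = aln.aligned
    if len(blocks_q) == 0:
        return None
    matches = mismatches = 0
    for (qa, qb), (sa, sb) in zip(blocks_q, blocks_s):
        for x, y in zip(qs[qa:qb], ss[sa:sb]):
            if x == y and x != "N":
                matches += 1
            else:
                mismatches += 1
    gap_opens = 0
    gap_cols = 0
    for idx in range(1, len(blocks_q)):
        dq = blocks_q[idx][0] - blocks_q[idx - 1][1]
        ds = blocks_s[idx][0] - blocks_s[idx - 1][1]
        if dq > 0:
            gap_opens += 1
            gap_cols += dq
        if ds > 0:
            gap_opens += 1
            gap_cols += ds
    aln_len = matches + mismatches + gap_cols
    return _RawHit(
        q0=q_lo + int(blocks_q[0][0]),
        q1=q_lo + int(blocks_q[-1][1]) - 1,
        s0=s_lo + int(blocks_s[0][0]),
        s1=s_lo + int(blocks_s[-1][1]) - 1,
        score=float(aln.score),
        matches=matches,
        mismatches=mismatches,
        gap_opens=gap_opens,
        aln_len=aln_len,
    )


def _align_envelope_adaptive(
    qseq: str,
    sseq: str,
    q_lo: int,
    q_hi: int,
    s_lo: int,
    s_hi: int,
    aligner: Align.PairwiseAligner,
    step: int = 600,
    max_rounds: int = 12,
) -> _RawHit | None:
    """Align an envelope, growing any side the optimal alignment runs
    into: seeds of a diverged homology often cover only part of it, so a
    fixed envelope would truncate the alignment."""
    for _ in range(max_rounds):
        rh = _align_envelope(qseq, sseq, q_lo, q_hi, s_lo, s_hi, aligner)
        if rh is None:
            return None
        grew = False
        if rh.q0 <= q_lo + 2 and q_lo > 0:
            q_lo = max(0, q_lo - step)
            grew = True
        if rh.q1 >= q_hi - 2 and q_hi < len(qseq) - 1:
            q_hi = min(len(qseq) - 1, q_hi + step)
            grew = True
        if rh.s0 <= s_lo + 2 and s_lo > 0:
            s_lo = max(0, s_lo - step)
            grew = True
        if rh.s1 >= s_hi - 2 and s_hi < len(sseq) - 1:
            s_hi = min(len(sseq) - 1, s_hi + step)
            grew = True
        if not grew:
            return rh
    return rh


def _chain_pass(
    hits: list[_RawHit],
    qseq: str,
    sseq: str,
    aligner: Align.PairwiseAligner,
    max_join_gap: int = 250,
    max_diag_shift: int = 120,
) -> list[_RawHit]:
    """Re-align envelopes of near-colinear hit pairs so one homologous
    tract yields one hit even when seeding split it."""
    merged_any = True
    while merged_any and len(hits) > 1:
        merged_any = False
        hits.sort(key=lambda h: h.q0)
        for i in range(len(hits)):
            for j in range(i + 1, len(hits)):
                a, b = hits[i], hits[j]
                if b.q0 - a.q1 > max_join_gap:
                    break
                qgap = b.q0 - a.q1 - 1
                sgap = b.s0 - a.s1 - 1
                diag_shift = abs((b.q0 - b.s0) - (a.q1 - a.s1))
                if (
                    -50 <= qgap <= max_join_gap
                    and -50 <= sgap <= max_join_gap
                    and diag_shift <= max_diag_shift
                ):
                    re_hit = _align_envelope(
                        qseq,
                        sseq,
                        min(a.q0, b.q0),
                        max(a.q1, b.q1),
                        min(a.s0, b.s0),
                        max(a.s1, b.s1),
                        aligner,
                    )
                    if re_hit is not None and re_hit.score >= max(a.score, b.score):
                        hits[i] = re_hit
                        hits.pop(j)
                        merged_any = True
                        break
            if merged_any:
                break
    return sorted(hits, key=lambda h: h.q0)


def _dedup(raw: list[_RawHit]) -> list[_RawHit]:
    raw.sort(key=lambda h: -h.score)
    kept: list[_RawHit] = []
    for h in raw:
        dup = False
        for k in kept:
            q_ov = min(h.q1, k.q1) - max(h.q0, k.q0) + 1
            s_ov = min(h.s1, k.s1) - max(h.s0, k.s0) + 1
            shorter_q = min(h.q1 - h.q0, k.q1 - k.q0) + 1
            shorter_s = min(h.s1 - h.s0, k.s1 - k.s0) + 1
            if q_ov >= 0.8 * shorter_q and s_ov >= 0.8 * shorter_s:
                dup = True
                break
        if not dup:
            kept.append(h)
    return kept


def find_hits(
    query: GenomeRecord,
    subject: GenomeRecord,
    params: SearchParams | None = None,
    subject_index: SubjectIndex | None = None,
) -> list[HomologyHit]:
    """All gapped local alignments between query and subject passing the
    E-value cutoff, on either strand, sorted by query start then
    descending bit score."""
    params = params or SearchParams()
    qseq = query.sequence
    m, n = len(qseq), len(subject.sequence)
    if params.word_size > min(m, n):
        logger.warning(
            "word_size %d exceeds min sequence length %d; no hits",
            params.word_size,
            min(m, n),
        )
        return []
    if subject_index is None:
        subject_index = SubjectIndex(subject, params.word_size)
    elif subject_index.word_size != params.word_size:
        raise ValueError("subject index word size does not match params")

    aligner = _aligner(params)
    s_min_raw = min_raw_score(m, n, params)
    # seeding over diverse inputs: wide joins for long words (few random
    # seeds), tight joins for short words (many random seeds)
    if params.word_size >= 12:
        join, band = 400, 100
    else:
        join, band = 60, 24
    pad = 40

    hits: list[HomologyHit] = []
    for strand, index, sseq in (
        ("+", subject_index.fwd, subject.sequence),
        ("-", subject_index.rev, subject_index.rc_seq),
    ):
        k = params.word_size
        q_arr, s_arr = _find_seeds(qseq, index, k)
        if k < 12:
            q_arr, s_arr = _filter_sparse_seeds(q_arr, s_arr)
        if len(q_arr) == 0:
            continue
        seeds = list(zip(q_arr.tolist(), s_arr.tolist()))
        raw_hits: list[_RawHit] = []
        for cl in _cluster_seeds(seeds, k, join, band):
            # sound upper bound from the envelope spans
            span = min(cl.q_max - cl.q_min, cl.s_max - cl.s_min) + 1 + 2 * pad
            if params.match * span < s_min_raw:
                continue
            mid = cl.seeds[len(cl.seeds) // 2]
            est = _ungapped_score(qseq, sseq, mid[0], mid[1], params)
            if est < 0.5 * s_min_raw:
                continue
            rh = _align_envelope_adaptive(
                qseq,
                sseq,
                max(0, cl.q_min - pad),
                min(m - 1, cl.q_max + pad),
                max(0, cl.s_min - pad),
                min(n - 1, cl.s_max + pad),
                aligner,
            )
            if rh is not None:
                raw_hits.append(rh)
        raw_hits = _dedup(raw_hits)
        raw_hits = _chain_pass(raw_hits, qseq, sseq, aligner)
        for rh in raw_hits:
            bit = raw_to_bitscore(rh.score, params)
            ev = bitscore_to_evalue(bit, m, n)
            if ev > params.evalue_max:
                continue
            if strand == "+":
                s_start, s_end = rh.s0 + 1, rh.s1 + 1
            else:
                s_start, s_end = n - rh.s0, n - rh.s1
            hits.append(
                HomologyHit(
                    query_id=query.id,
                    subject_id=subject.id,
                    pct_identity=round(100.0 * rh.matches / rh.aln_len, 2),
                    aln_len=rh.aln_len,
                    mismatches=rh.mismatches,
                    gap_opens=rh.gap_opens,
                    q_start=rh.q0 + 1,
                    q_end=rh.q1 + 1,
                    s_start=s_start,
                    s_end=s_end,
                    evalue=ev,
                    bitscore=round(bit, 1),
                )
            )
    hits.sort(key=lambda h: (h.q_start, -h.bitscore))
    return hits


def find_hits_vs_panel(
    query: GenomeRecord,
    panel: list[GenomeRecord],
    params: SearchParams | None = None,
    index_cache: dict[tuple[str, int], SubjectIndex] | None = None,
    panel_warn_size: int = 200,
) -> list[HomologyHit]:
    """Search one query against a panel of subjects, with optional shared
    index cache keyed by (subject id, word size)."""
    params = params or SearchParams()
    if len(panel) > panel_warn_size:
        logger.warning(
            "panel of %d subjects exceeds the desk-scale guideline (%d)",
            len(panel),
            panel_warn_size,
        )
    out: list[HomologyHit] = []
    for subject in panel:
        idx = None
        if index_cache is not None:
            key = (subject.id, params.word_size)
            idx = index_cache.get(key)
            if idx is None:
                idx = SubjectIndex(subject, params.word_size)
                index_cache[key] = idx
        out.extend(find_hits(query, subject, params, subject_index=idx))
    return out
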
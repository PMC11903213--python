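"""Seed-and-extend local nucleotide alignment.

This is the alignment engine behind junction-read support, dispersed-repeat
detection and mito-plastid homology search.  The strategy is the classic
one for long noisy reads against short references:

1. exact k-mer anchors between query and reference (both strands),
2. anchors clustered by diagonal,
3. each cluster extended by a banded affine-gap local (Smith-Waterman/Gotoh)
   dynamic program restricted to a window around the cluster.

Scoring follows the blastn-style convention ``match``/``-mismatch`` with a
length-``L`` gap costing ``gap_open + L * gap_extend``.  When the band covers
every diagonal of the window the DP is exact, so on short pairs the best hit
score equals a full dynamic-programming solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ._seq import encode, revcomp

__all__ = ["Scoring", "LocalHit", "local_align"]


@dataclass(frozen=True)
class Scoring:
    """Alignment scores; penalties are positive magnitudes."""

    match: int = 2
    mismatch: int = 3
    gap_open: int = 5
    gap_extend: int = 2


DEFAULT_SCORING = Scoring()


@dataclass
class LocalHit:
    """A local alignment; coordinates are 0-based half-open.

    ``query_start``/``query_end`` are always on the forward query; ``strand``
    records whether the reverse complement of the query was aligned.
    """

    score: int
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    strand: str
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        """Percent identity: matches / alignment columns (incl. gaps) x 100."""
        return round(self.matches / self.columns * 100.0, 3)


@njit(cache=True)
def _banded_dp(ref, qry, dmin, dmax, match, mismatch, gap_oe, gap_e):
    """Banded affine local DP over diagonals j-i in [dmin, dmax].

    Returns (score, ref_start, ref_end, qry_start, qry_end, matches, columns),
    half-open ends; score 0 means no positive-scoring alignment in the band.
    """
    Lr = ref.shape[0]
    Lq = qry.shape[0]
    W = dmax - dmin + 1
    NEG = -(1 << 30)

    Hprev = np.zeros(W, np.int32)
    Fprev = np.full(W, NEG, np.int32)
    ptrH = np.zeros((Lr, W), np.uint8)
    ptrE = np.zeros((Lr, W), np.uint8)
    ptrF = np.zeros((Lr, W), np.uint8)

    best = 0
    bi = -1
    bk = -1
    for i in range(Lr):
        Hcur = np.zeros(W, np.int32)
        Ecur = np.full(W, NEG, np.int32)
        Fcur = np.full(W, NEG, np.int32)
        jlo = i + dmin
        if jlo < 0:
            jlo = 0
        jhi = i + dmax
        if jhi > Lq - 1:
            jhi = Lq - 1
        for j in range(jlo, jhi + 1):
            k = j - i - dmin
            # E: gap in reference, consumes qry[j]; predecessor (i, j-1)
            e = NEG
            if k >= 1 and j >= 1:
                eh = Hcur[k - 1] - gap_oe
                ee = Ecur[k - 1] - gap_e
                if ee > eh:
                    e = ee
                    ptrE[i, k] = 1
                else:
                    e = eh
                    ptrE[i, k] = 0
            Ecur[k] = e
            # F: gap in query, consumes ref[i]; predecessor (i-1, j)
            f = NEG
            if k + 1 < W and i >= 1:
                fh = Hprev[k + 1] - gap_oe
                ff = Fprev[k + 1] - gap_e
                if ff > fh:
                    f = ff
                    ptrF[i, k] = 1
                else:
                    f = fh
                    ptrF[i, k] = 0
            Fcur[k] = f
            # diagonal
            if ref[i] == qry[j] and ref[i] < 4:
                s = match
            else:
                s = -mismatch
            diag = Hprev[k] + s
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if e > h:
                h = e
                p = 2
            if f > h:
                h = f
                p = 3
            Hcur[k] = h
            ptrH[i, k] = p
            if h > best:
                best = h
                bi = i
                bk = k
        Hprev = Hcur
        Fprev = Fcur

    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0

    # traceback
    i = bi
    k = bk
    re = bi + 1
    qe = bi + dmin + bk + 1
    nmatch = 0
    ncol = 0
    state = 0  # 0=H, 1=E, 2=F
    while True:
        if state == 0:
            if i < 0 or i + dmin + k < 0:
                break  # alignment starts at the matrix edge
            p = ptrH[i, k]
            if p == 0:
                break
            if p == 1:
                ncol += 1
                if ref[i] == qry[i + dmin + k] and ref[i] < 4:
                    nmatch += 1
                i -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ncol += 1
            pe = ptrE[i, k]
            k -= 1
            if pe == 0:
                state = 0
        else:
            ncol += 1
            pf = ptrF[i, k]
            i -= 1
            k += 1
            if pf == 0:
                state = 0
    rs = i + 1
    qs = i + dmin + k + 1
    return best, rs, re, qs, qe, nmatch, ncol


def _kmer_index(ref: str, k: int, max_positions: int = 200) -> dict:
    index: dict = {}
    for i in range(len(ref) - k + 1):
        index.setdefault(ref[i : i + k], []).append(i)
    # drop hyper-repetitive words to bound anchor counts
    return {w: p for w, p in index.items() if len(p) <= max_positions}


def _clusters(anchors: list[tuple[int, int]], diag_tol: int, pos_gap: int):
    """Group (diag, rpos) anchors into diagonal clusters."""
    anchors.sort()
    groups: list[list[tuple[int, int]]] = []
    for a in anchors:
        if groups and a[0] - groups[-1][-1][0] <= diag_tol and (
            abs(a[1] - groups[-1][-1][1]) <= pos_gap
        ):
            groups[-1].append(a)
        else:
            groups.append([a])
    return groups


def _extend_cluster(ref_enc, qry_enc, group, k, scoring: Scoring):
    Lr = ref_enc.shape[0]
    Lq = qry_enc.shape[0]
    diags = [d for d, _ in group]
    rposs = [r for _, r in group]
    qmin = min(d + r for d, r in group)
    qmax = max(d + r for d, r in group) + k
    # margins let the DP extend past the anchored region; capped so huge
    # self-comparisons stay banded around the seeded match
    left_margin = min(int(1.3 * qmin) + 16, 2500)
    right_margin = min(int(1.3 * (Lq - qmax)) + 16, 2500)
    r0 = max(0, min(rposs) - left_margin)
    r1 = min(Lr, max(rposs) + k + right_margin)
    pad = max(24, min(160, (r1 - r0) // 8))
    dmin = min(diags) - pad + r0
    dmax = max(diags) + pad + r0
    dmin = max(dmin, -(r1 - r0 - 1))
    dmax = min(dmax, Lq - 1)
    if dmax < dmin:
        return None
    res = _banded_dp(
        ref_enc[r0:r1],
        qry_enc,
        np.int64(dmin),
        np.int64(dmax),
        scoring.match,
        scoring.mismatch,
        scoring.gap_open + scoring.gap_extend,
        scoring.gap_extend,
    )
    score, rs, re, qs, qe, nmatch, ncol = res
    if score <= 0:
        return None
    return int(score), rs + r0, re + r0, qs, qe, int(nmatch), int(ncol)


def local_align(
    query: str,
    ref: str,
    scoring: Scoring = DEFAULT_SCORING,
    k: int = 13,
    min_score: int = 40,
    both_strands: bool = True,
    max_clusters: int = 100,
    suppress_overlaps: bool = True,
) -> list[LocalHit]:
    """Local alignments of ``query`` against ``ref``, best-first.

    Queries shorter than the seed size ``k`` yield an empty list (no error).
    Overlapping hits (>=50% query overlap with a better hit on the same
    strand) are suppressed.
    """
    if scoring.match <= 0 or min(scoring.mismatch, scoring.gap_open, scoring.gap_extend) < 0:
        raise ValueError("scoring: match must be > 0 and penalties >= 0")
    if len(query) < k or len(ref) < k:
        return []
    ref_enc = encode(ref)
    index = _kmer_index(ref, k)
    hits: list[LocalHit] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        q = query if strand == "+" else revcomp(query)
        q_enc = encode(q)
        anchors = []
        for qpos in range(len(q) - k + 1):
            for rpos in index.get(q[qpos : qpos + k], ()):
                anchors.append((qpos - rpos, rpos))
        if not anchors:
            continue
        groups = _clusters(anchors, diag_tol=50, pos_gap=600)
        groups.sort(key=len, reverse=True)
        seen = set()
        for group in groups[:max_clusters]:
            out = _extend_cluster(ref_enc, q_enc, group, k, scoring)
            if out is None:
                continue
            score, rs, re, qs, qe, nmatch, ncol = out
            if score < min_score:
                continue
            if strand == "-":
                qs, qe = len(q) - qe, len(q) - qs
            key = (rs, re, qs, qe, strand)
            if key in seen:
                continue
            seen.add(key)
            hits.append(LocalHit(score, rs, re, qs, qe, strand, nmatch, ncol))
    hits.sort(key=lambda h: (-h.score, h.ref_start, h.query_start, h.strand))
    if not suppress_overlaps:
        return hits
    kept: list[LocalHit] = []
    for h in hits:
        redundant = False
        for g in kept:
            ov = min(h.query_end, g.query_end) - max(h.query_start, g.query_start)
            shorter = min(h.query_end - h.query_start, g.query_end - g.query_start)
            if ov > 0.5 * shorter:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept
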
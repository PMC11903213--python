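"""Mitochondrial plastid DNA (MTPT) detection.

Plastid-to-mitochondrion sequence transfer leaves mitochondrial intervals
homologous to the plastome.  These are found by local alignment of each
mitochondrial chromosome against the plastome (both strands) with a BLASTn-
style identity floor and an ungapped Karlin-Altschul e-value cut-off; hits
sharing a mitochondrial interval are merged into one fragment that may carry
several plastid-side intervals.  A fragment whose plastid hits fall inside
the plastome's inverted repeat (IR) — hence two plastid copies for a single
mitochondrial copy — marks a *transfer hotspot*.  Plastome genes wholly
contained in a fragment's plastid interval are annotated as completely
transferred.

All reported coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.optimize import brentq

from .alignment import DEFAULT_SCORING, Scoring, local_align

__all__ = [
    "IRAnnotation",
    "MTPTFragment",
    "MTPTSummary",
    "detect_inverted_repeat",
    "homology_search",
    "classify_hotspots",
    "annotate_contained_genes",
    "summarize_mtpt",
    "karlin_altschul_evalue",
]


@dataclass
class IRAnnotation:
    """The plastome's large inverted-repeat pair (1-based intervals)."""

    ira: tuple[int, int]
    irb: tuple[int, int]
    length: int
    identity: float


@dataclass
class MTPTFragment:
    label: str
    chromosome: str
    mito_start: int
    mito_end: int
    plastid_intervals: list[tuple[int, int, str]]  # (start, end, strand)
    length: int
    identity: float
    e_value: float
    hotspot: bool = False
    contained_genes: list[str] = field(default_factory=list)
    partial_genes: list[str] = field(default_factory=list)


@dataclass
class MTPTSummary:
    n_fragments: int
    cumulative_bp: int
    percent_of_mitogenome: float
    n_complete_genes: int


def _lambda_ungapped(scoring: Scoring, p_match: float = 0.25) -> float:
    """Karlin-Altschul lambda for the match/mismatch scores under a uniform
    base composition."""

    def f(lam):
        return (
            p_match * np.exp(lam * scoring.match)
            + (1 - p_match) * np.exp(-lam * scoring.mismatch)
            - 1.0
        )

    return brentq(f, 1e-6, 10.0)


def karlin_altschul_evalue(
    score: int, m: int, n: int, scoring: Scoring = DEFAULT_SCORING, K: float = 0.41
) -> float:
    """E = K * m * n * exp(-lambda * S); the thresholding behaviour is what
    matters here, NCBI parity is not claimed."""
    lam = _lambda_ungapped(scoring)
    return float(K * m * n * np.exp(-lam * score))


def detect_inverted_repeat(
    plastome: str, min_len: int = 1000, min_identity: float = 95.0
) -> IRAnnotation | None:
    """Longest interval pair where one copy matches the reverse complement of
    the other at >= ``min_identity`` over >= ``min_len`` bp; None if absent.

    A sequence that is one whole palindrome (each half the reverse
    complement of the other) is split at its centre.
    """
    if len(plastome) < 1000:
        raise ValueError("plastome shorter than 1 kb")
    hits = local_align(
        plastome,
        plastome,
        k=21,
        min_score=min_len,
        suppress_overlaps=False,
    )
    best: IRAnnotation | None = None
    for h in hits:
        if h.strand != "-":
            continue
        if h.identity < min_identity:
            continue
        a = (h.ref_start + 1, h.ref_end)
        b = (h.query_start + 1, h.query_end)
        if min(a[1] - a[0], b[1] - b[0]) + 1 < min_len:
            continue
        if a > b:
            a, b = b, a
        if b[0] <= a[1]:  # overlapping mirror hit: a palindrome, split at centre
            lo, hi = min(a[0], b[0]), max(a[1], b[1])
            mid = (lo + hi) // 2
            a, b = (lo, mid), (mid + 1, hi)
            if min(a[1] - a[0], b[1] - b[0]) + 1 < min_len:
                continue
        length = min(a[1] - a[0] + 1, b[1] - b[0] + 1)
        cand = IRAnnotation(ira=a, irb=b, length=length, identity=h.identity)
        if best is None or cand.length > best.length:
            best = cand
    return best


def homology_search(
    mito_seqs: dict[str, str],
    plastome: str,
    min_identity: float = 80.0,
    max_evalue: float = 1e-5,
    scoring: Scoring = DEFAULT_SCORING,
    k: int = 11,
    min_score: int = 30,
) -> list[MTPTFragment]:
    """Local alignments between each mitochondrial chromosome and the
    plastome above the identity floor and below the e-value cut-off, merged
    by mitochondrial interval and labelled MTPT1..n in mitochondrial
    coordinate order (chromosomes in the order supplied)."""
    if not (0 < min_identity <= 100):
        raise ValueError(f"min_identity must be in (0, 100], got {min_identity}")
    n_db = len(plastome)
    raw: list[tuple[str, int, int, tuple[int, int, str], float, float]] = []
    for chrom, seq in mito_seqs.items():
        hits = local_align(
            seq, plastome, scoring=scoring, k=k, min_score=min_score, suppress_overlaps=False
        )
        for h in hits:
            if h.identity < min_identity:
                continue
            ev = karlin_altschul_evalue(h.score, len(seq), n_db, scoring)
            if ev > max_evalue:
                continue
            raw.append(
                (
                    chrom,
                    h.query_start + 1,
                    h.query_end,
                    (h.ref_start + 1, h.ref_end, h.strand),
                    h.identity,
                    ev,
                )
            )
    # merge hits sharing (>= 80% reciprocal overlap) the same mito interval
    order = {c: i for i, c in enumerate(mito_seqs)}
    raw.sort(key=lambda t: (order[t[0]], t[1], t[2]))
    fragments: list[MTPTFragment] = []
    for chrom, ms, me, pint, ident, ev in raw:
        merged = False
        for f in fragments:
            if f.chromosome != chrom:
                continue
            ov = min(f.mito_end, me) - max(f.mito_start, ms) + 1
            if ov >= 0.8 * min(me - ms + 1, f.mito_end - f.mito_start + 1):
                f.mito_start = min(f.mito_start, ms)
                f.mito_end = max(f.mito_end, me)
                if pint not in f.plastid_intervals:
                    f.plastid_intervals.append(pint)
                f.identity = max(f.identity, ident)
                f.e_value = min(f.e_value, ev)
                f.length = f.mito_end - f.mito_start + 1
                merged = True
                break
        if not merged:
            fragments.append(
                MTPTFragment(
                    label="",
                    chromosome=chrom,
                    mito_start=ms,
                    mito_end=me,
                    plastid_intervals=[pint],
                    length=me - ms + 1,
                    identity=ident,
                    e_value=ev,
                )
            )
    fragments.sort(key=lambda f: (order[f.chromosome], f.mito_start, f.mito_end))
    for i, f in enumerate(fragments, start=1):
        f.label = f"MTPT{i}"
    return fragments


def classify_hotspots(
    fragments: list[MTPTFragment], ir: IRAnnotation | None
) -> list[MTPTFragment]:
    """Flag transfer hotspots: every plastid hit inside the IR (two plastid
    copies) while the mitochondrial interval is single-copy among the
    fragments (no other fragment shares half of it)."""
    def inside(interval, region, slop=10):
        # local alignments may extend a few coincidental bases past the IR
        return region[0] - slop <= interval[0] and interval[1] <= region[1] + slop

    for f in fragments:
        if ir is None:
            f.hotspot = False
            continue
        in_ir = all(
            inside((s, e), ir.ira) or inside((s, e), ir.irb)
            for s, e, _ in f.plastid_intervals
        )
        single_copy = True
        for g in fragments:
            if g is f or g.chromosome != f.chromosome:
                continue
            ov = min(f.mito_end, g.mito_end) - max(f.mito_start, g.mito_start) + 1
            if ov >= 0.5 * (f.mito_end - f.mito_start + 1):
                single_copy = False
                break
        f.hotspot = in_ir and single_copy
    return fragments


def annotate_contained_genes(
    fragments: list[MTPTFragment],
    genes: list[tuple[str, int, int, str]],
    plastome_len: int,
) -> list[MTPTFragment]:
    """A gene is *complete* in a fragment iff its whole plastome interval
    lies within one of the fragment's plastid intervals; genes merely
    overlapping a boundary are recorded as partial."""
    for name, gs, ge, _strand in genes:
        if not (1 <= gs <= ge <= plastome_len):
            raise ValueError(f"gene {name!r} interval [{gs}, {ge}] outside plastome bounds")
    for f in fragments:
        complete: list[str] = []
        partial: list[str] = []
        for name, gs, ge, _strand in genes:
            if any(ps <= gs and ge <= pe for ps, pe, _ in f.plastid_intervals):
                complete.append(name)
            elif any(min(ge, pe) - max(gs, ps) >= 0 for ps, pe, _ in f.plastid_intervals):
                partial.append(name)
        f.contained_genes = sorted(set(complete))
        f.partial_genes = sorted(set(partial) - set(complete))
    return fragments


def summarize_mtpt(fragments: list[MTPTFragment], mitogenome_len: int) -> MTPTSummary:
    """Fragment count, cumulative transferred length (union of mitochondrial
    intervals) and its percentage of the mitogenome (half-up, 2 decimals)."""
    if mitogenome_len <= 0:
        raise ValueError("mitogenome_len must be positive")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in fragments:
        if f.mito_start < 1 or f.mito_end > mitogenome_len or f.mito_start > f.mito_end:
            raise ValueError(
                f"{f.label}: interval [{f.mito_start}, {f.mito_end}] outside the mitogenome"
            )
        by_chrom.setdefault(f.chromosome, []).append((f.mito_start, f.mito_end))
    cumulative = 0
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                cumulative += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        cumulative += cur_e - cur_s + 1
    pct = float(
        Decimal(cumulative * 100) / Decimal(mitogenome_len)
    )
    pct = float(Decimal(str(pct)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    n_complete = len({g for f in fragments for g in f.contained_genes})
    return MTPTSummary(
        n_fragments=len(fragments),
        cumulative_bp=cumulative,
        percent_of_mitogenome=pct,
        n_complete_genes=n_complete,
    )
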
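"""Long-read support for repeat-mediated recombination junctions.

For each repeat the possible flank pairings are turned into junction
references (flank + repeat + flank); long reads are aligned locally to every
reference, and a read supports a pairing when its best alignment *spans* the
repeat — covers the whole repeat and reaches a minimum anchor distance into
both flanks — above an identity floor.  Spanning reads are assigned to the
best-scoring path (exact score ties are ambiguous and excluded), counted per
path, and summed per conformation over the paths its circles realise; the
conformation with the most support is the dominant in-vivo form.

Conventions match the field's read-validation tables: 1-based inclusive
coordinates, percent identity to three decimals, and reverse-strand reads
reported with read_start > read_end.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

from ._seq import revcomp
from .alignment import DEFAULT_SCORING, LocalHit, Scoring, local_align
from .graph_model import AssemblyGraph, Conformation, SignedStep, label_conformations

__all__ = [
    "JunctionRef",
    "ReadAlignment",
    "SupportRecord",
    "SupportParams",
    "SupportTable",
    "ConformationRanking",
    "junction_label",
    "build_junction_refs",
    "align_read_local",
    "is_spanning",
    "tabulate_support",
    "rank_conformations",
    "load_published_support_records",
    "published_support_table",
]


def _step_str(sid: str, orient: str) -> str:
    # plus orientation is unmarked; minus carries a prime, as in ctg1'
    return sid if orient == "+" else sid + "'"


def junction_label(a: SignedStep, r: SignedStep, b: SignedStep) -> str:
    """Canonical label for a flankA-repeat-flankB junction.

    A junction and its reverse-complement traversal are the same physical
    junction; the representative with the repeat in '+' orientation is used
    (lexicographic tie-break when the repeat orientation is '-' both ways).
    """
    triple = (a, r, b)
    rc = (b.flipped(), r.flipped(), a.flipped())
    if r.orient == "-" and rc[1].orient == "+":
        triple = rc
    elif r.orient == rc[1].orient:
        triple = min(
            (triple, rc), key=lambda t: tuple((s.segment_id, s.orient) for s in t)
        )
    x, rep, y = triple
    return f"{_step_str(x.segment_id, x.orient)}-{_step_str(rep.segment_id, rep.orient)}-{_step_str(y.segment_id, y.orient)}"


@dataclass
class JunctionRef:
    """Reference for one flank pairing: flankA + repeat + flankB."""

    path_label: str
    sequence: str
    flank_len: int
    repeat_span: tuple[int, int]  # 1-based inclusive interval of the repeat
    repeat_id: str
    truncated: bool = False  # true when a flank was shorter than flank_len


@dataclass
class ReadAlignment:
    read_id: str
    identity: float  # percent, 3 decimals
    alignment_len: int  # columns incl. gaps
    ref_start: int  # 1-based inclusive
    ref_end: int
    read_start: int  # 1-based; start > end on the reverse strand
    read_end: int
    score: int = 0


@dataclass
class SupportRecord:
    path_label: str
    read_id: str
    alignment: ReadAlignment
    spanning: bool


@dataclass(frozen=True)
class SupportParams:
    flank_len: int = 2000
    min_anchor: int = 200
    min_identity: float = 80.0
    scoring: Scoring = DEFAULT_SCORING


@dataclass
class SupportTable:
    records: list[SupportRecord]
    params: SupportParams
    #: read_id -> assigned path label for unambiguously spanning reads
    assignments: dict[str, str] = field(default_factory=dict)
    ambiguous: set[str] = field(default_factory=set)

    def path_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for path in self.assignments.values():
            counts[path] = counts.get(path, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "path": r.path_label,
                "read_id": r.read_id,
                "identity_pct": r.alignment.identity,
                "alignment_bp": r.alignment.alignment_len,
                "ref_start": r.alignment.ref_start,
                "ref_end": r.alignment.ref_end,
                "read_start": r.alignment.read_start,
                "read_end": r.alignment.read_end,
                "spanning": r.spanning,
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "path",
                "read_id",
                "identity_pct",
                "alignment_bp",
                "ref_start",
                "ref_end",
                "read_start",
                "read_end",
                "spanning",
            ],
        )


@dataclass
class ConformationRanking:
    labels: list[str]
    conformation_counts: dict[str, int]
    path_counts: dict[str, int]
    dominant: str
    unsupported: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "conformation": self.labels,
                "supporting_reads": [self.conformation_counts[l] for l in self.labels],
                "dominant": [l == self.dominant for l in self.labels],
            }
        )


# ------------------------------------------------------------- references

def build_junction_refs(
    graph: AssemblyGraph, repeat_id: str, flank_len: int
) -> list[JunctionRef]:
    """One reference per admissible ordered (incoming flank, outgoing flank)
    pair of ``repeat_id``; flanks are the terminal ``flank_len`` bases of the
    adjacent contig on the joined side (truncated and flagged when shorter).

    References equivalent under reverse complement are emitted once.
    """
    if repeat_id not in graph.segments:
        raise KeyError(f"unknown repeat segment {repeat_id!r}")
    if flank_len < 0:
        raise ValueError("flank_len must be >= 0")
    succ = graph.out_transitions()

    def oriented(seq: str, orient: str) -> str:
        return seq if orient == "+" else revcomp(seq)

    refs: list[JunctionRef] = []
    seen: set[tuple] = set()
    for rep_orient in "+-":
        rep = SignedStep(repeat_id, rep_orient)
        incoming = [u for u, outs in succ.items() for t, _ in outs if t == rep]
        outgoing = [t for t, _ in succ.get(rep, ())]
        for a in incoming:
            for b in outgoing:
                key = (a, rep, b)
                rc_key = (b.flipped(), rep.flipped(), a.flipped())
                if key in seen or rc_key in seen:
                    continue
                seen.add(key)
                a_seq = oriented(graph.segments[a.segment_id].sequence, a.orient)
                b_seq = oriented(graph.segments[b.segment_id].sequence, b.orient)
                rep_seq = oriented(graph.segments[repeat_id].sequence, rep_orient)
                left = a_seq[-flank_len:] if flank_len else ""
                right = b_seq[:flank_len] if flank_len else ""
                truncated = len(left) < flank_len or len(right) < flank_len
                seq = left + rep_seq + right
                span = (len(left) + 1, len(left) + len(rep_seq))
                refs.append(
                    JunctionRef(
                        path_label=junction_label(a, rep, b),
                        sequence=seq,
                        flank_len=flank_len,
                        repeat_span=span,
                        repeat_id=repeat_id,
                        truncated=truncated,
                    )
                )
    refs.sort(key=lambda r: r.path_label)
    if not refs:
        import warnings

        warnings.warn(f"repeat {repeat_id!r} has no links; no junction references built")
    return refs


# -------------------------------------------------------------- alignment

def _hit_to_alignment(read_id: str, read_len: int, hit: LocalHit) -> ReadAlignment:
    if hit.strand == "+":
        rs, re = hit.query_start + 1, hit.query_end
    else:
        rs, re = hit.query_end, hit.query_start + 1  # start > end marks reverse strand
    return ReadAlignment(
        read_id=read_id,
        identity=hit.identity,
        alignment_len=hit.columns,
        ref_start=hit.ref_start + 1,
        ref_end=hit.ref_end,
        read_start=rs,
        read_end=re,
        score=hit.score,
    )


def align_read_local(
    read: str,
    ref: JunctionRef,
    scoring: Scoring = DEFAULT_SCORING,
    read_id: str = "read",
    k: int = 13,
    min_score: int = 40,
) -> list[ReadAlignment]:
    """Local alignments of a read against a junction reference, best-first."""
    hits = local_align(read, ref.sequence, scoring=scoring, k=k, min_score=min_score)
    return [_hit_to_alignment(read_id, len(read), h) for h in hits]


def is_spanning(
    aln: ReadAlignment, ref: JunctionRef, min_anchor: int, min_identity: float
) -> bool:
    """True iff the alignment covers the repeat plus ``min_anchor`` bp of both
    flanks (clipped to the reference) at or above the identity floor."""
    if min_anchor > ref.flank_len:
        raise ValueError(
            f"min_anchor ({min_anchor}) exceeds flank length ({ref.flank_len})"
        )
    if aln.identity < min_identity:
        return False
    lo = max(1, ref.repeat_span[0] - min_anchor)
    hi = min(len(ref.sequence), ref.repeat_span[1] + min_anchor)
    return aln.ref_start <= lo and aln.ref_end >= hi


def tabulate_support(
    reads,
    refs: list[JunctionRef],
    params: SupportParams = SupportParams(),
) -> SupportTable:
    """Best alignment per (read, path), spanning flags, and unambiguous
    read-to-path assignment.

    ``reads`` is an iterable of (read_id, sequence) pairs or Biopython
    SeqRecords.  A read is assigned to the path with its highest-scoring
    spanning alignment; exact score ties leave the read ambiguous and out of
    all counts.
    """
    if not refs:
        raise ValueError("at least one junction reference is required")
    records: list[SupportRecord] = []
    assignments: dict[str, str] = {}
    ambiguous: set[str] = set()
    for read in reads:
        if hasattr(read, "seq"):
            read_id, seq = read.id, str(read.seq)
        else:
            read_id, seq = read
        best_by_path: dict[str, tuple[ReadAlignment, JunctionRef]] = {}
        for ref in refs:
            alns = align_read_local(seq, ref, scoring=params.scoring, read_id=read_id)
            if alns:
                best_by_path[ref.path_label] = (alns[0], ref)
        spanning_paths: list[tuple[int, str]] = []
        for path, (aln, ref) in sorted(best_by_path.items()):
            sp = is_spanning(aln, ref, params.min_anchor, params.min_identity)
            records.append(SupportRecord(path, read_id, aln, sp))
            if sp:
                spanning_paths.append((aln.score, path))
        if spanning_paths:
            spanning_paths.sort(reverse=True)
            top = spanning_paths[0][0]
            tied = [p for s, p in spanning_paths if s == top]
            if len(tied) == 1:
                assignments[read_id] = tied[0]
            else:
                ambiguous.add(read_id)
    return SupportTable(records, params, assignments, ambiguous)


# ---------------------------------------------------------------- ranking

def conformation_junctions(conf: Conformation) -> set[str]:
    """Canonical labels of the repeat junctions realised by a conformation's
    circles (a step is a junction centre when the segment is used more than
    once genome-wide, i.e. is a repeat)."""
    usage = conf.segment_usage()
    labels: set[str] = set()
    for circle in conf.circles:
        steps = circle.steps
        n = len(steps)
        if n == 1:
            continue
        for i, s in enumerate(steps):
            if usage.get(s.segment_id, 0) >= 2:
                a = steps[(i - 1) % n]
                b = steps[(i + 1) % n]
                labels.add(junction_label(a, s, b))
    return labels


def rank_conformations(
    confs: list[Conformation], table: SupportTable
) -> ConformationRanking:
    """Per-conformation supporting-read counts and the dominant conformation.

    A conformation's support is the number of spanning, unambiguous reads
    whose assigned path is one of its junctions; ties break toward more
    circles, then canonical key (so an unsupported table still reports the
    most-fragmented conformation as dominant, flagged unsupported).
    """
    labels = label_conformations(confs)
    junctions = {lab: conformation_junctions(conf) for lab, conf in labels.items()}
    all_junctions = set().union(*junctions.values()) if junctions else set()
    path_counts = table.path_counts()
    unmappable = sorted(set(path_counts) - all_junctions)
    if unmappable:
        raise ValueError(
            f"path labels not realised by any conformation: {', '.join(unmappable)}"
        )
    conf_counts = {
        lab: sum(n for path, n in path_counts.items() if path in junctions[lab])
        for lab in labels
    }
    ordered = list(labels)  # already sorted: circles desc, canonical key
    dominant = max(ordered, key=lambda l: (conf_counts[l], -ordered.index(l)))
    return ConformationRanking(
        labels=ordered,
        conformation_counts=conf_counts,
        path_counts=path_counts,
        dominant=dominant,
        unsupported=all(v == 0 for v in conf_counts.values()),
    )


# -------------------------------------------- published read-support data

def load_published_support_records() -> pd.DataFrame:
    """The 17 junction-spanning Nanopore read records published for the
    *Iris domestica* mitogenome (assembled chromosomes PQ468093-PQ468095),
    as transcribed coordinates on the R1/R2 junction references."""
    with importlib.resources.files("chondriome.data").joinpath(
        "junction_read_support.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def published_support_table(
    refs: list[JunctionRef], params: SupportParams = SupportParams()
) -> SupportTable:
    """Reconstruct a :class:`SupportTable` from the published records, with
    spanning flags recomputed from the transcribed coordinates against the
    supplied junction references."""
    df = load_published_support_records()
    by_label = {r.path_label: r for r in refs}
    records: list[SupportRecord] = []
    assignments: dict[str, str] = {}
    for row in df.itertuples(index=False):
        ref = by_label.get(row.path)
        if ref is None:
            raise ValueError(f"no junction reference for path {row.path!r}")
        aln = ReadAlignment(
            read_id=row.read_id,
            identity=float(row.identity_pct),
            alignment_len=int(row.alignment_bp),
            ref_start=int(row.ref_start),
            ref_end=int(row.ref_end),
            read_start=int(row.read_start),
            read_end=int(row.read_end),
        )
        sp = is_spanning(aln, ref, params.min_anchor, params.min_identity)
        records.append(SupportRecord(row.path, row.read_id, aln, sp))
        if sp:
            assignments[row.read_id] = row.path
    return SupportTable(records, params, assignments, set())
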
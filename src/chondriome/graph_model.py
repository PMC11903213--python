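"""Assembly-graph representation and circular-chromosome conformation enumeration.

Plant mitochondrial genomes assembled from reads frequently collapse into a
small graph: a few unique contigs joined through repeats present in more than
one copy.  Each way of threading the repeats — pairing every entry into a
repeat copy with an exit — decomposes the graph into a set of circular
chromosomes, a *conformation*.  Repeat-mediated homologous recombination
interconverts these conformations in vivo, so several can coexist;
enumerating them is the first step of the analysis.

A conformation must traverse every segment exactly its copy number
(multiplicity) using declared links only, which makes the enumeration an
Eulerian-style decomposition of a small multigraph.  Circles are reported in
a canonical form (minimal over rotation and strand flip), conformations are
deduplicated, and the invariant that every conformation of a graph has the
same total length holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from ._seq import gc_percent, validate_alphabet

__all__ = [
    "Segment",
    "Link",
    "AssemblyGraph",
    "SignedStep",
    "CircularPath",
    "Conformation",
    "GFAParseError",
    "GraphValidationError",
    "NonCircularizableError",
    "read_gfa",
    "write_gfa",
    "assign_multiplicities",
    "canonicalize_path",
    "enumerate_conformations",
    "label_conformations",
    "conformation_summary",
]


class GFAParseError(ValueError):
    pass


class GraphValidationError(ValueError):
    pass


class NonCircularizableError(ValueError):
    def __init__(self, segments):
        self.segments = list(segments)
        super().__init__(
            "graph is non-circularizable; segments that cannot be placed on a "
            f"circuit: {', '.join(self.segments)}"
        )


def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


@dataclass
class Segment:
    """A graph node: one assembled sequence with a per-genome copy number."""

    id: str
    sequence: str
    multiplicity: int = 1
    depth: float | None = None

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise GraphValidationError(f"segment {self.id}: empty sequence")
        if self.multiplicity < 1:
            raise GraphValidationError(f"segment {self.id}: multiplicity < 1")
        validate_alphabet(self.sequence, f"segment {self.id}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Link:
    """An oriented join: leaving ``from_id``(``from_orient``) enters
    ``to_id``(``to_orient``), overlapping by ``overlap`` bp."""

    from_id: str
    from_orient: str
    to_id: str
    to_orient: str
    overlap: int = 0

    def reverse(self) -> "Link":
        return Link(
            self.to_id, _flip(self.to_orient), self.from_id, _flip(self.from_orient), self.overlap
        )


@dataclass(frozen=True)
class SignedStep:
    segment_id: str
    orient: str

    def flipped(self) -> "SignedStep":
        return SignedStep(self.segment_id, _flip(self.orient))


@dataclass
class AssemblyGraph:
    segments: dict[str, Segment] = field(default_factory=dict)
    links: set[Link] = field(default_factory=set)

    def add_segment(self, seg: Segment) -> None:
        self.segments[seg.id] = seg

    def add_link(self, link: Link) -> None:
        """Add a link; the set is kept closed under reverse-complement symmetry."""
        self.links.add(link)
        self.links.add(link.reverse())

    def validate(self) -> None:
        if not self.segments:
            raise GraphValidationError("graph has no segments")
        for l in self.links:
            for sid in (l.from_id, l.to_id):
                if sid not in self.segments:
                    raise GraphValidationError(f"link references unknown segment {sid!r}")
            if l.reverse() not in self.links:
                raise GraphValidationError(f"link set not closed under reverse complement: {l}")

    def out_transitions(self) -> dict[SignedStep, list[tuple[SignedStep, int]]]:
        """Adjacency of oriented segments: successor steps with link overlaps."""
        out: dict[SignedStep, list[tuple[SignedStep, int]]] = {}
        for l in self.links:
            out.setdefault(SignedStep(l.from_id, l.from_orient), []).append(
                (SignedStep(l.to_id, l.to_orient), l.overlap)
            )
        for v in out.values():
            v.sort(key=lambda t: (t[0].segment_id, t[0].orient, t[1]))
        return out

    def link_overlap(self, a: SignedStep, b: SignedStep) -> int:
        for l in self.links:
            if (l.from_id, l.from_orient, l.to_id, l.to_orient) == (
                a.segment_id,
                a.orient,
                b.segment_id,
                b.orient,
            ):
                return l.overlap
        raise GraphValidationError(f"no link {a} -> {b}")


# ---------------------------------------------------------------- GFA I/O

def _parse_overlap(cigar: str, lineno: int) -> int:
    if cigar == "*":
        return 0
    total = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        elif ch in "MIDNSHP=X":
            if not num:
                raise GFAParseError(f"line {lineno}: bad CIGAR {cigar!r}")
            if ch in "M=X":
                total += int(num)
            num = ""
        else:
            raise GFAParseError(f"line {lineno}: bad CIGAR {cigar!r}")
    if num:
        raise GFAParseError(f"line {lineno}: bad CIGAR {cigar!r}")
    return total


def read_gfa(path, fasta: dict[str, str] | None = None) -> AssemblyGraph:
    """Read a GFA1 file (S and L lines; dp:i / ml:i tags honoured).

    ``fasta`` supplies sequences for S lines whose sequence field is ``*``.
    """
    graph = AssemblyGraph()
    pending_links = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "H":
                continue
            if kind == "S":
                if len(fields) < 3:
                    raise GFAParseError(f"line {lineno}: S line needs name and sequence")
                name, seq = fields[1], fields[2]
                if seq == "*":
                    if not fasta or name not in fasta:
                        raise GFAParseError(
                            f"line {lineno}: segment {name!r} has no sequence and no "
                            "companion FASTA entry"
                        )
                    seq = fasta[name]
                mult = 1
                depth = None
                for tag in fields[3:]:
                    if tag.startswith("ml:i:"):
                        mult = int(tag[5:])
                    elif tag.startswith("dp:i:"):
                        depth = float(tag[5:])
                    elif tag.startswith("dp:f:"):
                        depth = float(tag[5:])
                try:
                    graph.add_segment(Segment(name, seq, multiplicity=mult, depth=depth))
                except GraphValidationError as exc:
                    raise GFAParseError(f"line {lineno}: {exc}") from exc
            elif kind == "L":
                if len(fields) < 6:
                    raise GFAParseError(f"line {lineno}: L line needs 5 fields")
                a, oa, b, ob, cig = fields[1:6]
                if oa not in "+-" or ob not in "+-":
                    raise GFAParseError(f"line {lineno}: bad orientation")
                pending_links.append((Link(a, oa, b, ob, _parse_overlap(cig, lineno)), lineno))
            # other record types ignored
    for link, lineno in pending_links:
        for sid in (link.from_id, link.to_id):
            if sid not in graph.segments:
                raise GraphValidationError(
                    f"line {lineno}: link references unknown segment {sid!r}"
                )
        graph.add_link(link)
    graph.validate()
    return graph


def write_gfa(graph: AssemblyGraph, path) -> None:
    """Write GFA1; multiplicity and depth stored as ml:i / dp:f tags.

    Each link pair (a link and its reverse complement) is written once.
    """
    graph.validate()
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for sid in sorted(graph.segments):
            seg = graph.segments[sid]
            tags = [f"LN:i:{seg.length}", f"ml:i:{seg.multiplicity}"]
            if seg.depth is not None:
                tags.append(f"dp:f:{seg.depth:g}")
            fh.write("\t".join(["S", sid, seg.sequence, *tags]) + "\n")
        written = set()
        for l in sorted(
            graph.links, key=lambda x: (x.from_id, x.from_orient, x.to_id, x.to_orient)
        ):
            if l in written or l.reverse() in written:
                continue
            written.add(l)
            fh.write(f"L\t{l.from_id}\t{l.from_orient}\t{l.to_id}\t{l.to_orient}\t{l.overlap}M\n")


# ----------------------------------------------- multiplicity assignment

def assign_multiplicities(
    graph: AssemblyGraph,
    overrides: dict[str, int] | None = None,
    coverage: dict[str, float] | None = None,
    unit_depth: float | None = None,
) -> AssemblyGraph:
    """Return a copy of the graph with per-segment copy numbers set.

    Priority: explicit override, else round(depth / unit depth) when coverage
    is supplied (unit depth defaults to the median of the coverage values),
    else 1.  Results are floored at 1.
    """
    overrides = overrides or {}
    for sid, m in overrides.items():
        if sid not in graph.segments:
            raise GraphValidationError(f"override references unknown segment {sid!r}")
        if m < 1:
            raise ValueError(f"override for {sid!r} must be a positive integer, got {m}")
    if coverage and unit_depth is None:
        vals = sorted(coverage.values())
        mid = len(vals) // 2
        unit_depth = vals[mid] if len(vals) % 2 else 0.5 * (vals[mid - 1] + vals[mid])
    new = AssemblyGraph()
    for sid, seg in graph.segments.items():
        if sid in overrides:
            mult = overrides[sid]
        elif coverage and sid in coverage and unit_depth:
            mult = max(1, round(coverage[sid] / unit_depth))
        else:
            mult = 1
        new.add_segment(replace(seg, multiplicity=mult))
    for l in graph.links:
        new.links.add(l)
    return new


# -------------------------------------------------------- conformations

def _canonical_steps(steps: tuple[SignedStep, ...]) -> tuple[SignedStep, ...]:
    n = len(steps)
    candidates = []
    rc = tuple(s.flipped() for s in reversed(steps))
    for seq in (steps, rc):
        for r in range(n):
            candidates.append(seq[r:] + seq[:r])
    return min(candidates, key=lambda c: tuple((s.segment_id, s.orient) for s in c))


@dataclass(frozen=True)
class CircularPath:
    """A circular signed-segment path in canonical form."""

    steps: tuple[SignedStep, ...]
    length: int = 0

    def key(self) -> tuple:
        return tuple((s.segment_id, s.orient) for s in self.steps)

    def __str__(self) -> str:
        return ",".join(f"{s.segment_id}{s.orient}" for s in self.steps)


def canonicalize_path(path: CircularPath) -> CircularPath:
    """Lexicographically minimal representative over rotations and the
    reverse-complement traversal; idempotent."""
    if not path.steps:
        raise ValueError("empty circular path")
    return CircularPath(_canonical_steps(path.steps), path.length)


@dataclass(frozen=True)
class Conformation:
    """One decomposition of the graph into circular chromosomes."""

    circles: tuple[CircularPath, ...]

    @property
    def n_circles(self) -> int:
        return len(self.circles)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.circles)

    def key(self) -> tuple:
        return tuple(c.key() for c in self.circles)

    def segment_usage(self) -> dict[str, int]:
        usage: dict[str, int] = {}
        for c in self.circles:
            for s in c.steps:
                usage[s.segment_id] = usage.get(s.segment_id, 0) + 1
        return usage

    def __str__(self) -> str:
        return " | ".join(str(c) for c in self.circles)


def _circle_length(graph: AssemblyGraph, steps: tuple[SignedStep, ...]) -> int:
    total = sum(graph.segments[s.segment_id].length for s in steps)
    n = len(steps)
    for i in range(n):
        total -= graph.link_overlap(steps[i], steps[(i + 1) % n])
    return total


def enumerate_conformations(graph: AssemblyGraph) -> list[Conformation]:
    """Every distinct decomposition of the graph into circular paths in which
    each segment is traversed exactly its multiplicity, links traversed in
    declared orientations only.

    Conformations are deduplicated after canonicalisation and sorted by
    (descending circle count, canonical key).  Raises
    :class:`NonCircularizableError` when some segment cannot sit on any
    circuit.
    """
    graph.validate()
    out = graph.out_transitions()
    succ = {k: [t for t, _ in v] for k, v in out.items()}

    stuck = []
    for sid in graph.segments:
        has_out = any(SignedStep(sid, o) in succ for o in "+-")
        has_in = any(
            any(t.segment_id == sid for t in v) for v in succ.values()
        )
        if not (has_out and has_in):
            stuck.append(sid)
    if stuck:
        raise NonCircularizableError(sorted(stuck))

    order = sorted(graph.segments)
    remaining = {sid: graph.segments[sid].multiplicity for sid in order}
    results: dict[tuple, Conformation] = {}

    def record(circles: list[tuple[SignedStep, ...]]) -> None:
        canon = sorted(
            (CircularPath(_canonical_steps(c), _circle_length(graph, c)) for c in circles),
            key=lambda c: c.key(),
        )
        conf = Conformation(tuple(canon))
        results.setdefault(conf.key(), conf)

    def search(circles: list[tuple[SignedStep, ...]]) -> None:
        start_seg = next((sid for sid in order if remaining[sid] > 0), None)
        if start_seg is None:
            record(circles)
            return
        start = SignedStep(start_seg, "+")
        remaining[start_seg] -= 1
        path = [start]

        def extend(cur: SignedStep) -> None:
            for nxt in succ.get(cur, ()):
                if nxt == start:
                    circles.append(tuple(path))
                    search(circles)
                    circles.pop()
                if remaining[nxt.segment_id] > 0:
                    remaining[nxt.segment_id] -= 1
                    path.append(nxt)
                    extend(nxt)
                    path.pop()
                    remaining[nxt.segment_id] += 1

        extend(start)
        remaining[start_seg] += 1

    search([])
    if not results:
        raise NonCircularizableError(order)
    confs = sorted(results.values(), key=lambda c: (-c.n_circles, c.key()))
    totals = {c.total_length for c in confs}
    assert len(totals) == 1, "total length must be conserved across conformations"
    return confs


def label_conformations(confs: list[Conformation]) -> dict[str, Conformation]:
    """Stable human-readable labels: '3-circle', '2-circle-a', '2-circle-b', ...

    Input order (the enumeration's sort) is preserved; suffix letters are
    used only when several conformations share a circle count.
    """
    by_n: dict[int, list[Conformation]] = {}
    for c in confs:
        by_n.setdefault(c.n_circles, []).append(c)
    labels: dict[str, Conformation] = {}
    for c in confs:
        group = by_n[c.n_circles]
        if len(group) == 1:
            labels[f"{c.n_circles}-circle"] = c
        else:
            suffix = chr(ord("a") + group.index(c))
            labels[f"{c.n_circles}-circle-{suffix}"] = c
    return labels


def conformation_summary(conf: Conformation, graph: AssemblyGraph) -> pd.DataFrame:
    """Per-circle length and GC table (descending length), mirroring the
    chromosome-level summary a genome announcement would print."""
    rows = []
    for circle in conf.circles:
        seq_parts = []
        for s in circle.steps:
            seg = graph.segments.get(s.segment_id)
            if seg is None or not seg.sequence:
                raise GraphValidationError(f"missing sequence for segment {s.segment_id!r}")
            from ._seq import revcomp

            seq_parts.append(seg.sequence if s.orient == "+" else revcomp(seg.sequence))
        circle_seq = "".join(seq_parts)
        rows.append(
            {
                "length_bp": circle.length,
                "gc_percent": gc_percent(circle_seq),
                "path": str(circle),
            }
        )
    rows.sort(key=lambda r: -r["length_bp"])
    for i, r in enumerate(rows, start=1):
        r["chromosome"] = f"chromosome_{i}"
        r["type"] = "circular"
    df = pd.DataFrame(rows, columns=["chromosome", "type", "length_bp", "gc_percent", "path"])
    return df
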
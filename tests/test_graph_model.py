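"""Assembly-graph model: GFA I/O, multiplicities, conformation enumeration."""

import itertools

import numpy as np
import pytest

from chondriome._seq import random_dna
from chondriome.graph_model import (
    AssemblyGraph,
    CircularPath,
    GFAParseError,
    GraphValidationError,
    Link,
    NonCircularizableError,
    Segment,
    SignedStep,
    assign_multiplicities,
    canonicalize_path,
    conformation_summary,
    enumerate_conformations,
    label_conformations,
    read_gfa,
    write_gfa,
)

from conftest import make_graph


# ------------------------------------------------------------------ GFA I/O

def test_read_minimal_gfa(tmp_path):
    p = tmp_path / "g.gfa"
    p.write_text("S\tctg1\tACGTACGTAC\nS\tctg2\tGGGGCCCCAA\nL\tctg1\t+\tctg2\t+\t0M\n")
    g = read_gfa(p)
    assert set(g.segments) == {"ctg1", "ctg2"}
    # one declared link (stored with its reverse-complement mate)
    assert Link("ctg1", "+", "ctg2", "+", 0) in g.links
    assert Link("ctg2", "-", "ctg1", "-", 0) in g.links


def test_read_gfa_sequences_from_companion_fasta(tmp_path):
    p = tmp_path / "g.gfa"
    p.write_text("S\tctg1\t*\n")
    g = read_gfa(p, fasta={"ctg1": "ACGT"})
    assert g.segments["ctg1"].sequence == "ACGT"
    with pytest.raises(GFAParseError, match="ctg1"):
        read_gfa(p)


def test_read_gfa_paper_topology_adjacency(iris_graph_small, tmp_path):
    graph, _ = iris_graph_small
    p = tmp_path / "iris.gfa"
    write_gfa(graph, p)
    g = read_gfa(p)

    def neighbours(rid):
        return {
            l.to_id for l in g.links if l.from_id == rid
        } | {l.from_id for l in g.links if l.to_id == rid}

    assert neighbours("R1") == {"ctg1", "ctg2", "ctg3"}
    assert neighbours("R2") == {"ctg1", "ctg2", "ctg4"}


def test_read_gfa_link_to_unknown_segment_errors(tmp_path):
    p = tmp_path / "g.gfa"
    p.write_text("S\tctg1\tACGTACGT\nL\tctg1\t+\tmissing\t+\t0M\n")
    with pytest.raises(GraphValidationError, match="missing"):
        read_gfa(p)


def test_read_gfa_malformed_line_names_line_number(tmp_path):
    p = tmp_path / "g.gfa"
    p.write_text("S\tctg1\tACGT\nL\tctg1\t+\tctg1\t+\tnotacigar\n")
    with pytest.raises(GFAParseError, match="line 2"):
        read_gfa(p)


@pytest.mark.parametrize("n_segments", [2, 6, 12, 20])
def test_gfa_round_trip_random_graphs(tmp_path, n_segments):
    rng = np.random.default_rng(n_segments)
    g = AssemblyGraph()
    ids = [f"s{i}" for i in range(n_segments)]
    for sid in ids:
        g.add_segment(
            Segment(
                sid,
                random_dna(rng, int(rng.integers(10, 200))),
                multiplicity=int(rng.integers(1, 4)),
                depth=float(rng.integers(10, 100)),
            )
        )
    for _ in range(n_segments * 2):
        a, b = rng.choice(ids, 2)
        g.add_link(Link(a, rng.choice(["+", "-"]), b, rng.choice(["+", "-"]), 0))
    p = tmp_path / "g.gfa"
    write_gfa(g, p)
    g2 = read_gfa(p)
    assert {sid: (s.sequence, s.multiplicity, s.depth) for sid, s in g.segments.items()} == {
        sid: (s.sequence, s.multiplicity, s.depth) for sid, s in g2.segments.items()
    }
    assert g.links == g2.links


# ---------------------------------------------------------- multiplicities

def test_assign_multiplicities_rules(iris_graph_small):
    graph, _ = iris_graph_small
    flat = assign_multiplicities(graph)  # no info -> all 1
    assert all(s.multiplicity == 1 for s in flat.segments.values())
    g = assign_multiplicities(flat, overrides={"R1": 2, "R2": 2})
    assert g.segments["R1"].multiplicity == 2
    assert g.segments["ctg1"].multiplicity == 1
    # coverage-based rounding against an explicit unit depth
    g = assign_multiplicities(flat, coverage={"ctg1": 50, "R1": 98}, unit_depth=50)
    assert g.segments["R1"].multiplicity == 2
    assert g.segments["ctg1"].multiplicity == 1


def test_assign_multiplicities_rejects_nonpositive_override(iris_graph_small):
    graph, _ = iris_graph_small
    with pytest.raises(ValueError, match="positive"):
        assign_multiplicities(graph, overrides={"R1": 0})
    with pytest.raises(GraphValidationError, match="unknown"):
        assign_multiplicities(graph, overrides={"nope": 2})


# -------------------------------------------------------- canonicalisation

def test_canonical_form_invariant_to_rotation_and_strand():
    steps = tuple(
        SignedStep(s, o) for s, o in [("ctg1", "+"), ("R1", "+"), ("ctg2", "+"), ("R2", "+")]
    )
    base = canonicalize_path(CircularPath(steps))
    for r in range(len(steps)):
        rotated = steps[r:] + steps[:r]
        assert canonicalize_path(CircularPath(rotated)).key() == base.key()
    rc = tuple(s.flipped() for s in reversed(steps))
    assert canonicalize_path(CircularPath(rc)).key() == base.key()
    assert canonicalize_path(base).key() == base.key()  # idempotent


def test_canonicalize_rejects_empty_path():
    with pytest.raises(ValueError):
        canonicalize_path(CircularPath(()))


# ------------------------------------------------------------- enumeration

def test_two_repeat_topology_yields_four_conformations(iris_graph_small):
    graph, _ = iris_graph_small
    confs = enumerate_conformations(graph)
    assert [c.n_circles for c in confs] == [3, 2, 2, 1]
    labels = label_conformations(confs)
    assert list(labels) == ["3-circle", "2-circle-a", "2-circle-b", "1-circle"]


def test_single_self_loop_has_one_conformation():
    g = make_graph({"c": 30}, set(), [("c", "c")], seed=2)
    confs = enumerate_conformations(g)
    assert len(confs) == 1 and confs[0].n_circles == 1


def test_two_disjoint_self_loops_force_two_circles():
    g = make_graph({"a": 30, "b": 40}, set(), [("a", "a"), ("b", "b")], seed=3)
    confs = enumerate_conformations(g)
    assert len(confs) == 1 and confs[0].n_circles == 2


def test_unplaceable_segment_raises_non_circularizable():
    g = make_graph({"a": 30, "b": 40}, set(), [("a", "a")], seed=4)
    with pytest.raises(NonCircularizableError, match="b"):
        enumerate_conformations(g)


def test_conservation_across_conformations(iris_graph_small):
    graph, _ = iris_graph_small
    confs = enumerate_conformations(graph)
    totals = {c.total_length for c in confs}
    assert len(totals) == 1
    usages = {tuple(sorted(c.segment_usage().items())) for c in confs}
    assert len(usages) == 1
    (usage,) = usages
    assert dict(usage) == {sid: s.multiplicity for sid, s in graph.segments.items()}


# --------------------------------------------- brute-force pairing oracle

def _canon(steps):
    n = len(steps)
    rc = tuple((s, "-" if o == "+" else "+") for s, o in reversed(steps))
    return min(seq[r:] + seq[:r] for seq in (tuple(steps), rc) for r in range(n))


def _oracle_conformations(graph):
    """Independent route: enumerate every simple circuit with usage within
    multiplicity, then exhaustively combine circuits into exact covers."""
    succ = {}
    for l in graph.links:
        succ.setdefault((l.from_id, l.from_orient), []).append((l.to_id, l.to_orient))
    mult = {sid: s.multiplicity for sid, s in graph.segments.items()}

    circles = set()

    def dfs(path, usage):
        cur = path[-1]
        for nxt in succ.get(cur, ()):
            if nxt == path[0]:
                circles.add(_canon(path))
            if usage.get(nxt[0], 0) < mult[nxt[0]]:
                usage[nxt[0]] = usage.get(nxt[0], 0) + 1
                path.append(nxt)
                dfs(path, usage)
                path.pop()
                usage[nxt[0]] -= 1

    for sid in mult:
        start = (sid, "+")
        dfs([start], {sid: 1})

    circle_list = sorted(circles)
    usage_of = []
    for c in circle_list:
        u = {}
        for s, _ in c:
            u[s] = u.get(s, 0) + 1
        usage_of.append(u)

    results = set()

    def combine(idx, remaining, chosen):
        if all(v == 0 for v in remaining.values()):
            results.add(tuple(sorted(chosen)))
            return
        if idx == len(circle_list):
            return
        u = usage_of[idx]
        max_t = min(remaining[s] // n for s, n in u.items())
        for t in range(max_t + 1):
            combine(
                idx + 1,
                {s: remaining[s] - t * u.get(s, 0) for s in remaining},
                chosen + [circle_list[idx]] * t,
            )

    combine(0, dict(mult), [])
    return results


@pytest.mark.parametrize(
    "case",
    [
        # the two-repeat four-contig topology
        dict(lengths={**{f"c{i}": 20 for i in range(1, 5)}, "R1": 12, "R2": 12},
             repeats={"R1", "R2"},
             topology=[("c1", "R1"), ("R1", "c2"), ("R1", "c3"), ("c3", "R1"),
                       ("c2", "R2"), ("R2", "c1"), ("c4", "R2"), ("R2", "c4")]),
        # one repeat at multiplicity 3 threading three unique contigs
        dict(lengths={"a": 20, "b": 20, "c": 20, "R": 10},
             repeats=set(),
             topology=[("a", "R"), ("R", "a"), ("b", "R"), ("R", "b"), ("c", "R"), ("R", "c")],
             mult_overrides={"R": 3}),
        # two single-copy joiners offering alternative routings
        dict(lengths={"a": 20, "b": 20, "P": 10, "Q": 10},
             repeats=set(),
             topology=[("a", "P"), ("P", "b"), ("b", "Q"), ("Q", "a"),
                       ("a", "Q"), ("Q", "b"), ("b", "P"), ("P", "a")]),
    ],
)
def test_enumeration_matches_pairing_oracle(case):
    g = make_graph(case["lengths"], case["repeats"], case["topology"], seed=5)
    for sid, m in case.get("mult_overrides", {}).items():
        g = assign_multiplicities(
            g, overrides={**{r: 2 for r in case["repeats"]}, sid: m}
        )
    confs = enumerate_conformations(g)
    mine = {tuple(c.key() for c in conf.circles) for conf in confs}
    oracle = {
        tuple(sorted(chosen)) for chosen in _oracle_conformations(g)
    }
    mine_norm = {tuple(sorted(conf)) for conf in mine}
    assert mine_norm == oracle


# ------------------------------------------------------------ summaries

def test_chromosome_summary_lengths_match_published_arithmetic(iris_graph_full):
    confs = enumerate_conformations(iris_graph_full)
    primary = confs[0]
    df = conformation_summary(primary, iris_graph_full)
    # contig1+contig2+R1+R2 and contig4+R2, all overlaps zero
    assert df["length_bp"].tolist() == [324581, 50347, 42766]
    assert (df["type"] == "circular").all()
    assert df["chromosome"].tolist() == ["chromosome_1", "chromosome_2", "chromosome_3"]


def test_summary_gc_of_pure_gc_circle():
    g = AssemblyGraph()
    g.add_segment(Segment("gc", "GC" * 20))
    g.add_link(Link("gc", "+", "gc", "+", 0))
    conf = enumerate_conformations(g)[0]
    df = conformation_summary(conf, g)
    assert df["gc_percent"].iloc[0] == 100.00


def test_summary_missing_sequence_names_segment(iris_graph_small):
    graph, truth = iris_graph_small
    conf = truth.conformations["3-circle"]
    broken = AssemblyGraph()
    for sid, seg in graph.segments.items():
        if sid != "ctg2":
            broken.add_segment(seg)
    broken.links = set(graph.links)
    with pytest.raises(GraphValidationError, match="ctg2"):
        conformation_summary(conf, broken)
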
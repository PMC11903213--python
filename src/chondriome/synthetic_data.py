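"""Synthetic organelle genomes with ground truth.

Every pipeline stage is exercised on generated data: a toy multipartite
mitogenome graph (four unique contigs joined by two repeats, the classic
two-repeat topology whose repeat pairings yield one three-circle, two
two-circle and one single-circle conformation), noisy long reads drawn from
a mixture of conformations, a plastome with an inverted-repeat pair and
planted mito-homologous transfers, planted SSR/dispersed repeats, and
fabricated C-to-U edit-site lists.  All generators are deterministic under a
fixed seed and record exact ground-truth coordinates.

Default dimensions are a 1/100 scale-down of a real multichromosomal
mitogenome (contigs 2,225 / 908 / 426 / 392 bp) with both repeats floored at
300 bp so that junction-spanning reads remain meaningful; full scale is one
``scale=1.0`` away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import random_dna, revcomp
from .editing_effects import EditSite, apply_c_to_u
from .graph_model import (
    AssemblyGraph,
    Conformation,
    Link,
    Segment,
    enumerate_conformations,
    label_conformations,
)

__all__ = [
    "SimSpec",
    "ReadSimParams",
    "GroundTruth",
    "build_toy_graph",
    "simulate_long_reads",
    "build_toy_plastome",
    "plant_repeats",
    "simulate_edit_sites",
]

#: published contig/repeat lengths of the Iris domestica mitogenome graph
IRIS_CONTIGS = {"ctg1": 222498, "ctg2": 90780, "ctg3": 42563, "ctg4": 39247}
IRIS_REPEATS = {"R1": 7784, "R2": 3519}
IRIS_TOPOLOGY = [
    ("ctg1", "R1"),
    ("R1", "ctg2"),
    ("R1", "ctg3"),
    ("ctg3", "R1"),
    ("ctg2", "R2"),
    ("R2", "ctg1"),
    ("ctg4", "R2"),
    ("R2", "ctg4"),
]


@dataclass
class SimSpec:
    """Dimensions and topology of a toy mitogenome graph."""

    contig_lengths: dict[str, int] = field(default_factory=lambda: dict(IRIS_CONTIGS))
    repeat_lengths: dict[str, int] = field(default_factory=lambda: dict(IRIS_REPEATS))
    topology: list[tuple[str, str]] = field(default_factory=lambda: list(IRIS_TOPOLOGY))
    gc_target: float = 0.46
    seed: int = 0

    def __post_init__(self):
        declared = set(self.contig_lengths) | set(self.repeat_lengths)
        for a, b in self.topology:
            if a not in declared or b not in declared:
                raise ValueError(f"topology references undeclared segment {a!r}/{b!r}")
        for sid, L in {**self.contig_lengths, **self.repeat_lengths}.items():
            if L < 1:
                raise ValueError(f"segment {sid!r}: length must be >= 1")

    @classmethod
    def iris(cls, scale: float = 0.01, seed: int = 0, repeat_floor: int = 300) -> "SimSpec":
        """The two-repeat four-contig topology at a given scale; repeat
        lengths are floored so junctions stay spannable by reads."""
        return cls(
            contig_lengths={k: max(50, round(v * scale)) for k, v in IRIS_CONTIGS.items()},
            repeat_lengths={
                k: max(repeat_floor, round(v * scale)) for k, v in IRIS_REPEATS.items()
            },
            seed=seed,
        )


@dataclass
class ReadSimParams:
    """Long-read simulation: a conformation mixture, fold coverage, a
    log-normal length distribution and i.i.d. per-base errors."""

    weights: dict[str, float]
    depth: float = 30.0
    read_length_mean: float = 1500.0
    read_length_sd: float = 1000.0
    sub_rate: float = 0.04
    ins_rate: float = 0.02
    del_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.weights.values()) - 1.0) > 1e-9:
            raise ValueError("conformation weights must sum to 1")
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= r <= 0.2:
                raise ValueError("error rates must be in [0, 0.2]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclass
class GroundTruth:
    """Planted features and per-read provenance, as generated."""

    conformations: dict[str, Conformation] | None = None
    reads: pd.DataFrame | None = None
    ir: tuple[tuple[int, int], tuple[int, int]] | None = None
    transfers: list[dict] = field(default_factory=list)
    ssrs: list[dict] = field(default_factory=list)
    dispersed: list[dict] = field(default_factory=list)
    edit_sites: pd.DataFrame | None = None


# ----------------------------------------------------------------- graph

def build_toy_graph(spec: SimSpec | None = None) -> tuple[AssemblyGraph, GroundTruth]:
    """Random sequences on the spec's topology; repeats are multiplicity 2,
    contigs 1.  Ground truth holds the labelled conformation enumeration."""
    spec = spec or SimSpec.iris()
    rng = np.random.default_rng([spec.seed, 1])
    graph = AssemblyGraph()
    for sid in sorted(spec.contig_lengths):
        graph.add_segment(
            Segment(sid, random_dna(rng, spec.contig_lengths[sid], spec.gc_target))
        )
    for sid in sorted(spec.repeat_lengths):
        graph.add_segment(
            Segment(sid, random_dna(rng, spec.repeat_lengths[sid], spec.gc_target), multiplicity=2)
        )
    for a, b in spec.topology:
        graph.add_link(Link(a, "+", b, "+", 0))
    confs = enumerate_conformations(graph)  # raises if the topology cannot close
    return graph, GroundTruth(conformations=label_conformations(confs))


def _circle_sequence(graph: AssemblyGraph, circle) -> str:
    parts = []
    for s in circle.steps:
        seq = graph.segments[s.segment_id].sequence
        parts.append(seq if s.orient == "+" else revcomp(seq))
    return "".join(parts)


def _mutate(seq: str, rng: np.random.Generator, sub: float, ins: float, de: float) -> str:
    bases = "ACGT"
    out = []
    for ch in seq:
        r = rng.random()
        if r < de:
            continue
        if r < de + sub:
            out.append(bases[(bases.index(ch) + rng.integers(1, 4)) % 4] if ch in bases else ch)
        else:
            out.append(ch)
        if rng.random() < ins:
            out.append(bases[rng.integers(4)])
    return "".join(out)


def simulate_long_reads(
    graph: AssemblyGraph, truth: GroundTruth, params: ReadSimParams
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Reads drawn from circles proportional to conformation weight x circle
    length; uniform start (reads may cross the origin), uniform strand,
    i.i.d. errors.  Returns (read_id, sequence) pairs and a per-read truth
    table."""
    if truth.conformations is None:
        raise ValueError("ground truth lacks conformations")
    for label in params.weights:
        if label not in truth.conformations:
            raise ValueError(f"weight references unknown conformation {label!r}")
    rng = np.random.default_rng([params.seed, 2])
    pool = []  # (conf_label, circle_idx, circle_seq, probability mass)
    for label, w in sorted(params.weights.items()):
        if w <= 0:
            continue
        conf = truth.conformations[label]
        for ci, circle in enumerate(conf.circles):
            pool.append((label, ci, _circle_sequence(graph, circle), w * circle.length))
    masses = np.array([m for *_, m in pool])
    masses = masses / masses.sum()
    genome_len = next(iter(truth.conformations.values())).total_length
    n_reads = max(1, round(params.depth * genome_len / params.read_length_mean))
    sigma2 = np.log(1 + params.read_length_sd**2 / params.read_length_mean**2)
    mu = np.log(params.read_length_mean) - sigma2 / 2

    reads: list[tuple[str, str]] = []
    rows = []
    for i in range(n_reads):
        which = rng.choice(len(pool), p=masses)
        label, ci, cseq, _ = pool[which]
        L = len(cseq)
        length = int(np.clip(rng.lognormal(mu, np.sqrt(sigma2)), 50, L))
        start = int(rng.integers(L))
        frag = (cseq + cseq)[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        seq = _mutate(frag, rng, params.sub_rate, params.ins_rate, params.del_rate)
        rid = f"read{i:05d}"
        reads.append((rid, seq))
        rows.append(
            {
                "read_id": rid,
                "conformation": label,
                "circle": ci,
                "start": start + 1,
                "length": length,
                "strand": strand,
            }
        )
    return reads, pd.DataFrame(rows)


# -------------------------------------------------------------- plastome

def build_toy_plastome(
    length: int = 30000,
    ir_length: int = 3000,
    transfers: list[tuple] = (),
    seed: int = 0,
    mito_seqs: dict[str, str] | None = None,
    gc_target: float = 0.37,
) -> tuple[str, dict[str, str], GroundTruth]:
    """A plastome with an exact IR pair (LSC-IRa-SSC-IRb layout) and planted
    mito-homologous transfers.

    ``transfers`` holds (length, divergence[, region]) tuples; region is
    'single' (default, source in the LSC) or 'ir' (source inside IRa, hence
    duplicated in IRb — a planted transfer hotspot).  Each transfer
    overwrites a random interval of a mitochondrial sequence with a
    divergence-mutated copy of the plastome source.
    """
    if 2 * ir_length >= length:
        raise ValueError("2 * ir_length must be smaller than the plastome length")
    rng = np.random.default_rng([seed, 3])  # stream distinct from the graph generator
    sc_total = length - 2 * ir_length
    lsc_len = (2 * sc_total) // 3
    ssc_len = sc_total - lsc_len
    lsc = random_dna(rng, lsc_len, gc_target)
    ira = random_dna(rng, ir_length, gc_target)
    ssc = random_dna(rng, ssc_len, gc_target)
    plastome = lsc + ira + ssc + revcomp(ira)
    ira_iv = (lsc_len + 1, lsc_len + ir_length)
    irb_iv = (lsc_len + ir_length + ssc_len + 1, length)

    mito = dict(mito_seqs or {})
    if not mito:
        mito = {"chrM": random_dna(rng, 20000, 0.45)}
    chrom_ids = sorted(mito)
    truth = GroundTruth(ir=(ira_iv, irb_iv))
    used: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_ids}
    for t in transfers:
        t_len, divergence, *rest = t
        region = rest[0] if rest else "single"
        if region == "ir":
            if t_len > ir_length:
                raise ValueError(f"transfer of {t_len} bp does not fit in the {ir_length} bp IR")
            src = int(rng.integers(ira_iv[0] - 1, ira_iv[1] - t_len + 1))
        else:
            if t_len > lsc_len:
                raise ValueError(
                    f"transfer of {t_len} bp exceeds the {lsc_len} bp single-copy region"
                )
            src = int(rng.integers(0, lsc_len - t_len + 1))
        fragment = plastome[src : src + t_len]
        if divergence > 0:
            frag = list(fragment)
            n_mut = round(divergence * t_len)
            for pos in rng.choice(t_len, size=n_mut, replace=False):
                frag[pos] = "ACGT"[(("ACGT".index(frag[pos])) + rng.integers(1, 4)) % 4]
            fragment = "".join(frag)
        # pick a destination chromosome/interval not already used
        for _attempt in range(500):
            chrom = chrom_ids[rng.integers(len(chrom_ids))]
            if len(mito[chrom]) <= t_len + 2:
                continue
            dst = int(rng.integers(1, len(mito[chrom]) - t_len))
            if all(dst + t_len <= s or dst >= e for s, e in used[chrom]):
                break
        else:
            raise ValueError("could not place transfer without overlap")
        used[chrom].append((dst, dst + t_len))
        mito[chrom] = mito[chrom][:dst] + fragment + mito[chrom][dst + t_len :]
        truth.transfers.append(
            {
                "chromosome": chrom,
                "mito_start": dst + 1,
                "mito_end": dst + t_len,
                "plastid_start": src + 1,
                "plastid_end": src + t_len,
                "length": t_len,
                "divergence": divergence,
                "region": region,
            }
        )
    return plastome, mito, truth


# ---------------------------------------------------------------- repeats

def plant_repeats(
    seq: str,
    ssr_spec: list[tuple[str, int]] = (),
    dispersed_spec: list[tuple[int, str]] = (),
    seed: int = 0,
) -> tuple[str, GroundTruth]:
    """Overwrite random non-overlapping intervals with SSR arrays
    (motif, copies) and dispersed repeat copies (length, 'forward' |
    'palindromic').  Planted SSR boundaries are adjusted so the array is
    maximal exactly as planted."""
    rng = np.random.default_rng([seed, 4])
    s = list(seq.upper())
    used: list[tuple[int, int]] = []
    truth = GroundTruth()

    def reserve(length: int, margin: int = 2) -> int:
        for _ in range(500):
            p = int(rng.integers(margin, len(s) - length - margin))
            if all(p + length + margin <= a or p >= b + margin for a, b in used):
                used.append((p, p + length))
                return p
        raise ValueError("overlap-free placement impossible")

    def other_base(b: str) -> str:
        return "ACGT"[("ACGT".index(b) + 1 + int(rng.integers(3))) % 4]

    for motif, copies in ssr_spec:
        motif = motif.upper()
        u = len(motif)
        arr = motif * copies
        p = reserve(len(arr))
        s[p : p + len(arr)] = arr
        # break periodicity at both boundaries so the planted array is maximal
        if s[p - 1] == s[p - 1 + u]:
            s[p - 1] = other_base(s[p - 1 + u])
        end = p + len(arr)
        if s[end] == s[end - u]:
            s[end] = other_base(s[end - u])
        truth.ssrs.append(
            {"motif": motif, "unit_size": u, "copies": copies, "start": p + 1, "end": p + len(arr)}
        )

    for length, orientation in dispersed_spec:
        src = reserve(length)
        dst = reserve(length)
        copy = "".join(s[src : src + length])
        if orientation == "palindromic":
            copy = revcomp(copy)
        s[dst : dst + length] = copy
        a, b = sorted((src, dst))
        truth.dispersed.append(
            {
                "start_a": a + 1,
                "end_a": a + length,
                "start_b": b + 1,
                "end_b": b + length,
                "length": length,
                "orientation": orientation,
            }
        )
    return "".join(s), truth


# ------------------------------------------------------------- edit sites

def simulate_edit_sites(
    cds_map: dict[str, str],
    n_sites: int,
    fraction_synonymous_target: float | None = None,
    seed: int = 0,
) -> tuple[list[EditSite], GroundTruth]:
    """Sample ``n_sites`` C positions (without replacement) across the CDS
    set, probabilities uniform in [0.9, 1.0]; the truth table stores each
    site's category from direct codon translation.

    When ``fraction_synonymous_target`` is set, that fraction of sites is
    drawn from synonymous-capable C positions (an error if too few exist).
    """
    rng = np.random.default_rng([seed, 5])
    candidates: list[tuple[str, int, str]] = []  # (gene, pos, category)
    for gene in sorted(cds_map):
        cds = cds_map[gene].upper().replace("U", "T")
        usable = 3 * (len(cds) // 3)
        for pos in range(1, usable + 1):
            if cds[pos - 1] == "C":
                change = apply_c_to_u(cds, EditSite(gene, pos, 1.0))
                candidates.append((gene, pos, change.category))
    if n_sites > len(candidates):
        raise ValueError(f"requested {n_sites} sites but only {len(candidates)} C positions exist")

    if fraction_synonymous_target is None:
        chosen_idx = rng.choice(len(candidates), size=n_sites, replace=False)
        chosen = [candidates[i] for i in sorted(chosen_idx)]
    else:
        n_syn = round(n_sites * fraction_synonymous_target)
        syn = [c for c in candidates if c[2] == "synonymous"]
        non = [c for c in candidates if c[2] != "synonymous"]
        if n_syn > len(syn):
            raise ValueError(
                f"requested {n_syn} synonymous sites but only {len(syn)} synonymous-capable "
                "C positions exist"
            )
        if n_sites - n_syn > len(non):
            raise ValueError("not enough nonsynonymous-capable C positions")
        pick_s = rng.choice(len(syn), size=n_syn, replace=False)
        pick_n = rng.choice(len(non), size=n_sites - n_syn, replace=False)
        chosen = sorted([syn[i] for i in pick_s] + [non[i] for i in pick_n])

    sites: list[EditSite] = []
    rows = []
    for gene, pos, category in chosen:
        prob = float(0.9 + 0.1 * rng.random())
        cds = cds_map[gene].upper().replace("U", "T")
        up = cds[max(0, pos - 21) : pos - 1]
        down = cds[pos : pos + 20]
        sites.append(EditSite(gene, pos, prob, flank_up=up, flank_down=down))
        rows.append({"gene": gene, "cds_pos": pos, "category": category, "probability": prob})
    truth = GroundTruth(edit_sites=pd.DataFrame(rows))
    return sites, truth
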
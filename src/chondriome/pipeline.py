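"""Pipeline orchestration and report rendering.

Runs the stages in dependency order — graph → conformations → junction
support; repeat, MTPT and editing scans are independent — and collects
their tables into a :class:`ReportBundle` that can be written as TSVs plus
a JSON metadata sidecar.  Every number in the bundle is the direct output
of the corresponding stage API; the report layer never recomputes.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import __version__
from .editing_effects import apply_c_to_u, read_sites_tsv, summarize_editing
from .graph_model import conformation_summary, enumerate_conformations, label_conformations, read_gfa
from .junction_support import (
    SupportParams,
    SupportTable,
    build_junction_refs,
    rank_conformations,
    tabulate_support,
)
from .mtpt_scan import (
    annotate_contained_genes,
    classify_hotspots,
    detect_inverted_repeat,
    homology_search,
    summarize_mtpt,
)
from .repeat_scan import (
    SSRThresholds,
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
    repeat_summary,
)

log = logging.getLogger("chondriome")

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "render_support_table", "parse_support_table"]


@dataclass
class PipelineConfig:
    """Inputs, stage toggles and stage parameters (field defaults are the
    analysis defaults: 2 kb junction flanks, 200 bp anchors, 80% identity,
    MISA thresholds 1-10 2-5 3-4 4-3 5-3 6-3, e-value 1e-5, editing
    probability floor 0.9)."""

    gfa: str | None = None
    reads: str | None = None
    plastome: str | None = None
    genes: str | None = None
    cds: str | None = None
    sites: str | None = None

    run_conformations: bool = True
    run_support: bool = True
    run_repeats: bool = True
    run_mtpt: bool = True
    run_editing: bool = True

    flank_len: int = 2000
    min_anchor: int = 200
    min_identity: float = 80.0
    ssr_thresholds: str = "1-10 2-5 3-4 4-3 5-3 6-3"
    min_dispersed_len: int = 30
    dispersed_min_identity: float = 90.0
    mtpt_min_identity: float = 80.0
    max_evalue: float = 1e-5
    min_probability: float = 0.9

    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        checks = [
            ("min_identity", 0 < self.min_identity <= 100),
            ("dispersed_min_identity", 0 < self.dispersed_min_identity <= 100),
            ("mtpt_min_identity", 0 < self.mtpt_min_identity <= 100),
            ("min_probability", 0 <= self.min_probability <= 1),
            ("flank_len", self.flank_len >= 0),
            ("min_anchor", 0 <= self.min_anchor <= self.flank_len),
            ("min_dispersed_len", self.min_dispersed_len >= 8),
            ("max_evalue", self.max_evalue > 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid parameter {name}: {getattr(self, name)!r}")
        needs = []
        if self.run_conformations or self.run_support or self.run_repeats or self.run_mtpt:
            needs.append(("gfa", self.gfa))
        if self.run_support:
            needs.append(("reads", self.reads))
        if self.run_mtpt:
            needs.append(("plastome", self.plastome))
        if self.run_editing:
            needs.append(("cds", self.cds))
            needs.append(("sites", self.sites))
        for name, path in needs:
            if path is None:
                raise ValueError(f"stage enabled but input {name!r} is not configured")
            if not Path(path).exists():
                raise FileNotFoundError(f"input {name!r}: no such file {path}")


@dataclass
class ReportBundle:
    conformations: pd.DataFrame | None = None
    chromosome_table: pd.DataFrame | None = None
    support_table: pd.DataFrame | None = None
    ranking: pd.DataFrame | None = None
    repeat_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    mtpt_table: pd.DataFrame | None = None
    mtpt_summary: dict | None = None
    editing_table: pd.DataFrame | None = None
    editing_summary: dict | None = None
    metadata: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "conformations.tsv": self.conformations,
            "chromosomes.tsv": self.chromosome_table,
            "support.tsv": self.support_table,
            "ranking.tsv": self.ranking,
            "mtpt.tsv": self.mtpt_table,
            "editing.tsv": self.editing_table,
        }
        for name, df in self.repeat_tables.items():
            tables[f"repeats_{name}.tsv"] = df
        for name, df in tables.items():
            if df is not None:
                df.to_csv(out / name, sep="\t", index=False)
        meta = dict(self.metadata)
        if self.mtpt_summary:
            meta["mtpt_summary"] = self.mtpt_summary
        if self.editing_summary:
            meta["editing_summary"] = self.editing_summary
        (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=str) + "\n")


def _read_fastx(path) -> list[tuple[str, str]]:
    fmt = "fastq" if str(path).endswith((".fastq", ".fq")) else "fasta"
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]


def render_support_table(table: SupportTable) -> pd.DataFrame:
    """Spanning, path-assigned records in the published table layout:
    numbered rows, identity to three decimals."""
    rows = []
    for r in table.records:
        if not r.spanning or table.assignments.get(r.read_id) != r.path_label:
            continue
        rows.append(
            {
                "No.": 0,
                "Path": r.path_label,
                "Reads_ID": r.read_id,
                "Identity_pct": round(r.alignment.identity, 3),
                "Alignment_bp": r.alignment.alignment_len,
                "Reference_start": r.alignment.ref_start,
                "Reference_end": r.alignment.ref_end,
                "Reads_start": r.alignment.read_start,
                "Reads_end": r.alignment.read_end,
                "Spanning": True,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "No.", "Path", "Reads_ID", "Identity_pct", "Alignment_bp",
            "Reference_start", "Reference_end", "Reads_start", "Reads_end", "Spanning",
        ],
    )
    df["No."] = range(1, len(df) + 1)
    return df


def parse_support_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _stage(name):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)

    return _Timer()


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the enabled stages and return (and optionally write) the
    report bundle.  Raises before any computation when the configuration is
    invalid."""
    config.validate()
    bundle = ReportBundle()
    bundle.metadata = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if k not in {"gfa", "reads", "plastome", "genes", "cds", "sites", "outdir"}
        },
        "inputs": {
            k: getattr(config, k)
            for k in ("gfa", "reads", "plastome", "genes", "cds", "sites")
            if getattr(config, k)
        },
    }

    graph = None
    confs = None
    labels = None
    primary = None
    chromosomes: dict[str, str] = {}
    if config.gfa and (
        config.run_conformations or config.run_support or config.run_repeats or config.run_mtpt
    ):
        with _stage("graph"):
            graph = read_gfa(config.gfa)
            confs = enumerate_conformations(graph)
            labels = label_conformations(confs)
            primary = confs[0]
            log.info("graph: %d segments, %d conformations", len(graph.segments), len(confs))
        summary = conformation_summary(primary, graph)
        chromosomes = dict(zip(summary["chromosome"], summary["path"]))
        from ._seq import revcomp as _rc

        chrom_seqs = {}
        for circle in primary.circles:
            seq = "".join(
                graph.segments[s.segment_id].sequence
                if s.orient == "+"
                else _rc(graph.segments[s.segment_id].sequence)
                for s in circle.steps
            )
            chrom_seqs[str(circle)] = seq
        # re-key by chromosome label (summary rows map path -> chromosome)
        chromosomes = {
            row.chromosome: chrom_seqs[row.path] for row in summary.itertuples(index=False)
        }
        if config.run_conformations:
            rows = []
            for lab, conf in labels.items():
                note = (
                    "requires simultaneous crossing of both repeats"
                    if conf.n_circles == 1 and len(confs) > 1
                    else ""
                )
                rows.append(
                    {
                        "conformation": lab,
                        "n_circles": conf.n_circles,
                        "total_length_bp": conf.total_length,
                        "circles": str(conf),
                        "note": note,
                    }
                )
            bundle.conformations = pd.DataFrame(rows)
            bundle.chromosome_table = summary
    elif config.run_conformations:
        raise ValueError("stage enabled but input 'gfa' is not configured")

    if config.run_support:
        with _stage("support"):
            reads = _read_fastx(config.reads)
            repeats = sorted(
                sid for sid, seg in graph.segments.items() if seg.multiplicity >= 2
            )
            refs = []
            for rid in repeats:
                refs.extend(build_junction_refs(graph, rid, config.flank_len))
            params = SupportParams(
                flank_len=config.flank_len,
                min_anchor=config.min_anchor,
                min_identity=config.min_identity,
            )
            table = tabulate_support(reads, refs, params)
            ranking = rank_conformations(confs, table)
            log.info(
                "support: %d reads, %d assigned, dominant %s",
                len(reads), len(table.assignments), ranking.dominant,
            )
        bundle.support_table = render_support_table(table)
        bundle.ranking = ranking.to_frame()
        bundle.metadata["dominant_conformation"] = ranking.dominant
        bundle.metadata["path_counts"] = ranking.path_counts

    if config.run_repeats:
        with _stage("repeats"):
            thresholds = SSRThresholds.from_misa(config.ssr_thresholds)
            ssrs = []
            tandems = []
            for chrom, seq in chromosomes.items():
                ssrs.extend(find_ssrs(seq, thresholds, chromosome=chrom, circular=True))
                tandems.extend(find_tandem_repeats(seq, chromosome=chrom, circular=True))
            dispersed = find_dispersed_repeats(
                chromosomes,
                min_len=config.min_dispersed_len,
                min_identity=config.dispersed_min_identity,
            )
            log.info(
                "repeats: %d SSRs, %d tandem, %d dispersed pairs",
                len(ssrs), len(tandems), len(dispersed),
            )
        bundle.repeat_tables["ssr"] = pd.DataFrame(
            [vars(r) for r in ssrs],
            columns=["chromosome", "motif", "unit_size", "copies", "start", "end", "compound"],
        )
        bundle.repeat_tables["tandem"] = pd.DataFrame(
            [vars(r) for r in tandems],
            columns=["chromosome", "start", "end", "period", "copies", "percent_matches"],
        )
        bundle.repeat_tables["dispersed"] = pd.DataFrame(
            [vars(r) for r in dispersed],
            columns=[
                "id_a", "start_a", "end_a", "id_b", "start_b", "end_b",
                "orientation", "length", "identity",
            ],
        )
        bundle.repeat_tables["summary"] = repeat_summary(
            list(chromosomes), ssrs, tandems, dispersed
        )

    if config.run_mtpt:
        with _stage("mtpt"):
            plastome = _read_fastx(config.plastome)[0][1]
            ir = detect_inverted_repeat(plastome)
            fragments = homology_search(
                chromosomes,
                plastome,
                min_identity=config.mtpt_min_identity,
                max_evalue=config.max_evalue,
            )
            classify_hotspots(fragments, ir)
            if config.genes:
                genes = [
                    (str(r.name), int(r.start), int(r.end), str(r.strand))
                    for r in pd.read_csv(config.genes, sep="\t").itertuples(index=False)
                ]
                annotate_contained_genes(fragments, genes, len(plastome))
            mito_len = sum(len(s) for s in chromosomes.values())
            summary = summarize_mtpt(fragments, mito_len)
            log.info(
                "mtpt: %d fragments, %d bp (%.2f%%)",
                summary.n_fragments, summary.cumulative_bp, summary.percent_of_mitogenome,
            )
        bundle.mtpt_table = pd.DataFrame(
            [
                {
                    "label": f.label,
                    "mito_chr": f.chromosome,
                    "mito_start": f.mito_start,
                    "mito_end": f.mito_end,
                    "plastid_intervals": ";".join(
                        f"{s}-{e}({st})" for s, e, st in f.plastid_intervals
                    ),
                    "length": f.length,
                    "identity": f.identity,
                    "evalue": f.e_value,
                    "hotspot": f.hotspot,
                    "complete_genes": ",".join(f.contained_genes),
                }
                for f in fragments
            ]
        )
        bundle.mtpt_summary = asdict(summary)

    if config.run_editing:
        with _stage("editing"):
            cds_map = {rid: seq for rid, seq in _read_fastx(config.cds)}
            sites = read_sites_tsv(config.sites)
            for s in sites:
                if s.gene not in cds_map:
                    raise ValueError(f"site references unknown gene {s.gene!r}")
                s.change = apply_c_to_u(cds_map[s.gene], s)
            summary = summarize_editing(sites, min_probability=config.min_probability)
            log.info(
                "editing: %d sites (%d syn / %d nonsyn)",
                summary.n_sites, summary.n_synonymous, summary.n_nonsynonymous,
            )
        bundle.editing_table = pd.DataFrame(
            [
                {
                    "gene": s.gene,
                    "pos": s.cds_pos,
                    "codon_index": s.change.codon_index,
                    "old_codon": s.change.old_codon,
                    "new_codon": s.change.new_codon,
                    "old_aa": s.change.old_aa,
                    "new_aa": s.change.new_aa,
                    "category": s.change.category,
                    "probability": s.probability,
                }
                for s in sites
                if s.probability >= config.min_probability
            ]
        )
        bundle.editing_summary = asdict(summary)

    if config.outdir:
        bundle.write(config.outdir)
    return bundle
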
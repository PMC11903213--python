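"""Codon-level consequences of C-to-U RNA editing on coding sequences.

Plant mitochondrial transcripts are post-transcriptionally edited, almost
exclusively converting cytidine to uridine.  Given a CDS and the 1-based
position of an edited C, this module derives the affected codon, the amino
acids before and after, and a category:

* ``start_gain`` — codon 1 becomes AUG from a non-AUG codon (e.g. ACG),
* ``stop_gain``  — the edited codon is a stop while the original was not,
* ``synonymous`` / ``nonsynonymous`` — by comparison of the encoded amino
  acids under the standard genetic code (plant mitochondria use it).

Stop- and start-gains count as nonsynonymous in summaries.  Input may be DNA
or RNA; codons are reported in the RNA alphabet (ACG -> AUG).  Sites come
from upstream prediction tools as a (gene, position, probability) table and
are filtered on a probability floor before summarisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "EditSite",
    "CodonChange",
    "EditingSummary",
    "locate_codon",
    "apply_c_to_u",
    "summarize_editing",
    "read_sites_tsv",
]

CATEGORIES = ("synonymous", "nonsynonymous", "stop_gain", "start_gain")


@dataclass
class EditSite:
    gene: str
    cds_pos: int  # 1-based on the coding sequence
    probability: float = 1.0
    flank_up: str = ""
    flank_down: str = ""
    change: "CodonChange | None" = None

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability must be in [0, 1], got {self.probability}")
        if self.cds_pos < 1:
            raise ValueError("cds_pos is 1-based and must be >= 1")


@dataclass
class CodonChange:
    codon_index: int  # 1-based
    offset_in_codon: int  # 1..3
    old_codon: str  # RNA alphabet
    new_codon: str
    old_aa: str  # single letter; '*' for stop
    new_aa: str
    category: str


@dataclass
class EditingSummary:
    n_sites: int
    n_synonymous: int
    n_nonsynonymous: int
    n_stop_gain: int
    n_start_gain: int
    per_gene: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.per_gene.items()), columns=["gene", "n_sites"]
        )


def locate_codon(cds_pos: int, cds_len: int | None = None) -> tuple[int, int]:
    """Map a 1-based CDS position to (codon_index, offset_in_codon)."""
    if cds_pos < 1:
        raise ValueError("cds_pos must be >= 1")
    if cds_len is not None and cds_pos > cds_len:
        raise IndexError(f"cds_pos {cds_pos} beyond CDS length {cds_len}")
    return (cds_pos + 2) // 3, (cds_pos - 1) % 3 + 1


def _translate_codon(codon_rna: str, table: CodonTable.CodonTable) -> str:
    if codon_rna in table.stop_codons:
        return "*"
    return table.forward_table[codon_rna]


def apply_c_to_u(
    cds: str, site: EditSite, table_id: int = 1
) -> CodonChange:
    """Consequence of editing the C at ``site.cds_pos`` to U.

    The base at the position must be C (T is read as U throughout); the
    genetic code defaults to the standard table and is swappable by NCBI
    table number.
    """
    rna = cds.upper().replace("T", "U")
    pos = site.cds_pos
    if pos > len(rna):
        raise IndexError(f"{site.gene}: cds_pos {pos} beyond CDS length {len(rna)}")
    if rna[pos - 1] != "C":
        raise ValueError(
            f"{site.gene}: position {pos} is {rna[pos - 1]!r}, not an editable C"
        )
    codon_index, offset = locate_codon(pos)
    c0 = (codon_index - 1) * 3
    if c0 + 3 > len(rna):
        raise IndexError(f"{site.gene}: codon {codon_index} is incomplete")
    old_codon = rna[c0 : c0 + 3]
    new_codon = old_codon[: offset - 1] + "U" + old_codon[offset:]
    table = CodonTable.unambiguous_rna_by_id[table_id]
    old_aa = _translate_codon(old_codon, table)
    new_aa = _translate_codon(new_codon, table)
    if codon_index == 1 and new_codon == "AUG" and old_codon != "AUG":
        category = "start_gain"
    elif new_aa == "*" and old_aa != "*":
        category = "stop_gain"
    elif old_aa == new_aa:
        category = "synonymous"
    else:
        category = "nonsynonymous"
    return CodonChange(codon_index, offset, old_codon, new_codon, old_aa, new_aa, category)


def summarize_editing(
    sites: list[EditSite],
    min_probability: float = 0.9,
    genes: set[str] | None = None,
) -> EditingSummary:
    """Per-gene counts and category totals over sites at or above the
    probability floor; stop- and start-gains are included in the
    nonsynonymous total, so n_sites = synonymous + nonsynonymous."""
    kept = [s for s in sites if s.probability >= min_probability]
    per_gene: dict[str, int] = {}
    n_syn = n_nonsyn = n_stop = n_start = 0
    for s in kept:
        if genes is not None and s.gene not in genes:
            raise ValueError(f"site references unknown gene {s.gene!r}")
        if s.change is None:
            raise ValueError(f"site {s.gene}:{s.cds_pos} has no computed codon change")
        per_gene[s.gene] = per_gene.get(s.gene, 0) + 1
        cat = s.change.category
        if cat == "synonymous":
            n_syn += 1
        else:
            n_nonsyn += 1
            if cat == "stop_gain":
                n_stop += 1
            elif cat == "start_gain":
                n_start += 1
    return EditingSummary(
        n_sites=len(kept),
        n_synonymous=n_syn,
        n_nonsynonymous=n_nonsyn,
        n_stop_gain=n_stop,
        n_start_gain=n_start,
        per_gene=per_gene,
    )


def read_sites_tsv(path) -> list[EditSite]:
    """Read a sites table (gene, cds_pos, probability[, flank_up, flank_down])."""
    df = pd.read_csv(path, sep="\t")
    sites = []
    for row in df.itertuples(index=False):
        sites.append(
            EditSite(
                gene=str(row.gene),
                cds_pos=int(row.cds_pos),
                probability=float(getattr(row, "probability", 1.0)),
                flank_up=str(getattr(row, "flank_up", "") or ""),
                flank_down=str(getattr(row, "flank_down", "") or ""),
            )
        )
    return sites
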
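"""Gene organization tables for annotated mitogenomes.

Produces, for each feature, the quantities conventionally tabulated in
mitogenome descriptions: size in bp, start/stop codon class for
protein-coding genes, and *continuity* — the signed number of nucleotides
between a feature and its predecessor in genome coordinate order
(0 = abutting, negative = overlap, positive = intergenic spacer).

Vertebrate mitochondrial PCGs frequently end on incomplete stop codons
("T" or "TA") that are completed to UAA by post-transcriptional
polyadenylation; these are reported as truncated classes, never "repaired".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .mito_io import GeneFeature, Mitogenome, extract_feature_seq

#: Stop codons of the vertebrate mitochondrial code (NCBI translation table 2).
MITO_STOP_CODONS = frozenset({"TAA", "TAG", "AGA", "AGG"})


class GeneTableError(ValueError):
    pass


def feature_size(start: int, end: int) -> int:
    """Feature size in bp for a 1-based inclusive [start, end] interval."""
    if start > end:
        raise GeneTableError(f"start {start} > end {end}")
    return end - start + 1


def continuity(prev_end: int, start: int) -> int:
    """Signed nucleotide count between consecutive features.

    ``start - prev_end - 1``: 0 means abutting, negative values are
    overlaps, positive values intergenic spacers.  Computed in genome
    coordinate order regardless of strand, so L-strand genes participate
    in the same chain as their H-strand neighbours.
    """
    return start - prev_end - 1


def classify_codons(cds: str) -> tuple[str, str, bool]:
    """Start/stop codon classes of a coding-sense CDS.

    Returns ``(start_codon, stop_codon, ok)``.  The stop class follows the
    length remainder mod 3: complete final codon when the length is a
    multiple of 3 (must be a mitochondrial stop — TAA/TAG/AGA/AGG —
    otherwise ``ok`` is False and the terminal triplet is reported as-is),
    truncated "TA" at remainder 2, truncated "T" at remainder 1.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise GeneTableError("CDS shorter than one codon")
    start_codon = cds[:3]
    rem = len(cds) % 3
    if rem == 0:
        stop = cds[-3:]
        return start_codon, stop, stop in MITO_STOP_CODONS
    if rem == 2:
        return start_codon, "TA", cds[-2:] == "TA"
    return start_codon, "T", cds[-1] == "T"


@dataclass(frozen=True)
class OrganizationRow:
    feature: GeneFeature
    size_bp: int
    continuity: int
    start_codon: Optional[str] = None  # PCGs with sequence only
    stop_codon: Optional[str] = None  # "TAA"/"AGA"/... or truncated "TA"/"T"
    flagged: bool = False  # complete-length CDS ending outside the stop set


@dataclass
class OrganizationTable:
    rows: list[OrganizationRow]
    genome_length: Optional[int]

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, name: str) -> OrganizationRow:
        for r in self.rows:
            if r.feature.name == name:
                return r
        raise KeyError(name)

    # -- aggregates ---------------------------------------------------------
    def count(self, category: str) -> int:
        return sum(1 for r in self.rows if r.feature.category == category)

    def total_bp(self, category: str) -> int:
        return sum(r.size_bp for r in self.rows if r.feature.category == category)

    def summary(self) -> dict[str, int | None]:
        trna_sizes = [r.size_bp for r in self.rows if r.feature.category == "tRNA"]
        return {
            "n_features": len(self.rows),
            "n_pcg": self.count("PCG"),
            "n_trna": self.count("tRNA"),
            "n_rrna": self.count("rRNA"),
            "n_control": self.count("control"),
            "pcg_total_bp": self.total_bp("PCG"),
            "trna_total_bp": self.total_bp("tRNA"),
            "trna_min_bp": min(trna_sizes) if trna_sizes else None,
            "trna_max_bp": max(trna_sizes) if trna_sizes else None,
            "genome_length": self.genome_length,
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Gene": [r.feature.name for r in self.rows],
                "Strand": [r.feature.strand for r in self.rows],
                "Start": [r.feature.start for r in self.rows],
                "End": [r.feature.end for r in self.rows],
                "Size(bp)": [r.size_bp for r in self.rows],
                "StartCodon": [r.start_codon or "-" for r in self.rows],
                "StopCodon": [r.stop_codon or "-" for r in self.rows],
                "Anticodon": [r.feature.anticodon or "-" for r in self.rows],
                "Continuity": [r.continuity for r in self.rows],
            }
        )

    def to_tsv(self, path: str | Path, header_comment: str = "") -> None:
        text = ""
        if header_comment:
            text += "".join(f"# {l}\n" for l in header_comment.splitlines())
        text += self.to_dataframe().to_csv(sep="\t", index=False)
        Path(path).write_text(text)

    def to_markdown(self) -> str:
        return self.to_dataframe().to_markdown(index=False)


def build_table(genome: Mitogenome) -> OrganizationTable:
    """Derive the organization table for a genome.

    One row per feature in start order.  The first row's continuity is
    ``start - 1`` (gap to the circular origin).  Codon columns are filled
    only for PCGs and only when the genome carries a sequence; a
    complete-length CDS whose final codon is not a mitochondrial stop is
    flagged rather than raising.  Pure: identical input -> identical table.
    """
    rows: list[OrganizationRow] = []
    prev_end = 0
    for f in genome.features:
        size = feature_size(f.start, f.end)
        cont = continuity(prev_end, f.start)
        start_codon = stop_codon = None
        flagged = False
        if f.category == "PCG" and genome.sequence is not None:
            start_codon, stop_codon, ok = classify_codons(extract_feature_seq(genome, f))
            flagged = not ok
        rows.append(OrganizationRow(f, size, cont, start_codon, stop_codon, flagged))
        prev_end = f.end
    return OrganizationTable(rows=rows, genome_length=genome.length)
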
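"""Codon counting and relative synonymous codon usage (RSCU).

All counts are taken over the concatenated protein-coding genes on their
coding sense under the vertebrate mitochondrial genetic code (NCBI
translation table 2): AGA/AGG are stops, AUA codes Met and UGA codes Trp.
RSCU of codon *c* in a synonymous family of size *k* is

    RSCU(c) = count(c) * k / sum of counts over the family,

i.e. the observed count divided by the expectation under uniform usage
within the family; the family mean is 1 whenever the family is observed.

Conventions (recorded in output metadata): start codons are counted as
ordinary codons; complete stop codons are excluded from the usage table;
trailing incomplete codons (truncated stops) are dropped.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path

import pandas as pd
from Bio.Data import CodonTable

from .mito_io import Mitogenome, extract_feature_seq

_TABLE2 = CodonTable.unambiguous_dna_by_id[2]

#: codon (RNA alphabet) -> amino acid, vertebrate mitochondrial code
GENETIC_CODE: dict[str, str] = {
    codon.replace("T", "U"): aa for codon, aa in _TABLE2.forward_table.items()
}
STOP_CODONS_RNA = frozenset(c.replace("T", "U") for c in _TABLE2.stop_codons)

#: amino acid -> synonymous family (sorted RNA codons)
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(GENETIC_CODE.items()):
    FAMILIES.setdefault(_aa, ())
    FAMILIES[_aa] += (_codon,)


class CodonUsageError(ValueError):
    pass


def count_codons(cds: str) -> Counter[str]:
    """Codon counts (RNA alphabet) of one coding-sense CDS.

    Trailing incomplete codons are dropped; a terminal complete stop codon
    is excluded.  Codons containing ambiguity symbols are skipped.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) < 3:
        raise CodonUsageError(f"CDS of length {len(cds)} (< 3)")
    usable = len(cds) - len(cds) % 3
    codons = [cds[i : i + 3] for i in range(0, usable, 3)]
    if codons and codons[-1].replace("T", "U") in STOP_CODONS_RNA:
        codons = codons[:-1]
    counts: Counter[str] = Counter()
    for c in codons:
        rna = c.replace("T", "U")
        if rna in GENETIC_CODE:
            counts[rna] += 1
    return counts


def extract_codons(genome: Mitogenome) -> Counter[str]:
    """Pooled codon counts over all annotated PCGs (coding sense)."""
    pcgs = genome.features_of("PCG")
    if not pcgs:
        raise CodonUsageError("genome has no annotated PCGs")
    total: Counter[str] = Counter()
    for f in pcgs:
        total += count_codons(extract_feature_seq(genome, f))
    return total


def rscu(counts: Counter[str] | dict[str, int]) -> pd.DataFrame:
    """RSCU table from codon counts.

    Returns a DataFrame with columns codon (RNA), aa, count, rscu, sorted
    by amino acid then codon.  Families with zero observations get RSCU 0
    for every member.  Unknown codons raise.
    """
    for codon in counts:
        if codon not in GENETIC_CODE:
            raise CodonUsageError(f"codon {codon!r} not in the genetic code")
    records = []
    for aa, family in sorted(FAMILIES.items()):
        family_total = sum(counts.get(c, 0) for c in family)
        k = len(family)
        for c in family:
            n = counts.get(c, 0)
            value = n * k / family_total if family_total else 0.0
            records.append({"codon": c, "aa": aa, "count": n, "rscu": value})
    return pd.DataFrame.from_records(records)


def codon_usage_table(genome: Mitogenome) -> pd.DataFrame:
    return rscu(extract_codons(genome))


def n_preferred_codons(table: pd.DataFrame, threshold: float = 1.0) -> int:
    """Number of codons used above uniform expectation (RSCU > threshold)."""
    return int((table["rscu"] > threshold).sum())


def write_rscu_tsv(table: pd.DataFrame, path: str | Path, header_comment: str = "") -> None:
    out = table.copy()
    out["rscu"] = out["rscu"].map(lambda v: f"{v:.3f}")
    text = "".join(f"# {l}\n" for l in header_comment.splitlines() if header_comment)
    Path(path).write_text(text + out.to_csv(sep="\t", index=False))
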
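"""Base composition and strand-asymmetry (skew) statistics.

AT skew = (A - T) / (A + T) and GC skew = (G - C) / (G + C), the standard
strand-asymmetry measures for mitochondrial genomes.  Ambiguous bases (N)
count toward feature length but are excluded from every composition
denominator.  A skew whose denominator is zero is defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .mito_io import Mitogenome, extract_feature_seq


class CompositionError(ValueError):
    pass


@dataclass(frozen=True)
class CompositionStats:
    a: int
    c: int
    g: int
    t: int

    @property
    def total(self) -> int:
        """Unambiguous bases (composition denominator)."""
        return self.a + self.c + self.g + self.t

    @property
    def at_content(self) -> float:
        return 100.0 * (self.a + self.t) / self.total

    @property
    def gc_content(self) -> float:
        return 100.0 * (self.g + self.c) / self.total

    @property
    def ag_content(self) -> float:
        return 100.0 * (self.a + self.g) / self.total

    @property
    def at_skew(self) -> float:
        return (self.a - self.t) / (self.a + self.t) if self.a + self.t else 0.0

    @property
    def gc_skew(self) -> float:
        return (self.g - self.c) / (self.g + self.c) if self.g + self.c else 0.0

    def __add__(self, other: "CompositionStats") -> "CompositionStats":
        return CompositionStats(
            self.a + other.a, self.c + other.c, self.g + other.g, self.t + other.t
        )


def composition_stats(seq: str) -> CompositionStats:
    """Count bases and derive contents/skews for one sequence."""
    if not seq:
        raise CompositionError("empty sequence")
    seq = seq.upper()
    stats = CompositionStats(seq.count("A"), seq.count("C"), seq.count("G"), seq.count("T"))
    if stats.total == 0:
        raise CompositionError("sequence contains no unambiguous bases")
    return stats


@dataclass
class PCGCompositionSummary:
    """Per-gene stats over the 13 PCGs plus their unweighted mean.

    ``mean_at_content`` is the plain average of per-gene A+T percentages;
    ``concatenated`` carries the length-weighted alternative (stats over
    the concatenation), since published per-class averages rarely say
    which of the two was used.
    """

    per_gene: dict[str, CompositionStats]
    concatenated: CompositionStats

    def _per_gene_at(self) -> dict[str, float]:
        return {name: s.at_content for name, s in self.per_gene.items()}

    @property
    def mean_at_content(self) -> float:
        vals = list(self._per_gene_at().values())
        return sum(vals) / len(vals)

    @property
    def min_gene(self) -> tuple[str, float]:
        return min(self._per_gene_at().items(), key=lambda kv: kv[1])

    @property
    def max_gene(self) -> tuple[str, float]:
        return max(self._per_gene_at().items(), key=lambda kv: kv[1])


def pcg_composition_summary(genome: Mitogenome) -> PCGCompositionSummary:
    """Composition of each protein-coding gene on its coding sense."""
    pcgs = genome.features_of("PCG")
    if not pcgs:
        raise CompositionError("genome has no annotated PCGs")
    per_gene = {f.name: composition_stats(extract_feature_seq(genome, f)) for f in pcgs}
    concatenated = composition_stats(
        "".join(extract_feature_seq(genome, f) for f in pcgs)
    )
    return PCGCompositionSummary(per_gene=per_gene, concatenated=concatenated)


def region_composition_table(genome: Mitogenome) -> pd.DataFrame:
    """One row per region: whole genome, each feature, the PCG
    concatenation, and per-category concatenations.  Percentages to two
    decimals in the TSV writer; full precision in the DataFrame."""
    if genome.sequence is None:
        raise CompositionError("genome has no sequence")
    rows: list[tuple[str, CompositionStats]] = [
        ("genome", composition_stats(genome.sequence))
    ]
    for f in genome.features:
        rows.append((f.name, composition_stats(extract_feature_seq(genome, f))))
    for category, label in (
        ("PCG", "PCG-concatenated"),
        ("rRNA", "rRNA-concatenated"),
        ("tRNA", "tRNA-concatenated"),
        ("control", "control-region"),
    ):
        feats = genome.features_of(category)
        if feats:
            cat = "".join(extract_feature_seq(genome, f) for f in feats)
            rows.append((label, composition_stats(cat)))
    return pd.DataFrame(
        {
            "Region": [name for name, _ in rows],
            "Unambiguous": [s.total for _, s in rows],
            "A": [s.a for _, s in rows],
            "C": [s.c for _, s in rows],
            "G": [s.g for _, s in rows],
            "T": [s.t for _, s in rows],
            "AT%": [s.at_content for _, s in rows],
            "GC%": [s.gc_content for _, s in rows],
            "AG%": [s.ag_content for _, s in rows],
            "AT-skew": [s.at_skew for _, s in rows],
            "GC-skew": [s.gc_skew for _, s in rows],
        }
    )


def write_composition_tsv(genome: Mitogenome, path: str | Path, header_comment: str = "") -> None:
    df = region_composition_table(genome).copy()
    for col in ("AT%", "GC%", "AG%"):
        df[col] = df[col].map(lambda v: f"{v:.2f}")
    for col in ("AT-skew", "GC-skew"):
        df[col] = df[col].map(lambda v: f"{v:.4f}")
    text = "".join(f"# {l}\n" for l in header_comment.splitlines() if header_comment)
    Path(path).write_text(text + df.to_csv(sep="\t", index=False))
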
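"""Reading and writing annotated mitochondrial genomes.

Coordinate convention, used everywhere in this package: 1-based, inclusive
on both ends, on the forward (heavy, "H") strand of the circular molecule.
Converters to 0-based half-open slices exist only at format boundaries.
Features that would wrap the circular origin are rejected: in the genomes
this package targets (vertebrate mitogenomes annotated so that position 1
is the start of tRNA-Phe) no feature spans the origin.

Three interchange formats are supported:

* GenBank flat files (sequence + features),
* FASTA (sequence only),
* a simple tab-delimited feature table (documented in
  :func:`read_feature_tsv`) that can carry annotations without a sequence,
  so coordinate-only analyses can run on a transcribed published table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

Category = Literal["PCG", "tRNA", "rRNA", "control"]
Strand = Literal["H", "L"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

CATEGORIES: tuple[Category, ...] = ("PCG", "tRNA", "rRNA", "control")


class MitoIOError(ValueError):
    """Raised for malformed input files or inconsistent annotations."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature in genome coordinates.

    ``strand`` is "H" (heavy; forward) or "L" (light; the feature's coding
    sense is the reverse complement).  ``anticodon`` is the 3-nt DNA
    anticodon, present exactly for tRNA features.
    """

    name: str
    category: Category
    strand: Strand
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    anticodon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise MitoIOError(f"{self.name}: unknown category {self.category!r}")
        if self.strand not in ("H", "L"):
            raise MitoIOError(f"{self.name}: strand must be 'H' or 'L'")
        if not (1 <= self.start <= self.end):
            raise MitoIOError(
                f"{self.name}: require 1 <= start <= end, got {self.start}..{self.end}"
                " (features wrapping the circular origin are not supported)"
            )
        if (self.category == "tRNA") != (self.anticodon is not None):
            raise MitoIOError(
                f"{self.name}: anticodon must be present exactly for tRNA features"
            )
        if self.anticodon is not None and (
            len(self.anticodon) != 3 or any(c not in "ACGT" for c in self.anticodon)
        ):
            raise MitoIOError(f"{self.name}: bad anticodon {self.anticodon!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Mitogenome:
    """A (possibly sequence-free) annotated mitochondrial genome.

    ``sequence`` may be ``None`` for coordinate-only work; ``length`` must
    then be supplied if any bound checking is wanted.  Features are kept
    sorted by start coordinate.
    """

    sequence: Optional[str]
    features: list[GeneFeature] = field(default_factory=list)
    topology: Literal["circular", "linear"] = "circular"
    length: Optional[int] = None
    name: str = "mitogenome"

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) == 0:
                raise MitoIOError("empty sequence")
            bad = set(self.sequence) - set("ACGTN")
            if bad:
                raise MitoIOError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
            if self.length is None:
                self.length = len(self.sequence)
            elif self.length != len(self.sequence):
                raise MitoIOError("declared length disagrees with sequence length")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        if self.length is not None:
            for f in self.features:
                if f.end > self.length:
                    raise MitoIOError(
                        f"{f.name}: end {f.end} beyond genome length {self.length}"
                    )

    def features_of(self, category: Category) -> list[GeneFeature]:
        return [f for f in self.features if f.category == category]

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


def extract_feature_seq(genome: Mitogenome, feature: GeneFeature) -> str:
    """Coding-sense nucleotide sequence of ``feature``.

    The substring [start, end] (1-based inclusive), reverse-complemented
    for L-strand features.  Length always equals ``end - start + 1``.
    """
    if genome.sequence is None:
        raise MitoIOError("genome has no sequence; cannot extract feature sequence")
    sub = genome.sequence[feature.start - 1 : feature.end]
    return reverse_complement(sub) if feature.strand == "L" else sub


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_GB_TYPE_TO_CATEGORY = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "control"}
_CATEGORY_TO_GB_TYPE = {v: k for k, v in _GB_TYPE_TO_CATEGORY.items()}


def _feature_name(gb_feature: SeqFeature) -> str:
    for key in ("gene", "product", "note"):
        if key in gb_feature.qualifiers:
            return str(gb_feature.qualifiers[key][0])
    return gb_feature.type


def _feature_anticodon(gb_feature: SeqFeature) -> Optional[str]:
    # accept either our own "anticodon:XXX" note or an INSDC-style
    # /anticodon=(pos:..,aa:..,seq:xxx) qualifier
    for note in gb_feature.qualifiers.get("note", []):
        if note.startswith("anticodon:"):
            return note.split(":", 1)[1].strip().upper()
    for q in gb_feature.qualifiers.get("anticodon", []):
        if "seq:" in q:
            return q.split("seq:")[1].strip(") ").upper().replace("U", "T")
    return None


def read_genbank(path: str | Path) -> Mitogenome:
    """Read a GenBank flat file into a :class:`Mitogenome`.

    CDS features map to PCG, tRNA/rRNA keep their type, and D-loop
    features map to the control region.  L-strand iff the feature is
    annotated on the complement.  Other feature types (``source``,
    ``gene`` wrappers, ...) are ignored.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError with context
        raise MitoIOError(f"cannot parse GenBank file {path}: {exc}") from exc
    if len(record.seq) == 0:
        raise MitoIOError(f"{path}: record has no ORIGIN sequence")
    features: list[GeneFeature] = []
    for gbf in record.features:
        category = _GB_TYPE_TO_CATEGORY.get(gbf.type)
        if category is None:
            continue
        loc = gbf.location
        if loc is None or len(loc.parts) != 1:
            raise MitoIOError(
                f"{path}: feature {_feature_name(gbf)} has a compound location "
                "(origin-spanning features are not supported)"
            )
        start = int(loc.start) + 1  # 0-based half-open -> 1-based inclusive
        end = int(loc.end)
        strand: Strand = "L" if loc.strand == -1 else "H"
        anticodon = _feature_anticodon(gbf) if category == "tRNA" else None
        if category == "tRNA" and anticodon is None:
            raise MitoIOError(
                f"{path}: tRNA feature {_feature_name(gbf)} lacks an anticodon"
            )
        features.append(
            GeneFeature(_feature_name(gbf), category, strand, start, end, anticodon)
        )
    topology = record.annotations.get("topology", "circular")
    return Mitogenome(
        sequence=str(record.seq),
        features=features,
        topology="circular" if topology == "circular" else "linear",
        name=record.id if record.id != "<unknown id>" else record.name,
    )


def write_genbank(genome: Mitogenome, path: str | Path) -> None:
    if genome.sequence is None:
        raise MitoIOError("cannot write a sequence-free genome to GenBank")
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.name,
        name=genome.name[:16].replace(" ", "_"),
        description="mitochondrial genome",
        annotations={
            "molecule_type": "DNA",
            "topology": genome.topology,
            "organelle": "mitochondrion",
        },
    )
    for f in genome.features:
        loc = FeatureLocation(f.start - 1, f.end, strand=-1 if f.strand == "L" else 1)
        qualifiers: dict[str, list[str]] = {"gene": [f.name]}
        if f.anticodon is not None:
            qualifiers["note"] = [f"anticodon:{f.anticodon}"]
        record.features.append(
            SeqFeature(loc, type=_CATEGORY_TO_GB_TYPE[f.category], qualifiers=qualifiers)
        )
    SeqIO.write([record], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Mitogenome:
    """Read a single-record FASTA as an unannotated circular genome."""
    record = SeqIO.read(str(path), "fasta")
    return Mitogenome(sequence=str(record.seq), name=record.id)


def write_fasta(genome: Mitogenome, path: str | Path) -> None:
    if genome.sequence is None:
        raise MitoIOError("cannot write a sequence-free genome to FASTA")
    SeqIO.write(
        [SeqRecord(Seq(genome.sequence), id=genome.name, description="")],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# Feature TSV
# ---------------------------------------------------------------------------

TSV_COLUMNS = ("Gene", "Category", "Strand", "Start", "End", "Anticodon")
_OPTIONAL_TSV_COLUMNS = ("StartCodon", "StopCodon")


def read_feature_tsv(
    path: str | Path, genome: Optional[Mitogenome] = None
) -> Mitogenome:
    """Read a tab-delimited feature table.

    Required columns: Gene, Category, Strand, Start, End, Anticodon
    ("-" where not applicable).  Lines starting with ``#`` are comments.
    Optional StartCodon/StopCodon columns are tolerated (they are template
    metadata for the synthetic generator, not annotations).

    If ``genome`` is given, its sequence is attached to the returned
    object; otherwise the result is sequence-free, which is enough for
    every coordinate-only computation (sizes, continuity, aggregates).
    Rows are re-sorted by start coordinate regardless of file order.
    """
    path = Path(path)
    features: list[GeneFeature] = []
    seen: set[str] = set()
    header: Optional[list[str]] = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.rstrip("\n").split("\t")
        if header is None:
            header = [c.strip() for c in cells]
            missing = [c for c in TSV_COLUMNS if c not in header]
            if missing:
                raise MitoIOError(f"{path}:{lineno}: missing columns {missing}")
            continue
        row = dict(zip(header, (c.strip() for c in cells)))
        name = row["Gene"]
        if name in seen:
            raise MitoIOError(f"{path}:{lineno}: duplicate feature name {name!r}")
        seen.add(name)
        try:
            start, end = int(row["Start"]), int(row["End"])
        except ValueError as exc:
            raise MitoIOError(f"{path}:{lineno}: non-numeric coordinates") from exc
        anticodon = row["Anticodon"] if row["Anticodon"] not in ("-", "") else None
        features.append(
            GeneFeature(name, row["Category"], row["Strand"], start, end, anticodon)
        )
    if header is None:
        raise MitoIOError(f"{path}: no header line found")
    return Mitogenome(
        sequence=genome.sequence if genome is not None else None,
        features=features,
        length=max((f.end for f in features), default=None)
        if genome is None
        else None,
        name=path.stem,
    )


def write_feature_tsv(genome: Mitogenome, path: str | Path, header_comment: str = "") -> None:
    lines = []
    if header_comment:
        lines.extend(f"# {l}" for l in header_comment.splitlines())
    lines.append("\t".join(TSV_COLUMNS))
    for f in genome.features:
        lines.append(
            "\t".join(
                (f.name, f.category, f.strand, str(f.start), str(f.end), f.anticodon or "-")
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_bcaspica_features() -> Mitogenome:
    """The published feature annotation of the Barbastella caspica
    mitogenome (GenBank PP963575), bundled as a sequence-free fixture."""
    ref = importlib.resources.files("chiromito.data") / "bcaspica_mtdna_features.tsv"
    with importlib.resources.as_file(ref) as path:
        genome = read_feature_tsv(path)
    genome.name = "PP963575"
    return genome
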
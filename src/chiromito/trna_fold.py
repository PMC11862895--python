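"""Cloverleaf secondary-structure assignment for mitochondrial tRNAs.

The canonical tRNA cloverleaf has four arms in fixed 5'->3' order:
acceptor stem (the paired 5'/3' termini), D arm, anticodon arm, and T arm.
Mitochondrial tRNAs are degenerate versions of this template — notably
tRNA-Ser(AGY), whose D arm is replaced by a short loop — so this module
performs a deterministic, anchored template search rather than
free-energy minimisation:

* the anticodon loop (7 nt, anticodon at loop positions 3-5) is anchored
  at an occurrence of the annotated anticodon;
* the anticodon stem is extended greedily outward (target 5 bp, >= 4
  required, no mismatches);
* the 5'/3' termini are paired into the acceptor stem (7 bp, >= 6
  matches required, <= 1 mismatch, with 0 or 1 unpaired discriminator
  nucleotide at the 3' end);
* the D arm (stem 3-4 bp, loop 4-12 nt) is searched in the 5' flank,
  anchored 1-2 nt before the anticodon stem with a 1-3 nt spacer after
  the acceptor strand;
* the T arm (stem 4-5 bp, loop 5-9 nt) is searched in the 3' flank,
  ending 0-1 nt before the acceptor 3' strand.

Arms searched but not found are reported absent; ``is_canonical`` is true
iff all four arms are present.  Allowed pairs are Watson-Crick plus the
G·U wobble.  The search order prefers the canonical geometry (spacer
sizes 2/1, stems 7/4/5/5, T loop 7), so structures built by
:func:`make_trna` are recovered exactly at their planted positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .mito_io import Mitogenome, extract_feature_seq

_PAIRS = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")})
_WC = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")})

MIN_LEN, MAX_LEN = 55, 95


class TrnaFoldError(ValueError):
    pass


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


@dataclass(frozen=True)
class Arm:
    """One paired region: 5' strand [five_start, five_end], loop, and 3'
    strand [three_start, three_end]; all positions 0-based inclusive on
    the tRNA sequence.  ``pairs`` lists the paired positions outermost
    first; mismatched positions (acceptor only) are omitted from it."""

    name: str
    five_start: int
    five_end: int
    three_start: int
    three_end: int
    pairs: tuple[tuple[int, int], ...]

    @property
    def stem_len(self) -> int:
        return self.five_end - self.five_start + 1

    @property
    def loop_len(self) -> int:
        return self.three_start - self.five_end - 1


@dataclass
class CloverleafStructure:
    sequence: str  # DNA, coding sense
    anticodon: str
    anticodon_pos: int  # 0-based start of the anticodon
    acceptor_stem: Optional[Arm]
    d_arm: Optional[Arm]
    anticodon_arm: Optional[Arm]
    t_arm: Optional[Arm]

    @property
    def is_canonical(self) -> bool:
        return all(
            a is not None
            for a in (self.acceptor_stem, self.d_arm, self.anticodon_arm, self.t_arm)
        )

    @property
    def arms(self) -> list[Arm]:
        return [
            a
            for a in (self.acceptor_stem, self.d_arm, self.anticodon_arm, self.t_arm)
            if a is not None
        ]

    @property
    def pairs(self) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        for arm in self.arms:
            out.extend(arm.pairs)
        return sorted(out)

    def dot_bracket(self) -> str:
        chars = ["."] * len(self.sequence)
        for i, j in self.pairs:
            chars[i], chars[j] = "(", ")"
        return "".join(chars)


def _stem_pairs(seq: str, f0: int, t1: int, n: int) -> Optional[tuple[tuple[int, int], ...]]:
    """Pairs (f0+m, t1-m) for m in 0..n-1 if every one is complementary."""
    pairs = []
    for m in range(n):
        if not _can_pair(seq[f0 + m], seq[t1 - m]):
            return None
        pairs.append((f0 + m, t1 - m))
    return tuple(pairs)


def _find_acceptor(seq: str) -> Optional[Arm]:
    n = len(seq)
    best: Optional[tuple[int, int, Arm]] = None
    for disc in (1, 0):  # unpaired 3' discriminator nt, tried first
        t_end = n - 1 - disc
        pairs, wc = [], 0
        for m in range(7):
            a, b = seq[m], seq[t_end - m]
            if _can_pair(a, b):
                pairs.append((m, t_end - m))
                wc += (a, b) in _WC
        if len(pairs) >= 6:
            arm = Arm("acceptor", 0, 6, t_end - 6, t_end, tuple(pairs))
            key = (len(pairs), wc)
            if best is None or key > best[:2]:
                best = (len(pairs), wc, arm)
    return best[2] if best else None


def _find_d_arm(seq: str, ac_five_start: int) -> Optional[Arm]:
    for spacer in (1, 2):  # nt between D arm and anticodon stem
        d3_end = ac_five_start - spacer - 1
        for stem in (4, 3):
            for d5_start in (9, 8, 10):  # 2 nt after the acceptor strand first
                loop = d3_end - stem - d5_start - stem + 1
                if not 4 <= loop <= 12:
                    continue
                pairs = _stem_pairs(seq, d5_start, d3_end, stem)
                if pairs is not None:
                    return Arm(
                        "D", d5_start, d5_start + stem - 1, d3_end - stem + 1, d3_end, pairs
                    )
    return None


def _find_t_arm(seq: str, ac_three_end: int, acc_three_start: int) -> Optional[Arm]:
    for gap in (0, 1):  # nt between T arm and acceptor 3' strand
        t3_end = acc_three_start - 1 - gap
        for stem in (5, 4):
            for loop in (7, 6, 8, 5, 9):
                t5_start = t3_end - stem - loop - stem + 1
                # leave a variable loop of >= 3 nt after the anticodon arm
                if t5_start < ac_three_end + 4:
                    continue
                pairs = _stem_pairs(seq, t5_start, t3_end, stem)
                if pairs is not None:
                    return Arm(
                        "T", t5_start, t5_start + stem - 1, t3_end - stem + 1, t3_end, pairs
                    )
    return None


def _fold_at(seq: str, pos: int) -> Optional[CloverleafStructure]:
    """Attempt a cloverleaf with the anticodon at 0-based ``pos``."""
    n = len(seq)
    loop_start, loop_end = pos - 2, pos + 4  # 7-nt anticodon loop
    if loop_start - 5 < 7 or loop_end + 5 > n - 8:
        return None
    stem = 0
    pairs = []
    while stem < 5 and _can_pair(seq[loop_start - 1 - stem], seq[loop_end + 1 + stem]):
        pairs.append((loop_start - 1 - stem, loop_end + 1 + stem))
        stem += 1
    if stem < 4:
        return None
    anticodon_arm = Arm(
        "anticodon",
        loop_start - stem,
        loop_start - 1,
        loop_end + 1,
        loop_end + stem,
        tuple(reversed(pairs)),
    )
    acceptor = _find_acceptor(seq)
    d_arm = _find_d_arm(seq, anticodon_arm.five_start)
    t_arm = (
        _find_t_arm(seq, anticodon_arm.three_end, acceptor.three_start)
        if acceptor is not None
        else None
    )
    return CloverleafStructure(
        sequence=seq,
        anticodon=seq[pos : pos + 3],
        anticodon_pos=pos,
        acceptor_stem=acceptor,
        d_arm=d_arm,
        anticodon_arm=anticodon_arm,
        t_arm=t_arm,
    )


def fold_cloverleaf(seq: str, anticodon: str) -> CloverleafStructure:
    """Assign a cloverleaf structure to one tRNA sequence.

    ``seq`` is the coding-sense DNA sequence; ``anticodon`` the annotated
    3-nt DNA anticodon.  When the anticodon occurs more than once the
    occurrence yielding the most paired bases wins; ties go to the
    5'-most occurrence.
    """
    seq = seq.upper().replace("U", "T")
    anticodon = anticodon.upper().replace("U", "T")
    if not MIN_LEN <= len(seq) <= MAX_LEN:
        raise TrnaFoldError(
            f"length {len(seq)} outside the tRNA range [{MIN_LEN}, {MAX_LEN}]"
        )
    occurrences = [i for i in range(len(seq) - 2) if seq[i : i + 3] == anticodon]
    if not occurrences:
        raise TrnaFoldError(f"anticodon {anticodon} does not occur in the sequence")
    candidates = [(pos, _fold_at(seq, pos)) for pos in occurrences]
    scored = [
        (sum(len(a.pairs) for a in s.arms), -pos, s)
        for pos, s in candidates
        if s is not None
    ]
    if not scored:
        # no occurrence supports even an anticodon stem: report a bare,
        # non-canonical structure anchored at the 5'-most occurrence
        pos = occurrences[0]
        acceptor = _find_acceptor(seq)
        return CloverleafStructure(seq, anticodon, pos, acceptor, None, None, None)
    return max(scored)[2]


@dataclass
class FoldSummary:
    structures: dict[str, CloverleafStructure]
    skipped: list[str] = field(default_factory=list)

    @property
    def n_canonical(self) -> int:
        return sum(1 for s in self.structures.values() if s.is_canonical)

    @property
    def non_canonical(self) -> list[str]:
        return [name for name, s in self.structures.items() if not s.is_canonical]


def fold_all(genome: Mitogenome) -> FoldSummary:
    """Fold every annotated tRNA on its coding sense."""
    structures: dict[str, CloverleafStructure] = {}
    skipped: list[str] = []
    for f in genome.features_of("tRNA"):
        if f.anticodon is None:  # defensive; the type normally forbids this
            skipped.append(f.name)
            continue
        structures[f.name] = fold_cloverleaf(extract_feature_seq(genome, f), f.anticodon)
    return FoldSummary(structures=structures, skipped=skipped)


def write_structure_tsv(summary: FoldSummary, path: str | Path, header_comment: str = "") -> None:
    lines = []
    if header_comment:
        lines.extend(f"# {l}" for l in header_comment.splitlines())
    lines.append(
        "tRNA\tlength\tcanonical\tacceptor_bp\td_bp\tanticodon_bp\tt_bp\tdot_bracket"
    )
    for name, s in summary.structures.items():
        def _bp(arm: Optional[Arm]) -> str:
            return str(len(arm.pairs)) if arm is not None else "-"

        lines.append(
            "\t".join(
                (
                    name,
                    str(len(s.sequence)),
                    "yes" if s.is_canonical else "no",
                    _bp(s.acceptor_stem),
                    _bp(s.d_arm),
                    _bp(s.anticodon_arm),
                    _bp(s.t_arm),
                    s.dot_bracket(),
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Arm-by-arm constructor (ground truth for folding tests and the synthetic
# genome generator)
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class TrnaTruth:
    """Planted structure of a constructed tRNA (same coordinates as the
    arms the folder reports)."""

    sequence: str
    anticodon: str
    anticodon_pos: int
    acceptor: Arm
    d_arm: Optional[Arm]
    anticodon_arm: Arm
    t_arm: Optional[Arm]

    @property
    def is_canonical(self) -> bool:
        return self.d_arm is not None and self.t_arm is not None


def _layout(length: int, with_d_arm: bool) -> tuple[int, int, int]:
    """Solve (d_loop_or_replacement, variable_loop, discriminator) sizes."""
    if with_d_arm:
        fixed = 7 + 2 + 8 + 1 + 17 + 17 + 7  # = 59; + dloop + var + disc
        for disc in (1, 0):
            for dloop in (8, 9, 7, 10, 6, 11, 5, 12, 4):
                var = length - fixed - disc - dloop
                if 3 <= var <= 23:
                    return dloop, var, disc
        raise TrnaFoldError(
            f"no canonical cloverleaf layout for length {length} (need >= {fixed + 7})"
        )
    fixed = 7 + 17 + 17 + 7  # = 48; + replacement + var + disc
    for disc in (1, 0):
        for rep in (5, 4, 6, 3, 7, 8, 9):
            var = length - fixed - disc - rep
            if 3 <= var <= 23:
                return rep, var, disc
    raise TrnaFoldError(f"no D-armless layout for length {length}")


def _rand(rng: np.random.Generator, n: int, p=None) -> str:
    return "".join(rng.choice(_BASES, size=n, p=p))


def make_trna(
    anticodon: str,
    length: int = 72,
    *,
    with_d_arm: bool = True,
    rng: Optional[np.random.Generator] = None,
    base_probs=None,
    fixed: Optional[dict[int, str]] = None,
    max_tries: int = 20000,
) -> TrnaTruth:
    """Construct a tRNA arm by arm with known (planted) structure.

    Stems are perfect Watson-Crick duplexes: acceptor 7 bp (+ optional
    discriminator nt), D stem 4 bp, anticodon stem 5 bp around a 7-nt
    loop with the anticodon at loop positions 3-5, T stem 5 bp with a
    7-nt loop.  Loop sizes are solved from ``length``.  With
    ``with_d_arm=False`` the D arm is replaced by a short loop, emulating
    the mitochondrial tRNA-Ser(AGY) geometry.

    ``fixed`` maps 0-based positions to required bases (used when a
    genomic tRNA overlaps a neighbouring feature); construction is
    redrawn until every fixed position matches, which stays deterministic
    for a given ``rng`` state.
    """
    if fixed:
        for _ in range(max_tries):
            truth = make_trna(
                anticodon,
                length,
                with_d_arm=with_d_arm,
                rng=rng,
                base_probs=base_probs,
                fixed=None,
            )
            if all(truth.sequence[i] == b for i, b in fixed.items()):
                return truth
        raise TrnaFoldError(
            f"could not satisfy {len(fixed)} fixed bases in {max_tries} draws"
        )
    rng = rng if rng is not None else np.random.default_rng(0)
    anticodon = anticodon.upper().replace("U", "T")
    if len(anticodon) != 3 or any(c not in "ACGT" for c in anticodon):
        raise TrnaFoldError(f"bad anticodon {anticodon!r}")
    dloop_or_rep, var, disc = _layout(length, with_d_arm)

    def stem(n: int) -> tuple[str, str]:
        five = _rand(rng, n, base_probs)
        three = "".join(_COMP[c] for c in reversed(five))
        return five, three

    acc5, acc3 = stem(7)
    ac5, ac3 = stem(5)
    t5, t3 = stem(5)
    ac_loop = _rand(rng, 2, base_probs) + anticodon + _rand(rng, 2, base_probs)
    parts: list[str] = [acc5]
    pos = 7
    d_arm: Optional[Arm] = None
    if with_d_arm:
        d5, d3 = stem(4)
        d_loop = _rand(rng, dloop_or_rep, base_probs)
        parts += [_rand(rng, 2, base_probs), d5, d_loop, d3]
        d_five_start = pos + 2
        d_arm = Arm(
            "D",
            d_five_start,
            d_five_start + 3,
            d_five_start + 4 + dloop_or_rep,
            d_five_start + 7 + dloop_or_rep,
            tuple(
                (d_five_start + m, d_five_start + 7 + dloop_or_rep - m) for m in range(4)
            ),
        )
        parts.append(_rand(rng, 1, base_probs))  # spacer before anticodon stem
        pos += 2 + 8 + dloop_or_rep + 1
    else:
        parts.append(_rand(rng, dloop_or_rep, base_probs))
        pos += dloop_or_rep
    ac_five_start = pos
    parts += [ac5, ac_loop, ac3]
    anticodon_arm = Arm(
        "anticodon",
        ac_five_start,
        ac_five_start + 4,
        ac_five_start + 12,
        ac_five_start + 16,
        tuple((ac_five_start + m, ac_five_start + 16 - m) for m in range(5)),
    )
    pos += 17
    parts.append(_rand(rng, var, base_probs))
    pos += var
    t_five_start = pos
    parts += [t5, _rand(rng, 7, base_probs), t3]
    t_arm = Arm(
        "T",
        t_five_start,
        t_five_start + 4,
        t_five_start + 12,
        t_five_start + 16,
        tuple((t_five_start + m, t_five_start + 16 - m) for m in range(5)),
    )
    pos += 17
    acc_three_start = pos
    parts.append(acc3)
    pos += 7
    if disc:
        parts.append(_rand(rng, 1, base_probs))
        pos += 1
    seq = "".join(parts)
    assert len(seq) == length == pos, (len(seq), length, pos)
    acceptor = Arm(
        "acceptor",
        0,
        6,
        acc_three_start,
        acc_three_start + 6,
        tuple((m, acc_three_start + 6 - m) for m in range(7)),
    )
    return TrnaTruth(
        sequence=seq,
        anticodon=anticodon,
        anticodon_pos=ac_five_start + 7,
        acceptor=acceptor,
        d_arm=d_arm,
        anticodon_arm=anticodon_arm,
        t_arm=t_arm,
    )
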
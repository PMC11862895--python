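"""Pairwise evolutionary distances and neighbor-joining trees.

Distances on aligned nucleotide marker genes (e.g. Cytb, ND1):

* **p-distance** — proportion of differing sites, with *pairwise deletion*:
  any site carrying a gap or ambiguity in either sequence of the pair is
  excluded from the comparison.
* **ML distance** — maximum-likelihood pairwise distance under JC69, K2P
  or TN93 (default TN93, the model family distance tables in the
  MEGA tradition use).  The likelihood of the observed site-pattern
  counts is maximised numerically over the time parameter using the
  model's analytic transition-probability matrix; for JC69 the estimate
  coincides with the closed form -(3/4) ln(1 - 4p/3).  Saturated pairs
  (divergence beyond the model's resolvable bound) are reported as
  ``inf`` rather than raising.

Trees are built by standard neighbor-joining; a negative branch length
produced by the agglomeration is clamped to zero and the deficit moved
onto its sister branch, preserving the path length between the joined
nodes.  Bootstrap support resamples alignment columns with replacement,
rebuilds the NJ tree per replicate, and annotates each internal split of
the point-estimate tree with the percentage of replicates containing it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
from Bio import SeqIO
from scipy.optimize import brentq, minimize_scalar

Model = Literal["JC69", "K2P", "TN93"]

_VALID = frozenset("ACGT")
_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_PURINES = frozenset("AG")


class DistanceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    taxa: list[str]
    rows: list[str]  # equal-length gapped nucleotide strings

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise DistanceError("taxa/rows length mismatch")
        if len(self.taxa) < 2:
            raise DistanceError("need >= 2 taxa")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise DistanceError(f"unequal row lengths: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.n_sites, size=self.n_sites)
        mat = np.array([list(r) for r in self.rows])
        return Alignment(list(self.taxa), ["".join(row) for row in mat[:, cols]])


# ---------------------------------------------------------------------------
# Pairwise distances
# ---------------------------------------------------------------------------

def _comparable(a: str, b: str) -> list[tuple[str, str]]:
    if len(a) != len(b):
        raise DistanceError("sequences have unequal lengths")
    return [(x, y) for x, y in zip(a.upper(), b.upper()) if x in _VALID and y in _VALID]

def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites under pairwise deletion."""
    sites = _comparable(a, b)
    if not sites:
        raise DistanceError("no comparable sites")
    return sum(x != y for x, y in sites) / len(sites)


def _pattern_counts(sites: Sequence[tuple[str, str]]) -> np.ndarray:
    counts = np.zeros((4, 4))
    for x, y in sites:
        counts[_IDX[x], _IDX[y]] += 1
    return counts


def _p_matrix_jc(t: float) -> np.ndarray:
    e = np.exp(-4.0 * t / 3.0)
    off = 0.25 - 0.25 * e
    p = np.full((4, 4), off)
    np.fill_diagonal(p, 0.25 + 0.75 * e)
    return p


def _p_matrix_k2p(t: float, kappa: float) -> np.ndarray:
    # rate matrix with transversion rate beta, transition rate kappa*beta,
    # scaled so the per-site rate kappa*beta + 2*beta equals 1
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e4 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    same = 0.25 + 0.25 * e4 + 0.5 * e2
    transition = 0.25 + 0.25 * e4 - 0.5 * e2
    transversion = 0.25 - 0.25 * e4
    p = np.full((4, 4), transversion)
    pairs = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    for x, i in _IDX.items():
        p[i, i] = same
        for y, j in _IDX.items():
            if (x, y) in pairs:
                p[i, j] = transition
    return p


def _p_matrix_tn93(t: float, freqs: np.ndarray, a1: float, a2: float, b: float) -> np.ndarray:
    """TN93 transition probabilities via its spectral form.

    ``a1``/``a2`` are the purine/pyrimidine transition rate parameters,
    ``b`` the transversion rate; ``freqs`` the stationary frequencies
    (A, C, G, T)."""
    pa, pc, pg, pt = freqs
    pr, py = pa + pg, pc + pt
    p = np.zeros((4, 4))
    ebt = np.exp(-b * t)
    e1 = np.exp(-(pr * a1 + py * b) * t)
    e2 = np.exp(-(py * a2 + pr * b) * t)
    for x, i in _IDX.items():
        for y, j in _IDX.items():
            pj = freqs[j]
            if x in _PURINES and y in _PURINES:
                if i == j:
                    p[i, j] = pj + pj * (1.0 / pr - 1.0) * ebt + ((pr - pj) / pr) * e1
                else:
                    p[i, j] = pj + pj * (1.0 / pr - 1.0) * ebt - (pj / pr) * e1
            elif x not in _PURINES and y not in _PURINES:
                if i == j:
                    p[i, j] = pj + pj * (1.0 / py - 1.0) * ebt + ((py - pj) / py) * e2
                else:
                    p[i, j] = pj + pj * (1.0 / py - 1.0) * ebt - (pj / py) * e2
            else:
                p[i, j] = pj * (1.0 - ebt)
    return p


def _tn93_scale(freqs: np.ndarray, a1: float, a2: float, b: float) -> float:
    """Expected substitution rate of the TN93 generator (for unit scaling)."""
    pa, pc, pg, pt = freqs
    return 2.0 * (pa * pg * a1 + pc * pt * a2 + (pa + pg) * (pc + pt) * b)


def _neg_loglik(counts: np.ndarray, pmat: np.ndarray, freqs: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        logp = np.log(np.maximum(pmat * freqs[:, None], 1e-300))
    return -float((counts * logp).sum())


_SATURATION_T = 50.0  # substitutions/site; beyond this the pair is saturated


def _polish_t(counts: np.ndarray, freqs: np.ndarray, pfun, t0: float) -> float:
    """Refine a likelihood optimum by locating the zero of the score
    function (scalar optimisers stop near sqrt(machine eps); the score
    root is sharp to ~1e-12).  ``pfun(t)`` is the transition matrix."""

    def score(t: float) -> float:
        h = 1e-6 * max(t, 1e-3)
        dp = (pfun(t + h) - pfun(t - h)) / (2.0 * h)
        p = np.maximum(pfun(t), 1e-300)
        return float((counts * (dp / p)).sum())

    lo, hi = t0 * 0.9, t0 * 1.1
    for _ in range(40):
        try:
            s_lo, s_hi = score(lo), score(hi)
        except FloatingPointError:
            return t0
        if s_lo > 0 > s_hi:
            return float(brentq(score, lo, hi, xtol=1e-13, rtol=1e-14))
        lo, hi = lo * 0.8, hi * 1.25
        if hi > _SATURATION_T:
            return t0
    return t0


def ml_distance(a: str, b: str, model: Model = "TN93") -> float:
    """Maximum-likelihood pairwise distance in substitutions/site.

    The time parameter of the chosen model is fitted by numerical
    likelihood maximisation on the pairwise site-pattern counts; rate
    parameters (K2P kappa, TN93 alpha1/alpha2/beta) are profiled out by
    joint optimisation on a coarse-to-fine grid.  Returns ``inf`` when
    the pair is saturated under the model.
    """
    sites = _comparable(a, b)
    if not sites:
        raise DistanceError("no comparable sites")
    counts = _pattern_counts(sites)
    n = counts.sum()
    p = float((counts.sum() - np.trace(counts)) / n)
    if p == 0.0:
        return 0.0
    uniform = np.full(4, 0.25)
    if model == "JC69":
        if p >= 0.75:
            return float("inf")
        obj = lambda t: _neg_loglik(counts, _p_matrix_jc(t), uniform)
        res = minimize_scalar(obj, bounds=(1e-9, _SATURATION_T), method="bounded",
                              options={"xatol": 1e-12})
        t = _polish_t(counts, uniform, _p_matrix_jc, float(res.x))
        return t if t < _SATURATION_T * 0.99 else float("inf")
    if model == "K2P":
        best = (np.inf, np.inf, 1.0)
        for kappa in np.geomspace(0.05, 1e6, 80):
            obj = lambda t: _neg_loglik(counts, _p_matrix_k2p(t, kappa), uniform)
            res = minimize_scalar(obj, bounds=(1e-9, _SATURATION_T), method="bounded",
                                  options={"xatol": 1e-12})
            if res.fun < best[0]:
                best = (res.fun, float(res.x), kappa)
        # refine kappa locally
        k0 = best[2]
        for kappa in np.geomspace(k0 / 1.5, k0 * 1.5, 33):
            obj = lambda t: _neg_loglik(counts, _p_matrix_k2p(t, kappa), uniform)
            res = minimize_scalar(obj, bounds=(1e-9, _SATURATION_T), method="bounded",
                                  options={"xatol": 1e-12})
            if res.fun < best[0]:
                best = (res.fun, float(res.x), kappa)
        kbest = best[2]
        t = _polish_t(counts, uniform, lambda t: _p_matrix_k2p(t, kbest), best[1])
        return t if t < _SATURATION_T * 0.99 else float("inf")
    if model == "TN93":
        freqs = counts.sum(axis=0) + counts.sum(axis=1)
        freqs = freqs / freqs.sum()
        if np.any(freqs == 0):
            freqs = (freqs + 1e-6) / (freqs + 1e-6).sum()

        def fit(a1: float, a2: float) -> tuple[float, float]:
            b = 1.0  # fixed; t carries the scale
            scale = _tn93_scale(freqs, a1, a2, b)
            obj = lambda t: _neg_loglik(
                counts, _p_matrix_tn93(t / scale, freqs, a1, a2, b), freqs
            )
            res = minimize_scalar(obj, bounds=(1e-9, _SATURATION_T), method="bounded",
                                  options={"xatol": 1e-12})
            return float(res.fun), float(res.x)

        grid = np.geomspace(0.2, 40, 12)
        best = (np.inf, np.inf, 1.0, 1.0)
        for a1 in grid:
            for a2 in grid:
                f, t = fit(a1, a2)
                if f < best[0]:
                    best = (f, t, a1, a2)
        # local refinement around the best grid point
        a1_0, a2_0 = best[2], best[3]
        for a1 in np.geomspace(a1_0 / 1.6, a1_0 * 1.6, 9):
            for a2 in np.geomspace(a2_0 / 1.6, a2_0 * 1.6, 9):
                f, t = fit(a1, a2)
                if f < best[0]:
                    best = (f, t, a1, a2)
        a1b, a2b = best[2], best[3]
        scale = _tn93_scale(freqs, a1b, a2b, 1.0)
        t = _polish_t(
            counts, freqs, lambda t: _p_matrix_tn93(t / scale, freqs, a1b, a2b, 1.0), best[1]
        )
        return t if t < _SATURATION_T * 0.99 else float("inf")
    raise DistanceError(f"unknown model {model!r}")


def jc69_closed_form(p: float) -> float:
    """Analytic JC69 distance -(3/4) ln(1 - 4p/3)."""
    if p >= 0.75:
        return float("inf")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def k2p_closed_form(P: float, Q: float) -> float:
    """Analytic K2P distance from transition (P) and transversion (Q)
    proportions: -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)."""
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return float("inf")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray  # symmetric, zero diagonal
    method: str  # "p" or "ML(<model>)"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise DistanceError("matrix shape does not match taxa")
        if not np.allclose(np.diag(self.values), 0.0):
            raise DistanceError("nonzero diagonal")
        finite = np.isfinite(self.values)
        if not np.allclose(self.values[finite], self.values.T[finite & finite.T]):
            raise DistanceError("matrix is not symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.taxa.index(pair[0]), self.taxa.index(pair[1])
        return float(self.values[i, j])

    def to_phylip(self) -> str:
        out = io.StringIO()
        out.write(f"{len(self.taxa)}\n")
        for name, row in zip(self.taxa, self.values):
            out.write(name.ljust(12) + " ".join(f"{v:.6f}" for v in row) + "\n")
        return out.getvalue()


def distance_matrix(aln: Alignment, method: str = "p", model: Model = "TN93") -> DistanceMatrix:
    n = len(aln.taxa)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if method == "p":
                d = p_distance(aln.rows[i], aln.rows[j])
            elif method == "ML":
                d = ml_distance(aln.rows[i], aln.rows[j], model=model)
            else:
                raise DistanceError(f"unknown method {method!r}")
            values[i, j] = values[j, i] = d
    label = "p" if method == "p" else f"ML({model})"
    return DistanceMatrix(list(aln.taxa), values, label)


def dual_triangle_table(
    upper: DistanceMatrix, lower: DistanceMatrix, percent: bool = True
) -> str:
    """Publication-style table: ``upper`` above the diagonal, ``lower``
    below, one triangle per method (or per gene), values optionally in %."""
    if upper.taxa != lower.taxa:
        raise DistanceError("matrices are over different taxa")
    scale = 100.0 if percent else 1.0
    lines = [
        "# upper triangle: %s; lower triangle: %s%s"
        % (upper.method, lower.method, " (in %)" if percent else "")
    ]
    lines.append("\t" + "\t".join(upper.taxa))
    for i, name in enumerate(upper.taxa):
        cells = []
        for j in range(len(upper.taxa)):
            if i == j:
                cells.append("-")
            elif j > i:
                cells.append(f"{upper.values[i, j] * scale:.1f}")
            else:
                cells.append(f"{lower.values[i, j] * scale:.1f}")
        lines.append(name + "\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: Optional[float] = None

    def leaves(self) -> frozenset[str]:
        if not self.children:
            return frozenset([self.name])  # type: ignore[list-item]
        out: frozenset[str] = frozenset()
        for child, _ in self.children:
            out |= child.leaves()
        return out

    def newick(self, with_support: bool = False) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, with_support: bool) -> str:
        if not self.children:
            return self.name or ""
        inner = ",".join(
            f"{child._newick(with_support)}:{length:.6f}"
            for child, length in self.children
        )
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:.0f}"
        return f"({inner}){label}"

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions (as the smaller-side-free leaf set of
        each internal edge), on an unrooted reading of the tree."""
        all_leaves = self.leaves()
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> None:
            for child, _ in node.children:
                clade = child.leaves()
                if 1 < len(clade) < len(all_leaves) - 1:
                    out.add(min(clade, all_leaves - clade, key=sorted))
                walk(child)

        walk(self)
        return out


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining (Saitou & Nei agglomeration).

    Negative branch lengths are clamped to 0 and the deficit moved to the
    sister branch, keeping the joined pair's path length intact.  The
    result is an unrooted tree serialised with a trifurcating root.
    """
    n = len(dm.taxa)
    if n < 3:
        raise DistanceError("need >= 3 taxa for a tree")
    if not np.all(np.isfinite(dm.values)):
        raise DistanceError("cannot build a tree from saturated (infinite) distances")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    d = dm.values.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        ai, aj = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit onto the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[(nodes[ai], li), (nodes[aj], lj)])
        new_d = 0.5 * (d[ai, :] + d[aj, :] - dij)
        d = np.vstack([d, new_d])
        d = np.hstack([d, np.append(new_d, 0.0)[:, None]])
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]
    # join the last three around a trifurcating root
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    return TreeNode(
        children=[
            (nodes[a], max(la, 0.0)),
            (nodes[b], max(lb, 0.0)),
            (nodes[c], max(lc, 0.0)),
        ]
    )


def bootstrap_support(
    aln: Alignment,
    method: str = "p",
    model: Model = "TN93",
    n_reps: int = 100,
    seed: int = 0,
) -> TreeNode:
    """NJ tree with bootstrap split support (percent) on internal nodes."""
    if n_reps < 1:
        raise DistanceError("n_reps must be >= 1")
    point = nj_tree(distance_matrix(aln, method=method, model=model))
    target = point.splits()
    tally = {s: 0 for s in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep = aln.resample_columns(rng)
        try:
            rep_splits = nj_tree(distance_matrix(aln=rep, method=method, model=model)).splits()
        except DistanceError:
            continue  # saturated replicate carries no split information
        for s in target:
            if s in rep_splits:
                tally[s] += 1

    def annotate(node: TreeNode, all_leaves: frozenset[str]) -> None:
        for child, _ in node.children:
            clade = child.leaves()
            if 1 < len(clade) < len(all_leaves) - 1:
                key = min(clade, all_leaves - clade, key=sorted)
                child.support = 100.0 * tally[key] / n_reps
            annotate(child, all_leaves)

    annotate(point, point.leaves())
    return point
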
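"""Distance and likelihood phylogenetics for duplicate-locus quartets.

The claim this package exists to reproduce is a *topology flip*: a tree
built from the unconverted 5' partition of the duplicated genes groups
orthologues together, while the converted 3' partition groups the
within-species paralogues.  That claim is model-robust, so the toolkit
here is deliberately small: p/JC69/K2P distances, neighbor-joining for
arbitrary taxon sets, exact JC69 maximum likelihood over the three
unrooted quartet topologies (Felsenstein pruning with per-branch
coordinate ascent), and nonparametric bootstrap over columns.

Quartet rows are always in fixed role order (species A paralogue a, A-b,
B-a, B-b), so the three unrooted topologies have fixed meanings:
``orthologue_sister`` = ((Aa,Ba),(Ab,Bb)), ``paralogue_sister`` =
((Aa,Ab),(Ba,Bb)), ``mixed`` = ((Aa,Bb),(Ab,Ba)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "DistanceMatrix",
    "Tree",
    "QuartetTopologyCall",
    "SaturationError",
    "TOPOLOGY_NAMES",
    "pairwise_distance",
    "distance_matrix",
    "nj_tree",
    "quartet_ml",
    "bootstrap_support",
]

GAP = "-"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_PURINES = {"A", "G"}

#: Quartet topology names keyed by the partner of row 0 (see module docstring).
TOPOLOGY_NAMES = {1: "paralogue_sister", 2: "orthologue_sister", 3: "mixed"}

BRANCH_MIN, BRANCH_MAX = 1e-8, 10.0


class SaturationError(ValueError):
    """Distance correction undefined: observed divergence beyond model range."""


def _compared_columns(x: str, y: str) -> list[tuple[str, str]]:
    pairs = []
    for cx, cy in zip(x.upper(), y.upper()):
        if cx in _BASE_INDEX and cy in _BASE_INDEX:
            pairs.append((cx, cy))
    return pairs


def pairwise_distance(
    seq_x: str, seq_y: str, model: Literal["p_distance", "jc69", "k2p"] = "jc69"
) -> float:
    """Pairwise distance between two aligned sequences.

    Columns with a gap or ambiguity in either sequence are excluded.
    ``p_distance`` is the mismatch proportion; ``jc69`` applies
    d = -(3/4) ln(1 - 4p/3); ``k2p`` corrects transitions and
    transversions separately.  Divergence beyond the model's valid range
    raises :class:`SaturationError`.
    """
    if len(seq_x) != len(seq_y):
        raise ValueError("aligned sequences differ in length")
    pairs = _compared_columns(seq_x, seq_y)
    if not pairs:
        raise ValueError("no comparable (gap-free) columns")
    n = len(pairs)
    if model == "p_distance":
        return sum(a != b for a, b in pairs) / n
    if model == "jc69":
        p = sum(a != b for a, b in pairs) / n
        if p >= 0.75:
            raise SaturationError(f"p = {p:.3f} >= 3/4: JC69 distance undefined")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    if model == "k2p":
        ts = sum(a != b and (a in _PURINES) == (b in _PURINES) for a, b in pairs) / n
        tv = sum(a != b and (a in _PURINES) != (b in _PURINES) for a, b in pairs) / n
        arg1 = 1.0 - 2.0 * ts - tv
        arg2 = 1.0 - 2.0 * tv
        if arg1 <= 0 or arg2 <= 0:
            raise SaturationError("K2P log argument non-positive: saturated")
        return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)
    raise ValueError(f"unknown model {model!r}")


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    model: str = "p_distance"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("distance matrix has non-finite entries")


def distance_matrix(
    seqs: Sequence[str], labels: Sequence[str], model: str = "jc69"
) -> DistanceMatrix:
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(seqs[i], seqs[j], model)  # type: ignore[arg-type]
    return DistanceMatrix(list(labels), d, model)


@dataclass
class Tree:
    """A (usually unrooted) tree held as a Newick string plus flags."""

    newick: str
    negative_branches_clamped: bool = False
    tie_broken: bool = False

    def dendropy(self):
        import dendropy

        return dendropy.Tree.get(data=self.newick, schema="newick")

    def path_lengths(self) -> dict[frozenset, float]:
        """Leaf-pair path lengths {frozenset({a,b}): distance}."""
        t = self.dendropy()
        pdm = t.phylogenetic_distance_matrix()
        out = {}
        taxa = list(t.taxon_namespace)
        for i, ta in enumerate(taxa):
            for tb in taxa[i + 1 :]:
                out[frozenset({ta.label, tb.label})] = pdm.distance(ta, tb)
        return out

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions as frozensets of leaf labels (smaller side)."""
        t = self.dendropy()
        t.encode_bipartitions()
        all_labels = frozenset(leaf.taxon.label for leaf in t.leaf_node_iter())
        out = set()
        for edge in t.preorder_edge_iter():
            if edge.head_node is None or edge.head_node.is_leaf():
                continue
            side = frozenset(
                leaf.taxon.label for leaf in edge.head_node.leaf_iter()
            )
            if 1 < len(side) < len(all_labels) - 1:
                other = all_labels - side
                out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbor-joining (Saitou & Nei agglomeration).

    Ties in the Q criterion are broken deterministically by label order;
    negative branch-length estimates are clamped to zero and flagged.  On
    an additive matrix the true tree and its branch lengths are recovered
    exactly (up to floating-point error).
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    # working state: node newick fragments, sort keys for ties, distance dict
    nodes = list(range(n0))
    newick = {i: lab for i, lab in enumerate(dm.labels)}
    sortkey = {i: dm.labels[i] for i in range(n0)}
    d = {(i, j): dm.matrix[i, j] for i in range(n0) for j in range(n0)}
    next_id = n0
    clamped = False
    tie_broken = False

    def dist(i: int, j: int) -> float:
        return 0.0 if i == j else d[(min(i, j), max(i, j))]

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = {i: sum(dist(i, k) for k in nodes) for i in nodes}
        candidates = []
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = nodes[ai], nodes[bi]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                key = (min(sortkey[i], sortkey[j]), max(sortkey[i], sortkey[j]))
                candidates.append((q, key, i, j))
        qmin = min(c[0] for c in candidates)
        optimal = [c for c in candidates if math.isclose(c[0], qmin, abs_tol=1e-12)]
        if len(optimal) > 1:
            tie_broken = True
        _, _, i, j = min(optimal, key=lambda c: c[1])
        raw_li = 0.5 * dist(i, j) + (r[i] - r[j]) / (2.0 * (m - 2))
        li = clamp(raw_li)
        lj = clamp(dist(i, j) - raw_li)
        u = next_id
        next_id += 1
        for k in nodes:
            if k in (i, j):
                continue
            duk = 0.5 * (dist(i, k) + dist(j, k) - dist(i, j))
            d[(min(u, k), max(u, k))] = duk
        newick[u] = f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g})"
        sortkey[u] = min(sortkey[i], sortkey[j])
        nodes = [k for k in nodes if k not in (i, j)] + [u]

    i, j, k = sorted(nodes, key=lambda x: sortkey[x])
    li = clamp(0.5 * (dist(i, j) + dist(i, k) - dist(j, k)))
    lj = clamp(0.5 * (dist(i, j) + dist(j, k) - dist(i, k)))
    lk = clamp(0.5 * (dist(i, k) + dist(j, k) - dist(i, j)))
    nwk = f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g},{newick[k]}:{lk:.10g});"
    return Tree(newick=nwk, negative_branches_clamped=clamped, tie_broken=tie_broken)


# ---------------------------------------------------------------------------
# JC69 quartet maximum likelihood (Felsenstein pruning)
# ---------------------------------------------------------------------------


def _jc_matrix(t: float) -> np.ndarray:
    same = 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)
    diff = 0.25 - 0.25 * math.exp(-4.0 * t / 3.0)
    p = np.full((4, 4), diff)
    np.fill_diagonal(p, same)
    return p


def _site_patterns(rows: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Unique gap-free ACGT column patterns and their counts."""
    cols = []
    for col in zip(*[r.upper() for r in rows]):
        if all(c in _BASE_INDEX for c in col):
            cols.append(tuple(_BASE_INDEX[c] for c in col))
    if not cols:
        raise ValueError("alignment has no gap-free A/C/G/T columns")
    uniq: dict[tuple, int] = {}
    for c in cols:
        uniq[c] = uniq.get(c, 0) + 1
    pats = np.array(list(uniq.keys()), dtype=int)
    counts = np.array(list(uniq.values()), dtype=float)
    return pats, counts


_TOPOLOGY_PAIRS = {1: ((0, 1), (2, 3)), 2: ((0, 2), (1, 3)), 3: ((0, 3), (1, 2))}


def _quartet_lnl(
    pats: np.ndarray, counts: np.ndarray, partner: int, branches: np.ndarray
) -> float:
    """Log-likelihood of topology grouping row 0 with row ``partner``.

    ``branches`` is (t for the four leaves in row order, t_internal)."""
    (i, j), (k, l) = _TOPOLOGY_PAIRS[partner]
    pm = [_jc_matrix(branches[r]) for r in range(4)]
    pint = _jc_matrix(branches[4])
    # conditional likelihood at each internal node, per pattern: (npat, 4)
    left = pm[i][:, pats[:, i]].T * pm[j][:, pats[:, j]].T
    right = pm[k][:, pats[:, k]].T * pm[l][:, pats[:, l]].T
    site_l = 0.25 * np.einsum("px,xy,py->p", left, pint, right)
    return float(np.sum(counts * np.log(np.maximum(site_l, 1e-300))))


def _optimize_topology(
    pats: np.ndarray,
    counts: np.ndarray,
    partner: int,
    tol: float = 1e-6,
    max_sweeps: int = 100,
) -> tuple[float, np.ndarray]:
    branches = np.full(5, 0.1)
    lnl = _quartet_lnl(pats, counts, partner, branches)
    for _ in range(max_sweeps):
        for b in range(5):
            def neg(t: float, b: int = b) -> float:
                trial = branches.copy()
                trial[b] = t
                return -_quartet_lnl(pats, counts, partner, trial)

            res = minimize_scalar(
                neg, bounds=(BRANCH_MIN, BRANCH_MAX), method="bounded",
                options={"xatol": 1e-8},
            )
            if -res.fun > _quartet_lnl(pats, counts, partner, branches):
                branches[b] = float(res.x)
        new = _quartet_lnl(pats, counts, partner, branches)
        if new - lnl < tol:
            lnl = new
            break
        lnl = new
    return lnl, branches


@dataclass
class QuartetTopologyCall:
    winner: str  # orthologue_sister | paralogue_sister | mixed
    log_likelihoods: dict[str, float]
    branch_lengths: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    flags: list[str] = field(default_factory=list)
    bootstrap_proportion: float | None = None

    def normalized_support(self) -> dict[str, float]:
        """Likelihood weights across the three topologies (sum to 1)."""
        vals = np.array([self.log_likelihoods[t] for t in sorted(self.log_likelihoods)])
        w = np.exp(vals - vals.max())
        w /= w.sum()
        return dict(zip(sorted(self.log_likelihoods), w))


def quartet_ml(
    rows: Sequence[str], model: Literal["jc69"] = "jc69", tol: float = 1e-6
) -> QuartetTopologyCall:
    """Maximum-likelihood topology over the three unrooted quartets (JC69).

    ``rows`` are four aligned sequences in fixed role order.  For each
    topology the five branch lengths are optimized by coordinate ascent
    (bounded scalar search per branch, sweep until the log-likelihood
    gain falls below ``tol``).  Ties within ``tol`` are called ``mixed``
    (conservative); an alignment with no signal is flagged.
    """
    if model != "jc69":
        raise ValueError("only the jc69 model is implemented")
    if len(rows) != 4:
        raise ValueError("quartet_ml requires exactly four sequences")
    pats, counts = _site_patterns(rows)
    lnls: dict[str, float] = {}
    brs: dict[str, np.ndarray] = {}
    for partner, name in TOPOLOGY_NAMES.items():
        lnl, br = _optimize_topology(pats, counts, partner, tol=tol)
        lnls[name] = lnl
        brs[name] = br
    ranked = sorted(lnls.items(), key=lambda kv: -kv[1])
    flags: list[str] = []
    if ranked[0][1] - ranked[-1][1] < tol:
        return QuartetTopologyCall("mixed", lnls, brs, flags=["no_signal"])
    if ranked[0][1] - ranked[1][1] < tol:
        flags.append("tie")
        return QuartetTopologyCall("mixed", lnls, brs, flags=flags)
    return QuartetTopologyCall(ranked[0][0], lnls, brs, flags=flags)


def bootstrap_support(
    rows: Sequence[str],
    labels: Sequence[str] | None = None,
    builder: Literal["nj", "quartet_ml"] = "quartet_ml",
    n_replicates: int = 100,
    seed: int = 0,
    model: str = "jc69",
) -> dict:
    """Nonparametric bootstrap over alignment columns.

    Columns are resampled with replacement ``n_replicates`` times and the
    builder re-run.  For ``quartet_ml`` the result maps each topology
    name to the fraction of replicates calling it; for ``nj`` it maps
    each internal bipartition of the full-data tree (frozenset of labels)
    to its replicate frequency.  Fully reproducible given the seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ncol = len(rows[0])
    if ncol == 0 or any(len(r) != ncol for r in rows):
        raise ValueError("rows must be non-empty and equal-length")
    rng = np.random.default_rng(seed)
    if builder == "quartet_ml":
        tallies = {name: 0 for name in TOPOLOGY_NAMES.values()}
        for _ in range(n_replicates):
            idx = rng.integers(0, ncol, size=ncol)
            sample = ["".join(r[i] for i in idx) for r in rows]
            try:
                call = quartet_ml(sample)
            except ValueError:
                call = QuartetTopologyCall("mixed", {}, flags=["no_signal"])
            tallies[call.winner] += 1
        return {k: v / n_replicates for k, v in tallies.items()}
    if builder == "nj":
        if labels is None:
            raise ValueError("nj bootstrap requires taxon labels")
        base = nj_tree(distance_matrix(rows, labels, model))
        base_bip = base.bipartitions()
        counts = {b: 0 for b in base_bip}
        for _ in range(n_replicates):
            idx = rng.integers(0, ncol, size=ncol)
            sample = ["".join(r[i] for i in idx) for r in rows]
            try:
                rep = nj_tree(distance_matrix(sample, labels, model))
            except (SaturationError, ValueError):
                continue
            rep_bip = rep.bipartitions()
            for b in base_bip:
                if b in rep_bip:
                    counts[b] += 1
        return {b: c / n_replicates for b, c in counts.items()}
    raise ValueError(f"unknown builder {builder!r}")
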
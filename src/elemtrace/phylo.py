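"""Bootstrap-supported phylogeny from the alignment.

Topology comes from neighbor joining on Jukes–Cantor distances; branch
lengths are polished by maximizing the GTR+Gamma likelihood (Felsenstein
pruning with discrete gamma rate categories); nonparametric bootstrap over
alignment columns yields bipartition supports.  Trees serialize as Newick
with supports as internal node labels.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc, logsumexp
from scipy.stats import gamma as gamma_dist

from .msa import GAP, Msa
from .sequence_io import DataError

log = logging.getLogger("elemtrace")

JC_DISTANCE_CAP = 5.0
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# tree structure


class TreeNode:
    """One node; ``length`` is the branch to the parent (None at the root)."""

    __slots__ = ("children", "label", "length", "support")

    def __init__(self, label=None, length=None, support=None, children=None):
        self.label = label
        self.length = length
        self.support = support
        self.children: list[TreeNode] = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Unrooted-binary tree stored rooted at an arbitrary multifurcation."""

    root: TreeNode
    log_likelihood: float | None = None

    def postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode):
            for ch in node.children:
                walk(ch)
            out.append(node)

        walk(self.root)
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def copy(self) -> "PhyloTree":
        return copy.deepcopy(self)

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Map canonical leaf-label bipartition -> subtree node, internal edges only.

        The canonical form of a split is the side not containing the
        alphabetically first leaf label.
        """
        all_labels = frozenset(self.leaf_labels())
        ref = min(all_labels)
        splits: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(walk(ch) for ch in node.children))
            if node is not self.root:
                side = all_labels - below if ref in below else below
                if 1 < len(side) < len(all_labels) - 1:
                    splits[side] = node
            return below

        walk(self.root)
        return splits

    def newick(self) -> str:
        return _newick_of(self.root) + ";"


def _newick_of(node: TreeNode) -> str:
    if node.is_leaf:
        body = node.label or ""
    else:
        inner = ",".join(_newick_of(ch) for ch in node.children)
        label = "" if node.support is None else str(node.support)
        body = f"({inner}){label}"
    if node.length is not None:
        body += f":{node.length:.6f}"
    return body


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


def read_newick(path: str | Path) -> PhyloTree:
    """Parse a Newick file; malformed input raises with the failing position."""
    text = Path(path).read_text().strip()
    return parse_newick(text)


def parse_newick(text: str) -> PhyloTree:
    pos = 0

    def error(msg: str):
        raise DataError(f"newick parse error at position {pos}: {msg}")

    def peek() -> str:
        return text[pos] if pos < len(text) else ""

    def parse_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(text) and text[pos] not in "():,;":
            pos += 1
        return text[start:pos].strip()

    def parse_clade() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if peek() == "(":
            pos += 1
            node.children.append(parse_clade())
            while peek() == ",":
                pos += 1
                node.children.append(parse_clade())
            if peek() != ")":
                error("expected ')'")
            pos += 1
            label = parse_label()
            if label:
                try:
                    node.support = int(float(label))
                except ValueError:
                    node.label = label
        else:
            node.label = parse_label()
            if node.label == "":
                error("expected a leaf label")
        if peek() == ":":
            pos += 1
            start = pos
            while pos < len(text) and (text[pos].isdigit() or text[pos] in ".eE+-"):
                pos += 1
            try:
                node.length = float(text[start:pos])
            except ValueError:
                error("invalid branch length")
        return node

    root = parse_clade()
    if peek() != ";":
        raise DataError(f"newick parse error at position {pos}: expected ';'")
    return PhyloTree(root=root)


# ---------------------------------------------------------------------------
# distances


def encode_alignment(msa: Msa) -> np.ndarray:
    """(n_rows, n_cols) int8 codes: A,C,G,T -> 0..3; gap and N -> -1."""
    mat = msa.to_matrix()
    codes = np.full(mat.shape, -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        codes[mat == base.encode()] = code
    return codes


def jc_codes_distance(codes: np.ndarray) -> np.ndarray:
    """Jukes–Cantor distance matrix from encoded alignment rows.

    p is computed over columns where both rows carry a real base; saturated
    pairs (p >= 0.75) and zero-overlap pairs get the cap distance.
    """
    n = codes.shape[0]
    d = np.zeros((n, n))
    valid = codes >= 0
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        diff = both & (codes[i] != codes[i + 1 :])
        overlap = both.sum(axis=1)
        mism = diff.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(overlap > 0, mism / np.maximum(overlap, 1), 1.0)
        dij = np.where(
            (overlap == 0) | (p >= 0.75),
            JC_DISTANCE_CAP,
            -0.75 * np.log(np.maximum(1.0 - 4.0 * p / 3.0, 1e-300)),
        )
        d[i, i + 1 :] = dij
        d[i + 1 :, i] = dij
    if np.any(d >= JC_DISTANCE_CAP):
        log.warning("some pairwise distances are saturated; capped at %.1f", JC_DISTANCE_CAP)
    return d


def jc_distance_matrix(msa: Msa) -> np.ndarray:
    if msa.n_rows < 2:
        raise DataError("need at least two rows for distances")
    return jc_codes_distance(encode_alignment(msa))


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dist: np.ndarray, labels: Sequence[str]) -> PhyloTree:
    """Canonical NJ (Q-matrix criterion), ties broken by smallest index pair.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister edge.  The result is rooted at the final three-way join
    (two leaves produce a single-edge cherry).
    """
    n = len(labels)
    if n < 2:
        raise DataError("neighbor joining needs at least two taxa")
    if n == 2:
        d = float(dist[0, 1])
        half = max(d / 2.0, 0.0)
        return PhyloTree(
            root=TreeNode(
                children=[
                    TreeNode(label=labels[0], length=half),
                    TreeNode(label=labels[1], length=half),
                ]
            )
        )
    nodes: dict[int, TreeNode] = {
        i: TreeNode(label=labels[i]) for i in range(n)
    }
    d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}

    def dd(i: int, j: int) -> float:
        return d[(i, j) if i < j else (j, i)]

    active = list(range(n))
    next_index = n
    while len(active) > 3:
        N = len(active)
        r = {i: sum(dd(i, m) for m in active if m != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (N - 2) * dd(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = dd(i, j) / 2.0 + (r[i] - r[j]) / (2.0 * (N - 2))
        lj = dd(i, j) - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        node_i, node_j = nodes.pop(i), nodes.pop(j)
        node_i.length, node_j.length = li, lj
        parent = TreeNode(children=[node_i, node_j])
        for m in active:
            if m in (i, j):
                continue
            d[(min(m, next_index), max(m, next_index))] = max(
                (dd(i, m) + dd(j, m) - dd(i, j)) / 2.0, 0.0
            )
        nodes[next_index] = parent
        active = [m for m in active if m not in (i, j)] + [next_index]
        next_index += 1
    a, b, c = active
    la = max((dd(a, b) + dd(a, c) - dd(b, c)) / 2.0, 0.0)
    lb = max((dd(a, b) + dd(b, c) - dd(a, c)) / 2.0, 0.0)
    lc = max((dd(a, c) + dd(b, c) - dd(a, b)) / 2.0, 0.0)
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = length
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root=root)


# ---------------------------------------------------------------------------
# GTR + discrete gamma model


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Mean-of-quantile-bin discrete gamma rates, normalized to mean 1.

    Quantile bin edges come from Gamma(alpha, rate alpha); the rate of each
    category is the conditional mean of the density within the bin.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if n_categories < 1:
        raise ValueError("need at least one category")
    edges = gamma_dist.ppf(
        np.arange(n_categories + 1) / n_categories, a=alpha, scale=1.0 / alpha
    )
    # E[X; a<X<b] for X ~ Gamma(alpha, rate alpha) (mean 1) via the
    # regularized incomplete gamma of shape alpha+1
    mass = gammainc(alpha + 1.0, alpha * edges[1:]) - gammainc(
        alpha + 1.0, alpha * edges[:-1]
    )
    rates = n_categories * mass
    return rates / rates.mean()


_EXCH_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")


@dataclass
class GtrGammaModel:
    """General time-reversible substitution model with gamma rate variation.

    ``exchangeabilities`` follow the order AC, AG, AT, CG, CT, GT (GT is the
    reference, conventionally 1).  The rate matrix is scaled so branch
    lengths are expected substitutions per site; category rates have mean 1.
    """

    exchangeabilities: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    alpha: float = 1.0
    n_categories: int = 4

    def __post_init__(self):
        if len(self.exchangeabilities) != 6 or any(
            s < 0 for s in self.exchangeabilities
        ):
            raise ValueError("need 6 nonnegative exchangeabilities")
        pi = np.asarray(self.base_freqs, dtype=float)
        if len(pi) != 4 or np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("base frequencies must be 4 positive values summing to 1")

    @cached_property
    def rate_matrix(self) -> np.ndarray:
        pi = np.asarray(self.base_freqs, dtype=float)
        s = np.zeros((4, 4))
        pairs = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
        for (i, j), x in zip(pairs, self.exchangeabilities):
            s[i, j] = s[j, i] = x
        Q = s * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.sum(pi * np.diag(Q)))
        return Q / mu

    @cached_property
    def _eigen(self):
        # eigendecomposition in the pi-symmetrized basis
        pi = np.asarray(self.base_freqs, dtype=float)
        sq = np.sqrt(pi)
        B = (sq[:, None] * self.rate_matrix) / sq[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        left = U.T * sq[None, :]
        right = U / sq[:, None]
        return w, right, left

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows sum to 1."""
        w, right, left = self._eigen
        P = (right * np.exp(w * t)[None, :]) @ left
        return np.clip(P, 0.0, None)

    @cached_property
    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.n_categories)

    @classmethod
    def from_msa(cls, msa: Msa, alpha: float = 1.0, n_categories: int = 4):
        """Model with empirical base frequencies (gaps and N excluded)."""
        codes = encode_alignment(msa)
        counts = np.array([(codes == c).sum() for c in range(4)], dtype=float)
        if counts.sum() == 0:
            freqs = (0.25, 0.25, 0.25, 0.25)
        else:
            counts = np.maximum(counts, 1.0)  # keep every frequency positive
            freqs = tuple(counts / counts.sum())
        return cls(base_freqs=freqs, alpha=alpha, n_categories=n_categories)


# ---------------------------------------------------------------------------
# likelihood by pruning

_LEAF_PARTIALS = np.vstack([np.eye(4), np.ones((1, 4))])  # codes 0..3, then missing


class LikelihoodEngine:
    """Felsenstein pruning over compressed column patterns.

    Gaps and N are missing data (partial vector of ones); per-node scaling
    guards against underflow; the column likelihood averages the gamma
    categories with equal weight.
    """

    def __init__(self, msa: Msa, model: GtrGammaModel):
        if msa.n_cols == 0:
            raise DataError("cannot compute a likelihood on zero columns")
        self.model = model
        self.labels = msa.labels
        codes = encode_alignment(msa)
        patterns, counts = np.unique(codes, axis=1, return_counts=True)
        self.patterns = patterns  # (n_rows, n_patterns)
        self.counts = counts.astype(float)
        self.row_index = {label: i for i, label in enumerate(self.labels)}
        self.pi = np.asarray(model.base_freqs, dtype=float)

    def log_likelihood(self, tree: PhyloTree) -> float:
        tree_labels = set(tree.leaf_labels())
        if tree_labels != set(self.labels):
            raise DataError("tree leaves do not match alignment rows")
        npat = self.patterns.shape[1]
        rates = self.model.category_rates
        per_cat = np.empty((len(rates), npat))
        for c, rate in enumerate(rates):
            per_cat[c] = self._cat_loglik(tree.root, rate)
        col_ll = logsumexp(per_cat, axis=0) - math.log(len(rates))
        return float(np.dot(self.counts, col_ll))

    def _leaf_partial(self, label: str) -> np.ndarray:
        codes = self.patterns[self.row_index[label]]
        return _LEAF_PARTIALS[np.where(codes < 0, 4, codes)]

    def _cat_loglik(self, root: TreeNode, rate: float) -> np.ndarray:
        partial, logscale = self._partial(root, rate)
        site = partial @ self.pi
        return np.log(np.maximum(site, 1e-300)) + logscale

    def _partial(self, node: TreeNode, rate: float):
        if node.is_leaf:
            return self._leaf_partial(node.label), np.zeros(1)
        npat = self.patterns.shape[1]
        partial = np.ones((npat, 4))
        logscale = np.zeros(npat)
        for child in node.children:
            ch_partial, ch_scale = self._partial(child, rate)
            t = (child.length or 0.0) * rate
            P = self.model.transition_matrix(t)
            partial *= ch_partial @ P.T
            logscale = logscale + ch_scale
        mx = partial.max(axis=1)
        mx = np.maximum(mx, 1e-300)
        partial /= mx[:, None]
        logscale = logscale + np.log(mx)
        return partial, logscale


def log_likelihood(tree: PhyloTree, msa: Msa, model: GtrGammaModel) -> float:
    """Total ln-likelihood of the alignment on the tree under GTR+Gamma."""
    return LikelihoodEngine(msa, model).log_likelihood(tree)


def optimize_branch_lengths(
    tree: PhyloTree,
    msa: Msa,
    model: GtrGammaModel,
    tol: float = 1e-3,
    max_cycles: int = 20,
    bounds: tuple[float, float] = (1e-8, 10.0),
) -> PhyloTree:
    """Cyclic per-edge 1-D likelihood maximization.

    Each cycle optimizes every branch in turn with a bounded scalar search;
    cycles stop when the ln-likelihood gain falls below ``tol`` (or after
    ``max_cycles``).  The ln-likelihood never decreases across cycles.
    """
    tree = tree.copy()
    engine = LikelihoodEngine(msa, model)
    edges = [n for n in tree.postorder() if n is not tree.root]
    current = engine.log_likelihood(tree)
    for _ in range(max_cycles):
        start = current
        for node in edges:
            original = node.length or bounds[0]

            def neg(t: float, _node=node) -> float:
                _node.length = t
                return -engine.log_likelihood(tree)

            res = minimize_scalar(
                neg, bounds=bounds, method="bounded", options={"xatol": 1e-6}
            )
            if -res.fun >= current:
                node.length = float(res.x)
                current = -res.fun
            else:
                node.length = original
        if current - start < tol:
            break
    tree.log_likelihood = current
    return tree


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    """Best tree with supports attached, plus the replicate NJ trees."""

    tree: PhyloTree
    replicates: list[PhyloTree]
    n_replicates: int
    seed: int


def bootstrap_support(
    msa: Msa,
    model: GtrGammaModel | None = None,
    n_replicates: int = 100,
    seed: int = 0,
    optimize: bool = True,
) -> BootstrapResult:
    """NJ best tree, ML branch-length polish, and column-bootstrap supports.

    Each replicate resamples alignment columns with replacement and rebuilds
    an NJ tree; the support of an internal edge of the best tree is the
    percentage of replicates containing the same leaf-label bipartition.
    Alignments with fewer than four rows have no internal edges and get no
    supports.
    """
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    model = model or GtrGammaModel.from_msa(msa)
    labels = msa.labels
    codes = encode_alignment(msa)
    best = neighbor_joining(jc_codes_distance(codes), labels)
    if optimize:
        best = optimize_branch_lengths(best, msa, model)
    rng = np.random.default_rng(seed)
    replicates: list[PhyloTree] = []
    split_counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        idx = rng.integers(0, codes.shape[1], size=codes.shape[1])
        rep = neighbor_joining(jc_codes_distance(codes[:, idx]), labels)
        replicates.append(rep)
        for split in rep.bipartitions():
            split_counts[split] = split_counts.get(split, 0) + 1
    if msa.n_rows < 4:
        log.warning("fewer than 4 rows: no internal edges, no supports")
    else:
        for split, node in best.bipartitions().items():
            node.support = round(100.0 * split_counts.get(split, 0) / n_replicates)
    return BootstrapResult(
        tree=best, replicates=replicates, n_replicates=n_replicates, seed=seed
    )


def write_tree_files(result: BootstrapResult, outdir: str | Path) -> dict[str, str]:
    """Write the four tree outputs: best, support-annotated, replicates, info.

    Returns a name -> path mapping.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree_best": outdir / "tree_best.nwk",
        "tree_support": outdir / "tree_support.nwk",
        "tree_bootstraps": outdir / "tree_bootstraps.nwk",
        "tree_info": outdir / "tree_info.txt",
    }
    stripped = result.tree.copy()
    for node in stripped.postorder():
        node.support = None
    write_newick(stripped, paths["tree_best"])
    write_newick(result.tree, paths["tree_support"])
    with open(paths["tree_bootstraps"], "w") as fh:
        for rep in result.replicates:
            fh.write(rep.newick() + "\n")
    with open(paths["tree_info"], "w") as fh:
        fh.write(f"n_replicates\t{result.n_replicates}\n")
        fh.write(f"seed\t{result.seed}\n")
        lnl = result.tree.log_likelihood
        fh.write(f"log_likelihood\t{'NA' if lnl is None else f'{lnl:.6f}'}\n")
        fh.write(f"n_leaves\t{len(result.tree.leaf_labels())}\n")
    return {k: str(v) for k, v in paths.items()}
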
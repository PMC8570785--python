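"""Progressive multiple sequence alignment of the query and its homologs.

A single refinement-free progressive pass in the classic style: k-mer
distances between the unaligned sequences, a UPGMA guide tree, and
profile–profile global alignment with affine gaps at each internal node.
Terminal gap runs are charged half the gap-open cost; N contributes nothing
to column profiles.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .search import ScoringScheme
from .sequence_io import DataError

log = logging.getLogger("elemtrace")

GAP = "-"
DEFAULT_K = 6

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# alignment container


@dataclass
class Msa:
    """A rectangular gapped alignment; the query row is first."""

    rows: list[tuple[str, str]]

    def __post_init__(self):
        if not self.rows:
            raise DataError("alignment must have at least one row")
        length = len(self.rows[0][1])
        if any(len(seq) != length for _, seq in self.rows):
            raise DataError("alignment rows differ in length")
        labels = [name for name, _ in self.rows]
        if len(set(labels)) != len(labels):
            raise DataError("alignment row labels must be unique")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    @property
    def labels(self) -> list[str]:
        return [name for name, _ in self.rows]

    def ungapped(self, label: str) -> str:
        for name, seq in self.rows:
            if name == label:
                return seq.replace(GAP, "")
        raise KeyError(label)

    def to_matrix(self) -> np.ndarray:
        """Rows as a (n_rows, n_cols) array of bytes (b'A', b'-', ...)."""
        return np.frombuffer(
            "".join(seq for _, seq in self.rows).encode(), dtype="S1"
        ).reshape(self.n_rows, self.n_cols)


# ---------------------------------------------------------------------------
# guide-tree distances


def kmer_distance(seqs: Sequence[str], k: int = DEFAULT_K) -> np.ndarray:
    """Pairwise k-mer multiset distance matrix.

    d(i,j) = 1 - shared / min(n_i, n_j), with `shared` the multiset
    intersection size of the two k-mer collections.  Sequences shorter than
    k get maximal distance 1 to everything (with a warning).
    """
    n = len(seqs)
    if n < 2:
        raise DataError("k-mer distances need at least two sequences")
    counters: list[Counter | None] = []
    for s in seqs:
        if len(s) < k:
            log.warning("sequence of length %d is shorter than k=%d", len(s), k)
            counters.append(None)
        else:
            counters.append(Counter(s[i : i + k] for i in range(len(s) - k + 1)))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = counters[i], counters[j]
            if ci is None or cj is None:
                dij = 1.0
            else:
                shared = sum((ci & cj).values())
                dij = 1.0 - shared / min(sum(ci.values()), sum(cj.values()))
            d[i, j] = d[j, i] = dij
    return d


# ---------------------------------------------------------------------------
# UPGMA guide tree


@dataclass
class GuideNode:
    """Node of the rooted UPGMA guide tree (leaf iff ``index`` < n_leaves)."""

    index: int
    height: float
    left: "GuideNode | None" = None
    right: "GuideNode | None" = None
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf:
            return f"{self.label}"
        lt = self.height - self.left.height
        rt = self.height - self.right.height
        return f"({self.left._nwk()}:{lt:g},{self.right._nwk()}:{rt:g})"


def upgma(dist: np.ndarray, labels: Sequence[str]) -> GuideNode:
    """Average-linkage agglomeration; ties broken by smallest (i, j) pair.

    Cluster indices count leaves 0..n-1 first, then merge order; the pair
    with minimal average distance and, on ties, the lexicographically
    smallest index pair is joined at height d/2.
    """
    n = len(labels)
    if dist.shape != (n, n):
        raise DataError("distance matrix does not match labels")
    active: dict[int, GuideNode] = {
        i: GuideNode(index=i, height=0.0, label=labels[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    d = {
        (i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_index = n
    while len(active) > 1:
        ids = sorted(active)
        best = None
        for a_pos, i in enumerate(ids):
            for j in ids[a_pos + 1 :]:
                key = (i, j)
                if best is None or d[key] < best[0] - 1e-15:
                    best = (d[key], i, j)
        _, i, j = best

        def min_leaf(node: GuideNode) -> int:
            return node.index if node.is_leaf else min(
                min_leaf(node.left), min_leaf(node.right)
            )

        first, second = active[i], active[j]
        if min_leaf(second) < min_leaf(first):
            first, second = second, first
        node = GuideNode(
            index=next_index, height=d[(i, j)] / 2.0, left=first, right=second
        )
        si, sj = sizes[i], sizes[j]
        for m in ids:
            if m in (i, j):
                continue
            dim = d[(min(i, m), max(i, m))]
            djm = d[(min(j, m), max(j, m))]
            d[(min(m, next_index), max(m, next_index))] = (si * dim + sj * djm) / (
                si + sj
            )
        del active[i], active[j], sizes[i], sizes[j]
        active[next_index] = node
        sizes[next_index] = si + sj
        next_index += 1
    return next(iter(active.values()))


# ---------------------------------------------------------------------------
# profile-profile alignment

_NEG = -1e18


def _profile(rows: Sequence[str]) -> np.ndarray:
    """(L, 4) base frequencies per column over A,C,G,T; gaps and N ignored.

    A column with no contributing base (all gap/N) yields a zero row and
    scores 0 against anything.
    """
    mat = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(
        len(rows), len(rows[0])
    )
    counts = np.stack(
        [(mat == base.encode()).sum(axis=0) for base in "ACGT"], axis=1
    ).astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
    return freqs


def _substitution_matrix(scheme: ScoringScheme) -> np.ndarray:
    s = np.full((4, 4), float(scheme.mismatch))
    np.fill_diagonal(s, float(scheme.match))
    return s


def profile_align(
    rows_a: Sequence[tuple[str, str]],
    rows_b: Sequence[tuple[str, str]],
    scheme: ScoringScheme | None = None,
) -> tuple[list[tuple[str, str]], float]:
    """Globally align two gapped blocks column-wise with affine gaps.

    The score of pairing column i of A with column j of B is the expected
    substitution score over the two columns' base frequencies.  New gap
    columns cost gap_open + L*gap_extend per run, half open cost for runs
    touching either end of the merged alignment.  Returns the merged block
    (rows of A then rows of B) and the alignment score.
    """
    scheme = scheme or ScoringScheme()
    if not rows_a or not rows_b:
        raise DataError("profile blocks must be nonempty")
    if not rows_a[0][1]:
        merged = [(n, GAP * len(rows_b[0][1])) for n, _ in rows_a] + list(rows_b)
        return merged, 0.0
    if not rows_b[0][1]:
        merged = list(rows_a) + [(n, GAP * len(rows_a[0][1])) for n, _ in rows_b]
        return merged, 0.0
    A = [seq for _, seq in rows_a]
    B = [seq for _, seq in rows_b]
    fa, fb = _profile(A), _profile(B)
    S = _substitution_matrix(scheme)
    col_scores = fa @ S @ fb.T  # (na, nb)
    na, nb = col_scores.shape
    op, ext = float(scheme.gap_open), float(scheme.gap_extend)
    half = op / 2.0

    M = np.full((na + 1, nb + 1), _NEG)
    X = np.full((na + 1, nb + 1), _NEG)  # gap column inserted into B
    Y = np.full((na + 1, nb + 1), _NEG)  # gap column inserted into A
    M[0, 0] = 0.0
    X[1:, 0] = half + ext * np.arange(1, na + 1)
    Y[0, 1:] = half + ext * np.arange(1, nb + 1)
    for i in range(1, na + 1):
        prevV = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prevV[:-1] + col_scores[i - 1]
        X[i, 1:] = np.maximum(prevV[1:] + op + ext, X[i - 1, 1:] + ext)
        # Y depends on same-row values to the left: prefix-scan formulation
        VV = np.maximum(M[i], X[i])
        run = np.maximum.accumulate(VV[:-1] + op - ext * np.arange(nb))
        Y[i, 1:] = run + ext * np.arange(1, nb + 1)
    # trailing terminal gaps at half open cost
    V = np.maximum(np.maximum(M, X), Y)
    end_candidates = [(float(V[na, nb]), na, nb, None)]
    for i in range(na):
        end_candidates.append(
            (float(V[i, nb] + half + ext * (na - i)), i, nb, "X")
        )
    for j in range(nb):
        end_candidates.append(
            (float(V[na, j] + half + ext * (nb - j)), na, j, "Y")
        )
    score, ei, ej, trailing = max(end_candidates, key=lambda t: t[0])

    # traceback
    ops: list[str] = []
    if trailing == "X":
        ops.extend("I" * (na - ei))
    elif trailing == "Y":
        ops.extend("D" * (nb - ej))
    i, j = ei, ej
    state = "V"
    while (i, j) != (0, 0):
        if state == "V":
            v = V[i, j]
            state = "M" if v == M[i, j] else ("X" if v == X[i, j] else "Y")
            continue
        if state == "W":  # a new gap-in-A run resumes from max(M, X) only
            state = "M" if M[i, j] >= X[i, j] else "X"
            continue
        if state == "M":
            ops.append("M")
            i, j = i - 1, j - 1
            state = "V"
        elif state == "X":
            ops.append("I")
            if j == 0:
                i -= 1  # boundary leading-gap column; stays X until (0,0)
            elif X[i, j] == X[i - 1, j] + ext:
                i -= 1  # gap run continues upward
            else:
                i -= 1
                state = "V"
        else:  # Y
            ops.append("D")
            if i == 0:
                j -= 1  # boundary leading-gap row; stays Y until (0,0)
            elif Y[i, j] == Y[i, j - 1] + ext:
                j -= 1  # gap run continues leftward
            else:
                j -= 1
                state = "W"
    ops.reverse()

    merged: list[tuple[str, str]] = []
    for name, seq in rows_a:
        out = []
        pos = 0
        for o in ops:
            if o in ("M", "I"):
                out.append(seq[pos])
                pos += 1
            else:
                out.append(GAP)
        merged.append((name, "".join(out)))
    for name, seq in rows_b:
        out = []
        pos = 0
        for o in ops:
            if o in ("M", "D"):
                out.append(seq[pos])
                pos += 1
            else:
                out.append(GAP)
        merged.append((name, "".join(out)))
    return merged, float(score)


# ---------------------------------------------------------------------------
# progressive driver


def build_msa(
    seqs: Sequence[tuple[str, str]],
    scheme: ScoringScheme | None = None,
    k: int = DEFAULT_K,
) -> Msa:
    """Align sequences progressively; the first entry is the query row.

    Merges follow the post-order of the UPGMA tree over k-mer distances;
    all-gap columns are stripped at the end and rows are returned in input
    order (query first).
    """
    scheme = scheme or ScoringScheme()
    if not seqs:
        raise DataError("no sequences to align")
    if len(seqs) == 1:
        log.warning("single sequence: returning a degenerate one-row alignment")
        return Msa(rows=list(seqs))
    labels = [name for name, _ in seqs]
    dist = kmer_distance([s for _, s in seqs], k=k)
    root = upgma(dist, labels)

    def merge(node: GuideNode) -> list[tuple[str, str]]:
        if node.is_leaf:
            name, seq = seqs[node.index]
            return [(name, seq)]
        left = merge(node.left)
        right = merge(node.right)
        merged, _ = profile_align(left, right, scheme)
        return merged

    rows = merge(root)
    order = {name: i for i, (name, _) in enumerate(seqs)}
    rows.sort(key=lambda r: order[r[0]])
    # strip all-gap columns (cannot normally occur, but keep the invariant)
    cols = list(zip(*[seq for _, seq in rows]))
    keep = [i for i, col in enumerate(cols) if any(c != GAP for c in col)]
    if len(keep) != len(cols):
        rows = [
            (name, "".join(seq[i] for i in keep)) for name, seq in rows
        ]
    return Msa(rows=rows)
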
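"""Distant-homolog search: discontiguous seed-and-extend local alignment.

Finds the best distant homolog(s) of the query in each genome using a
discontiguous-template word index (dc-megablast style: 12 sampled positions
in a 21-column window), banded affine-gap X-drop extension around each seed,
and Karlin–Altschul E-value statistics, followed by threshold filtering and
per-genome ortholog selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import brentq

from .sequence_io import DataError, GenomeRecord, QueryElement, reverse_complement

log = logging.getLogger("elemtrace")

# ---------------------------------------------------------------------------
# discontiguous template
#
# 21-column coding-style template with 12 matched positions; the remaining 9
# positions are free to mismatch.  A seed is a pair of 21-mers agreeing at
# every matched position.

TEMPLATE_SPAN = 21
TEMPLATE_POSITIONS = (0, 1, 3, 4, 6, 7, 9, 10, 12, 13, 15, 16)


def template_key(window: str, positions=TEMPLATE_POSITIONS) -> str | None:
    """Extract the sampled-position word of a 21-mer; None if it contains N."""
    key = "".join(window[p] for p in positions)
    return None if "N" in key else key


# ---------------------------------------------------------------------------
# scoring scheme and Karlin–Altschul parameters


def karlin_lambda(match: int, mismatch: int, freqs=(0.25, 0.25, 0.25, 0.25)) -> float:
    """Solve sum_ij p_i p_j exp(lambda*s_ij) = 1 for lambda > 0.

    For uniform base frequencies and a match/mismatch scheme this reduces to
    p_match*e^(lambda*match) + p_mismatch*e^(lambda*mismatch) = 1.
    """
    p = np.asarray(freqs, dtype=float)
    p_match = float(np.sum(p * p))
    p_mis = 1.0 - p_match

    def f(lam: float) -> float:
        return p_match * math.exp(lam * match) + p_mis * math.exp(lam * mismatch) - 1.0

    # f(0)=0; f grows without bound; bracket the positive root.
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    return float(brentq(f, 1e-9, hi, xtol=1e-12))


def karlin_K(
    match: int,
    mismatch: int,
    lam: float,
    freqs=(0.25, 0.25, 0.25, 0.25),
    tol: float = 1e-6,
    max_terms: int = 400,
) -> float:
    """Karlin–Altschul K for an i.i.d. match/mismatch walk (lattice case).

    Uses the standard series: with S_k the k-step random-walk sum of aligned
    pair scores, sigma = sum_k (1/k) [E(e^(lambda*S_k); S_k<0) + P(S_k>=0)],
    truncated when a term falls below ``tol``, and

        K = delta * lambda * exp(-2*sigma) / (H * (1 - e^(-lambda*delta)))

    where delta is the score lattice span and H the relative entropy.
    """
    p = np.asarray(freqs, dtype=float)
    p_match = float(np.sum(p * p))
    p_mis = 1.0 - p_match
    delta = math.gcd(abs(match), abs(mismatch))
    # relative entropy H = lambda * sum q_ij s_ij, q the lambda-tilted measure
    H = lam * (
        p_match * match * math.exp(lam * match)
        + p_mis * mismatch * math.exp(lam * mismatch)
    )
    # distribution of the single-step score on the integer lattice
    lo, hi = min(mismatch, match), max(mismatch, match)
    step = np.zeros(hi - lo + 1)
    step[match - lo] += p_match
    step[mismatch - lo] += p_mis
    dist = np.array([1.0])
    dist_lo = 0  # value of the lowest index of `dist`
    sigma = 0.0
    for k in range(1, max_terms + 1):
        dist = np.convolve(dist, step)
        dist_lo += lo
        values = dist_lo + np.arange(len(dist))
        neg = values < 0
        term = float(
            np.sum(dist[neg] * np.exp(lam * values[neg])) + np.sum(dist[~neg])
        )
        sigma += term / k
        if term < tol:
            break
    K = delta * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * delta)))
    return float(K)


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/affine-gap scores plus the derived E-value statistics.

    Gap of length L costs ``gap_open + L * gap_extend``.  ``lam`` and ``K``
    are the ungapped Karlin–Altschul parameters for the match/mismatch pair
    under uniform base frequencies; they are applied to gapped scores too.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    lam: float = field(default=0.0)
    K: float = field(default=0.0)

    def __post_init__(self):
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.lam == 0.0:
            lam = karlin_lambda(self.match, self.mismatch)
            object.__setattr__(self, "lam", lam)
        if self.K == 0.0:
            object.__setattr__(
                self, "K", karlin_K(self.match, self.mismatch, self.lam)
            )

    def score_pair(self, a: str, b: str) -> int:
        """Score one aligned base pair; N never counts as a match."""
        if a == b and a != "N":
            return self.match
        return self.mismatch

    def bit_score(self, raw_score: int) -> float:
        return (self.lam * raw_score - math.log(self.K)) / math.log(2.0)


def evalue(bit_score: float, m: int, n: int) -> float:
    """Karlin–Altschul expectation E = m*n*2^(-bit_score); no edge correction."""
    if m <= 0 or n <= 0:
        raise ValueError("m and n must be positive")
    return m * n * math.pow(2.0, -bit_score)


# ---------------------------------------------------------------------------
# seed index


@dataclass
class SeedIndex:
    """Discontiguous-word index over both strands of one genome.

    ``words`` maps the 12-base sampled word to (contig, offset, strand)
    triples.  Minus-strand offsets are positions on the reverse-complemented
    contig; :func:`hsp_forward_coords` converts back to forward coordinates.
    """

    genome_id: str
    words: dict[str, list[tuple[str, int, str]]]
    contig_lengths: dict[str, int]

    @property
    def n_words(self) -> int:
        return sum(len(v) for v in self.words.values())


def build_index(genome: GenomeRecord, positions=TEMPLATE_POSITIONS) -> SeedIndex:
    """Index every template word of both strands of a genome.

    Words containing N are skipped.  Contigs shorter than the 21-column
    template contribute nothing.
    """
    words: dict[str, list[tuple[str, int, str]]] = {}
    lengths: dict[str, int] = {}
    for contig_name, seq in genome.contigs:
        lengths[contig_name] = len(seq)
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            for off in range(len(s) - TEMPLATE_SPAN + 1):
                key = template_key(s[off : off + TEMPLATE_SPAN], positions)
                if key is not None:
                    words.setdefault(key, []).append((contig_name, off, strand))
    return SeedIndex(genome_id=genome.genome_id, words=words, contig_lengths=lengths)


def find_seeds(
    query: QueryElement, index: SeedIndex, positions=TEMPLATE_POSITIONS
) -> list[tuple[int, str, int, str]]:
    """All (q_pos, contig, s_pos, strand) template matches of query vs index.

    Complete: every window pair agreeing at the 12 sampled positions is
    reported; nothing is dropped at this stage.
    """
    seeds: list[tuple[int, str, int, str]] = []
    seq = query.seq
    for q_pos in range(len(seq) - TEMPLATE_SPAN + 1):
        key = template_key(seq[q_pos : q_pos + TEMPLATE_SPAN], positions)
        if key is None:
            continue
        for contig, s_pos, strand in index.words.get(key, ()):
            seeds.append((q_pos, contig, s_pos, strand))
    seeds.sort(key=lambda s: (s[1], s[3], s[0], s[2]))
    return seeds


# ---------------------------------------------------------------------------
# X-drop gapped extension

# Final gapped-extension drop-off, raw score units.  Must exceed the cost of
# any indel the extension should bridge: a 17-nt deletion costs
# |gap_open| + 17*|gap_extend| = 39, so megablast-style 100 keeps moderate
# indels inside a single HSP while still terminating quickly in random
# sequence.
DEFAULT_XDROP = 100
# score of a 14-nt exact match under the default +2 reward
MIN_RAW_SCORE = 28

_NEG = -1e18


def _xdrop_extend_one_way(A: str, B: str, scheme: ScoringScheme, xdrop: float):
    """Affine-gap extension of prefixes of A and B anchored at their start.

    Returns (best_score, i_end, j_end, ops) where ops is the edit script
    ('M' diagonal, 'I' consume A only, 'D' consume B only) of the best-scoring
    alignment of A[:i_end] vs B[:j_end]; the empty extension scores 0.
    A direction is abandoned once every live cell trails the running best by
    more than ``xdrop``.
    """
    la, lb = len(A), len(B)
    if la == 0 or lb == 0:
        return 0, 0, 0, []
    op, ext = scheme.gap_open, scheme.gap_extend
    # dict-of-rows sparse DP; rows indexed by i (A), columns by j (B)
    M_rows: list[dict[int, float]] = [dict() for _ in range(la + 1)]
    X_rows: list[dict[int, float]] = [dict() for _ in range(la + 1)]  # gap in B
    Y_rows: list[dict[int, float]] = [dict() for _ in range(la + 1)]  # gap in A
    V_rows: list[dict[int, float]] = [dict() for _ in range(la + 1)]
    V_rows[0][0] = 0.0
    best = 0.0
    best_cell = (0, 0)
    for i in range(1, la + 1):
        prevV = V_rows[i - 1]
        prevX = X_rows[i - 1]
        if not prevV:
            break
        lo = min(prevV)
        prev_hi = max(prevV)
        rowM, rowX, rowY, rowV = M_rows[i], X_rows[i], Y_rows[i], V_rows[i]
        j = lo
        while j <= lb:
            m = _NEG
            if j >= 1 and (j - 1) in prevV:
                m = prevV[j - 1] + scheme.score_pair(A[i - 1], B[j - 1])
            x = _NEG
            if j in prevV:
                x = prevV[j] + op + ext
            if j in prevX:
                x = max(x, prevX[j] + ext)
            y = _NEG
            if (j - 1) in rowV:
                y = rowV[j - 1] + op + ext
            if (j - 1) in rowY:
                y = max(y, rowY[j - 1] + ext)
            v = max(m, x, y)
            if v >= best - xdrop:
                rowM[j], rowX[j], rowY[j], rowV[j] = m, x, y, v
                if v > best:
                    best = v
                    best_cell = (i, j)
            elif j > prev_hi:
                # beyond the previous row's reach only within-row gap runs can
                # grow the window; once they fail the x-drop, stop the row
                break
            j += 1
        if not rowV:
            break
    # traceback from best_cell
    i, j = best_cell
    ops: list[str] = []
    if (i, j) != (0, 0):
        state = "V"
        while (i, j) != (0, 0):
            if state == "V":
                v = V_rows[i][j]
                if v == M_rows[i].get(j, _NEG):
                    state = "M"
                elif v == X_rows[i].get(j, _NEG):
                    state = "X"
                else:
                    state = "Y"
                continue
            if state == "M":
                ops.append("M")
                i, j = i - 1, j - 1
                state = "V"
            elif state == "X":
                x = X_rows[i][j]
                prev_x = X_rows[i - 1].get(j, _NEG)
                ops.append("I")
                if x == prev_x + ext:
                    i -= 1
                    state = "X"
                else:
                    i -= 1
                    state = "V"
            else:  # Y
                y = Y_rows[i][j]
                prev_y = Y_rows[i].get(j - 1, _NEG)
                ops.append("D")
                if y == prev_y + ext:
                    j -= 1
                    state = "Y"
                else:
                    j -= 1
                    state = "V"
    ops.reverse()
    return int(round(best)), best_cell[0], best_cell[1], ops


@dataclass(frozen=True)
class Hsp:
    """One local alignment (high-scoring segment pair) of query vs genome.

    Coordinates are 0-based half-open; subject coordinates are always on the
    contig's forward strand.  For minus-strand hits ``s_aln`` holds the
    reverse-complemented subject slice so both alignment strings read in
    query orientation.
    """

    genome_id: str
    contig: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    raw_score: int
    bit_score: float
    evalue: float
    pct_identity: float
    coverage: float
    q_aln: str
    s_aln: str

    @property
    def aln_query_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def n_mismatch(self) -> int:
        return sum(
            1
            for a, b in zip(self.q_aln, self.s_aln)
            if a != "-" and b != "-" and (a != b or a == "N")
        )

    @property
    def n_gap_openings(self) -> int:
        n = 0
        for aln in (self.q_aln, self.s_aln):
            prev = ""
            for ch in aln:
                if ch == "-" and prev != "-":
                    n += 1
                prev = ch
        return n


def _ops_to_alignment(ops: list[str], q: str, s: str) -> tuple[str, str]:
    qa, sa = [], []
    qi = si = 0
    for o in ops:
        if o == "M":
            qa.append(q[qi])
            sa.append(s[si])
            qi += 1
            si += 1
        elif o == "I":
            qa.append(q[qi])
            sa.append("-")
            qi += 1
        else:
            qa.append("-")
            sa.append(s[si])
            si += 1
    return "".join(qa), "".join(sa)


def extend_hit(
    seed: tuple[int, str, int, str],
    query: QueryElement,
    genome: GenomeRecord,
    scheme: ScoringScheme,
    xdrop: float = DEFAULT_XDROP,
    min_raw_score: int = MIN_RAW_SCORE,
    db_length: int | None = None,
) -> Hsp | None:
    """Banded affine-gap X-drop extension in both directions from a seed.

    Returns the locally optimal :class:`Hsp` containing the seed start, or
    None when the best extension scores below ``min_raw_score``.
    """
    q_pos, contig_name, s_pos, strand = seed
    contig_seq = dict(genome.contigs)[contig_name]
    subj = contig_seq if strand == "+" else reverse_complement(contig_seq)
    q = query.seq
    # rightward from the seed start pair inclusive
    r_score, r_i, r_j, r_ops = _xdrop_extend_one_way(
        q[q_pos:], subj[s_pos:], scheme, xdrop
    )
    # leftward over the reversed prefixes
    l_score, l_i, l_j, l_ops = _xdrop_extend_one_way(
        q[:q_pos][::-1], subj[:s_pos][::-1], scheme, xdrop
    )
    raw = r_score + l_score
    if raw < min_raw_score:
        return None
    q_start, q_end = q_pos - l_i, q_pos + r_i
    ss_start, ss_end = s_pos - l_j, s_pos + r_j  # stranded coordinates
    ops = [o for o in reversed(l_ops)] + r_ops
    q_aln, s_aln = _ops_to_alignment(ops, q[q_start:q_end], subj[ss_start:ss_end])
    L = len(contig_seq)
    if strand == "+":
        s_start, s_end = ss_start, ss_end
    else:
        s_start, s_end = L - ss_end, L - ss_start
    n_cols = len(q_aln)
    matches = sum(1 for a, b in zip(q_aln, s_aln) if a == b and a != "-" and a != "N")
    bit = scheme.bit_score(raw)
    n = db_length if db_length is not None else genome.total_length
    return Hsp(
        genome_id=genome.genome_id,
        contig=contig_name,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        strand=strand,
        raw_score=raw,
        bit_score=bit,
        evalue=evalue(bit, query.length, n),
        pct_identity=100.0 * matches / n_cols if n_cols else 0.0,
        coverage=(q_end - q_start) / query.length,
        q_aln=q_aln,
        s_aln=s_aln,
    )


def search_genome(
    query: QueryElement,
    genome: GenomeRecord,
    scheme: ScoringScheme | None = None,
    xdrop: float = DEFAULT_XDROP,
    min_raw_score: int = MIN_RAW_SCORE,
    db_length: int | None = None,
) -> list[Hsp]:
    """Seed, extend and deduplicate all HSPs of the query against one genome.

    Seeds whose start pair lies on the alignment path of an already-reported
    HSP are skipped (they would rediscover the same local optimum); the
    surviving HSPs are returned sorted by descending bit score.
    """
    scheme = scheme or ScoringScheme()
    index = build_index(genome)
    seeds = find_seeds(query, index)
    covered: dict[tuple[str, str], set[tuple[int, int]]] = {}
    hsps: list[Hsp] = []
    for seed in seeds:
        q_pos, contig, s_pos, strand = seed
        pairs = covered.get((contig, strand))
        if pairs and (q_pos, s_pos) in pairs:
            continue
        hsp = extend_hit(seed, query, genome, scheme, xdrop, min_raw_score, db_length)
        if hsp is None:
            continue
        # record the aligned (query, stranded-subject) pairs of the path
        L = index.contig_lengths[contig]
        if strand == "+":
            si = hsp.s_start
        else:
            si = L - hsp.s_end
        qi = hsp.q_start
        pairset = covered.setdefault((contig, strand), set())
        for a, b in zip(hsp.q_aln, hsp.s_aln):
            if a != "-" and b != "-":
                pairset.add((qi, si))
            if a != "-":
                qi += 1
            if b != "-":
                si += 1
        if any(
            h.contig == hsp.contig
            and h.strand == hsp.strand
            and h.q_start == hsp.q_start
            and h.q_end == hsp.q_end
            and h.s_start == hsp.s_start
            and h.s_end == hsp.s_end
            for h in hsps
        ):
            continue
        hsps.append(hsp)
    hsps.sort(key=_rank_key)
    return hsps


# ---------------------------------------------------------------------------
# filtering and ortholog selection


@dataclass(frozen=True)
class FilterConfig:
    """Hit-retention thresholds and per-genome ortholog policy.

    Defaults mirror the workflow's stated defaults: E-value at most 1e-5 and
    query coverage (aligned query fraction) at least 0.3; no identity floor.
    """

    max_evalue: float = 1e-5
    min_coverage: float = 0.3
    min_pct_identity: float = 0.0
    ortholog_mode: str = "best"  # best | all | top_k
    k: int = 1

    def __post_init__(self):
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ValueError("min_coverage must lie in [0, 1]")
        if self.ortholog_mode not in ("best", "all", "top_k"):
            raise ValueError(f"unknown ortholog_mode {self.ortholog_mode!r}")
        if self.ortholog_mode == "top_k" and self.k < 1:
            raise ValueError("k must be a positive integer")


def filter_hits(hsps: Iterable[Hsp], cfg: FilterConfig) -> list[Hsp]:
    """Keep hits meeting all three thresholds; input order preserved."""
    return [
        h
        for h in hsps
        if h.evalue <= cfg.max_evalue
        and h.coverage >= cfg.min_coverage
        and h.pct_identity >= cfg.min_pct_identity
    ]


def _rank_key(h: Hsp):
    # highest bit score, then lowest E-value, then smallest s_start, then contig
    return (-h.bit_score, h.evalue, h.s_start, h.contig)


def select_orthologs(
    hsps_by_genome: Mapping[str, list[Hsp]], cfg: FilterConfig
) -> dict[str, list[Hsp]]:
    """Apply the ortholog policy per genome (best / all / top_k).

    Genomes with zero surviving hits are absent from the result (and noted
    in the run log).
    """
    out: dict[str, list[Hsp]] = {}
    for genome_id, hits in hsps_by_genome.items():
        if not hits:
            log.info("genome %s: no hits survive filtering", genome_id)
            continue
        ranked = sorted(hits, key=_rank_key)
        if cfg.ortholog_mode == "best":
            out[genome_id] = ranked[:1]
        elif cfg.ortholog_mode == "top_k":
            out[genome_id] = ranked[: cfg.k]
        else:
            out[genome_id] = ranked
    return out


# ---------------------------------------------------------------------------
# hit log

_LOG_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore retained"
).split()


def write_hit_log(
    all_hsps: Iterable[Hsp],
    retained: Iterable[Hsp],
    path: str | Path,
    query_id: str = "query",
) -> None:
    """Tab-delimited hit log in BLAST outfmt-6-like column order.

    Coordinates are 1-based inclusive; minus-strand subject coordinates are
    written start > end, following the BLAST tabular convention.  A final
    ``retained`` 0/1 column marks hits surviving filtering and selection.
    """
    retained_set = set(id(h) for h in retained)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_LOG_COLUMNS) + "\n")
        for h in all_hsps:
            if h.strand == "+":
                sstart, send = h.s_start + 1, h.s_end
            else:
                sstart, send = h.s_end, h.s_start + 1
            fields = [
                query_id,
                f"{h.genome_id}:{h.contig}",
                f"{h.pct_identity:.3f}",
                str(len(h.q_aln)),
                str(h.n_mismatch),
                str(h.n_gap_openings),
                str(h.q_start + 1),
                str(h.q_end),
                str(sstart),
                str(send),
                f"{h.evalue:.2e}",
                f"{h.bit_score:.1f}",
                "1" if id(h) in retained_set else "0",
            ]
            fh.write("\t".join(fields) + "\n")
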
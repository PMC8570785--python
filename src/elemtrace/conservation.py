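"""Per-column conservation scores and conserved-element calls.

A deliberately simple, phylogeny-free stand-in for a phylo-HMM conservation
caller: each alignment column scores as (modal-base frequency among real
bases) x (fraction of rows that are non-gap), and a two-state HMM with
Gaussian emissions segments the score track into conserved elements by
Viterbi decoding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .msa import GAP, Msa
from .sequence_io import DataError

P_HIGH_DEFAULT = 0.9
P_LOW_DEFAULT = 0.5
SWITCH_PROB_DEFAULT = 0.01
EMISSION_SD = 0.15


@dataclass
class ConservedElement:
    """One conserved segment, 0-based half-open in alignment columns."""

    start: int
    end: int
    mean_score: float

    def __post_init__(self):
        if self.end <= self.start:
            raise DataError("element end must exceed start")


def column_score(msa: Msa) -> np.ndarray:
    """Conservation track in [0, 1], one value per alignment column.

    score = (modal real-base count / total rows) x (non-gap rows / total
    rows), where "real" excludes gaps and N.  A column with at most one
    contributing real base degenerates to the gap fraction alone (modal
    frequency 1), so a lone unaligned base is scored by coverage only.
    """
    if msa.n_rows < 2:
        raise DataError("conservation scoring needs at least two rows")
    mat = msa.to_matrix()
    n_rows = msa.n_rows
    scores = np.empty(msa.n_cols)
    gap = GAP.encode()
    n_char = b"N"
    for c in range(msa.n_cols):
        col = mat[:, c]
        non_gap = col != gap
        real = non_gap & (col != n_char)
        frac_non_gap = non_gap.sum() / n_rows
        if real.sum() <= 1:
            modal_freq = 1.0
        else:
            _, counts = np.unique(col[real], return_counts=True)
            modal_freq = counts.max() / n_rows
        scores[c] = modal_freq * frac_non_gap
    return scores


def call_elements(
    track: np.ndarray,
    p_high: float = P_HIGH_DEFAULT,
    p_low: float = P_LOW_DEFAULT,
    switch_prob: float = SWITCH_PROB_DEFAULT,
    sd: float = EMISSION_SD,
) -> list[ConservedElement]:
    """Viterbi segmentation of the score track into conserved elements.

    Two hidden states (neutral, conserved) with Gaussian emissions centred
    at ``p_low`` and ``p_high`` (shared ``sd``), symmetric switch
    probability and a uniform initial distribution.  Score ties are broken
    toward the neutral state.  Maximal runs of the conserved state become
    elements.
    """
    track = np.asarray(track, dtype=float)
    n = len(track)
    if n == 0:
        return []
    means = np.array([p_low, p_high])  # state 0 neutral, state 1 conserved
    log_emit = (
        -0.5 * ((track[:, None] - means[None, :]) / sd) ** 2
        - math.log(sd * math.sqrt(2 * math.pi))
    )
    log_stay = math.log(1.0 - switch_prob)
    log_switch = math.log(switch_prob)
    trans = np.array([[log_stay, log_switch], [log_switch, log_stay]])
    v = np.full((n, 2), -np.inf)
    back = np.zeros((n, 2), dtype=np.int8)
    v[0] = math.log(0.5) + log_emit[0]
    for t in range(1, n):
        for s in (0, 1):
            cand = v[t - 1] + trans[:, s]
            # ties broken toward neutral (state 0): >= keeps the earlier index
            prev = 0 if cand[0] >= cand[1] else 1
            back[t, s] = prev
            v[t, s] = cand[prev] + log_emit[t, s]
    state = 0 if v[n - 1, 0] >= v[n - 1, 1] else 1
    path = np.empty(n, dtype=np.int8)
    path[n - 1] = state
    for t in range(n - 1, 0, -1):
        state = back[t, state]
        path[t - 1] = state
    elements: list[ConservedElement] = []
    start = None
    for t in range(n):
        if path[t] == 1 and start is None:
            start = t
        elif path[t] == 0 and start is not None:
            elements.append(
                ConservedElement(start, t, float(track[start:t].mean()))
            )
            start = None
    if start is not None:
        elements.append(ConservedElement(start, n, float(track[start:].mean())))
    return elements


def project_to_query(
    elements: list[ConservedElement], msa: Msa, query_label: str | None = None
) -> list[ConservedElement]:
    """Re-express elements in ungapped query coordinates.

    Alignment columns where the query row is gapped are skipped; elements
    entirely inside a query gap are dropped.
    """
    label = query_label or msa.rows[0][0]
    query_row = dict(msa.rows)[label]
    # query position at/after each column
    pos = 0
    col_to_q = []
    for ch in query_row:
        col_to_q.append(pos)
        if ch != GAP:
            pos += 1
    q_len = pos
    out: list[ConservedElement] = []
    for el in elements:
        q_start = col_to_q[el.start]
        q_end = col_to_q[el.end] if el.end < len(col_to_q) else q_len
        if q_end > q_start:
            out.append(ConservedElement(q_start, q_end, el.mean_score))
    return out


def write_bed(
    elements: list[ConservedElement],
    track: np.ndarray,
    contig_name: str,
    path: str | Path,
    scores_path: str | Path | None = None,
) -> None:
    """BED4 of elements plus an optional per-column score TSV companion.

    BED coordinates are 0-based half-open; the fourth column is the mean
    conservation score of the element.
    """
    with open(path, "w") as fh:
        for el in elements:
            fh.write(f"{contig_name}\t{el.start}\t{el.end}\t{el.mean_score:.3f}\n")
    if scores_path is not None:
        with open(scores_path, "w") as fh:
            fh.write("column\tscore\n")
            for i, s in enumerate(np.asarray(track, dtype=float)):
                fh.write(f"{i}\t{s:.6f}\n")


def read_bed(path: str | Path) -> list[ConservedElement]:
    """Parse a BED4 file written by :func:`write_bed`."""
    out: list[ConservedElement] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            out.append(
                ConservedElement(int(fields[1]), int(fields[2]), float(fields[3]))
            )
    return out
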
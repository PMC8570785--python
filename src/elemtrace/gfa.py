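"""Convert a multiple sequence alignment into a GFA 1.0 variation graph.

Alignment columns are partitioned into maximal runs with an identical
row-presence-and-base pattern; each distinct row subsequence within a run
becomes one segment, consecutive segments on a row are linked, and every
row is emitted as a path, so each path respells its original ungapped
sequence.  Deletions appear as links that skip a segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .msa import GAP, Msa
from .sequence_io import DataError

Link = tuple[int, str, int, str, str]  # (from, orient, to, orient, overlap)


@dataclass
class GfaGraph:
    """Segments, links and per-row paths of a variation graph.

    All orientations are "+" (every MSA row reads in the same direction) and
    overlaps are "0M".  Segment ids are 1-based integers in left-to-right
    discovery order.
    """

    segments: list[tuple[int, str]] = field(default_factory=list)
    links: set[Link] = field(default_factory=set)
    paths: list[tuple[str, list[tuple[int, str]]]] = field(default_factory=list)

    def segment_seq(self, seg_id: int) -> str:
        for sid, seq in self.segments:
            if sid == seg_id:
                return seq
        raise KeyError(seg_id)


def _column_key(col: str) -> tuple:
    """Presence-and-base pattern of one alignment column.

    Rows are keyed by (tuple of non-gap row indices, per-row base-equality
    class ids assigned in first-occurrence order).
    """
    present = tuple(i for i, c in enumerate(col) if c != GAP)
    groups: dict[str, int] = {}
    classes = []
    for i in present:
        classes.append(groups.setdefault(col[i], len(groups)))
    return present, tuple(classes)


def msa_to_gfa(msa: Msa) -> GfaGraph:
    """Partition the alignment into blocks and emit the variation graph."""
    seqs = [seq for _, seq in msa.rows]
    labels = msa.labels
    n_rows, n_cols = msa.n_rows, msa.n_cols

    # maximal runs of columns with identical presence/base pattern
    blocks: list[tuple[int, int]] = []
    start = 0
    prev_key = None
    for c in range(n_cols):
        key = _column_key("".join(s[c] for s in seqs))
        if prev_key is None:
            prev_key = key
        elif key != prev_key:
            blocks.append((start, c))
            start = c
            prev_key = key
    blocks.append((start, n_cols))

    graph = GfaGraph()
    row_paths: list[list[int]] = [[] for _ in range(n_rows)]
    next_id = 1
    for b_start, b_end in blocks:
        # rows sharing a base-equality class spell the same gapless string
        by_string: dict[str, int] = {}
        for r in range(n_rows):
            sub = seqs[r][b_start:b_end]
            if GAP in sub:
                continue  # row skips this block entirely (pattern is uniform)
            if sub not in by_string:
                by_string[sub] = next_id
                graph.segments.append((next_id, sub))
                next_id += 1
            row_paths[r].append(by_string[sub])

    for r in range(n_rows):
        path = row_paths[r]
        for a, b in zip(path, path[1:]):
            graph.links.add((a, "+", b, "+", "0M"))
        graph.paths.append((labels[r], [(sid, "+") for sid in path]))
    return graph


def validate_paths(graph: GfaGraph, originals: dict[str, str]) -> bool:
    """True iff every path respells its original and every link/segment is used.

    ``originals`` maps path name to the ungapped input sequence; a missing
    label raises :class:`DataError`.
    """
    seqs = dict(graph.segments)
    used_links: set[Link] = set()
    used_segments: set[int] = set()
    for name, steps in graph.paths:
        if name not in originals:
            raise DataError(f"no original sequence for path {name!r}")
        spelled = "".join(seqs[sid] for sid, _ in steps)
        if spelled != originals[name]:
            return False
        for (a, ao), (b, bo) in zip(steps, steps[1:]):
            used_links.add((a, ao, b, bo, "0M"))
        used_segments.update(sid for sid, _ in steps)
    if used_links != graph.links:
        return False
    if used_segments != set(seqs):
        return False
    return True


def write_gfa(graph: GfaGraph, path: str | Path) -> None:
    """Serialize as GFA 1.0 (H/S/L/P records, loadable by BANDAGE-style viewers)."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for sid, seq in graph.segments:
            fh.write(f"S\t{sid}\t{seq}\n")
        for a, ao, b, bo, ov in sorted(graph.links):
            fh.write(f"L\t{a}\t{ao}\t{b}\t{bo}\t{ov}\n")
        for name, steps in graph.paths:
            walk = ",".join(f"{sid}{orient}" for sid, orient in steps)
            fh.write(f"P\t{name}\t{walk}\t*\n")


def read_gfa(path: str | Path) -> GfaGraph:
    """Parse a GFA 1.0 file written by :func:`write_gfa`."""
    graph = GfaGraph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "H":
                continue
            if tag == "S":
                if len(fields) < 3:
                    raise DataError(f"{path}: malformed S line at {lineno}")
                graph.segments.append((int(fields[1]), fields[2]))
            elif tag == "L":
                if len(fields) < 6:
                    raise DataError(f"{path}: malformed L line at {lineno}")
                graph.links.add(
                    (int(fields[1]), fields[2], int(fields[3]), fields[4], fields[5])
                )
            elif tag == "P":
                if len(fields) < 3:
                    raise DataError(f"{path}: malformed P line at {lineno}")
                steps = []
                for step in fields[2].split(","):
                    steps.append((int(step[:-1]), step[-1]))
                graph.paths.append((fields[1], steps))
    return graph
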
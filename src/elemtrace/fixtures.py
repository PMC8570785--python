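"""Synthetic genomes with known evolutionary structure.

Evolves the query element along a given tree (substitutions under
GTR+Gamma, site rates drawn once at the root), optionally excises a
clade-specific deletion — emulating the benchmark element, a limb enhancer
that carries a 17-nt deletion in snakes — and embeds each diverged copy at
a random position in i.i.d. uniform background sequence.  Everything is
deterministic given the seed, with one named RNG substream per genome.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .phylo import GtrGammaModel, PhyloTree, TreeNode, parse_newick
from .sequence_io import GenomeRecord, QueryElement, write_fasta
from .sequence_io import DataError

log = logging.getLogger("elemtrace")

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

DELETION_LENGTH_DEFAULT = 17


@dataclass
class SimSpec:
    """Full description of one synthetic study.

    ``deletion_span`` is (start, length) on the query, applied after
    substitution to every leaf in ``deletion_clade``.  ``background_length``
    is the total genome length; the diverged element overwrites a random
    window of the background.
    """

    query: QueryElement
    tree: PhyloTree
    model: GtrGammaModel
    seed: int
    deletion_clade: frozenset = frozenset()
    deletion_span: tuple[int, int] = (0, DELETION_LENGTH_DEFAULT)
    background_length: int = 10_000
    copies: int = 1

    def __post_init__(self):
        start, length = self.deletion_span
        if self.deletion_clade and not (
            0 <= start and start + length <= self.query.length
        ):
            raise DataError("deletion span exceeds query bounds")
        missing = self.deletion_clade - set(self.tree.leaf_labels())
        if missing:
            raise DataError(f"deletion clade labels not in tree: {sorted(missing)}")


def _seq_to_codes(seq: str, rng: np.random.Generator) -> np.ndarray:
    codes = np.array([_CODE.get(ch, -1) for ch in seq], dtype=np.int64)
    n_mask = codes < 0
    if n_mask.any():  # N in the root: substitute a random base for simulation
        codes[n_mask] = rng.integers(0, 4, size=int(n_mask.sum()))
    return codes


def _codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def evolve_along_tree(spec: SimSpec) -> dict[str, str]:
    """Simulate the diverged element of every leaf.

    The root sequence is the query; along each edge every site substitutes
    according to P(t * site_rate), with site rate categories drawn once at
    the root from the discrete gamma.  Leaves in the deletion clade have the
    deletion span excised after substitution.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    root_codes = _seq_to_codes(spec.query.seq, rng)
    L = len(root_codes)
    rates = spec.model.category_rates
    site_cat = rng.integers(0, len(rates), size=L)
    out: dict[str, str] = {}

    def walk(node: TreeNode, codes: np.ndarray):
        for child in node.children:
            t = child.length or 0.0
            child_codes = codes.copy()
            if t > 0:
                for c, rate in enumerate(rates):
                    sites = np.where(site_cat == c)[0]
                    if sites.size == 0:
                        continue
                    P = spec.model.transition_matrix(t * rate)
                    cum = np.cumsum(P, axis=1)
                    u = rng.random(sites.size)
                    rows = cum[codes[sites]]
                    child_codes[sites] = (u[:, None] < rows).argmax(axis=1)
            if child.is_leaf:
                seq = _codes_to_seq(child_codes)
                if child.label in spec.deletion_clade:
                    start, length = spec.deletion_span
                    seq = seq[:start] + seq[start + length :]
                out[child.label] = seq
            else:
                walk(child, child_codes)

    walk(spec.tree.root, root_codes)
    return out


def embed_in_background(
    elements: dict[str, str],
    background_length: int,
    seed: int,
    copies: int = 1,
) -> tuple[list[GenomeRecord], dict[str, list[tuple[int, int]]]]:
    """Plant each element in uniform random background sequence.

    Each genome is ``background_length`` bases of i.i.d. uniform background
    with ``copies`` non-overlapping copies of its element written over
    random windows.  Returns the genomes (one contig each, named
    "<label>_chr") plus the true insertion intervals for assertions.
    """
    genomes: list[GenomeRecord] = []
    truth: dict[str, list[tuple[int, int]]] = {}
    for g_index, (label, element) in enumerate(sorted(elements.items())):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(1, g_index))
        )
        elen = len(element)
        glen = max(background_length, elen * copies)
        codes = rng.integers(0, 4, size=glen)
        seq = _codes_to_seq(codes)
        spans: list[tuple[int, int]] = []
        for _ in range(copies):
            for _attempt in range(1000):
                start = int(rng.integers(0, glen - elen + 1))
                if all(start + elen <= s or start >= e for s, e in spans):
                    break
            else:
                raise DataError("could not place non-overlapping element copies")
            seq = seq[:start] + element + seq[start + elen :]
            spans.append((start, start + elen))
        genomes.append(
            GenomeRecord(genome_id=label, contigs=[(f"{label}_chr", seq)])
        )
        truth[label] = sorted(spans)
    return genomes, truth


def simulate_genomes(spec: SimSpec):
    """Evolve the query and embed every leaf's element; returns (genomes, truth)."""
    elements = evolve_along_tree(spec)
    return embed_in_background(
        elements, spec.background_length, spec.seed, spec.copies
    )


# ---------------------------------------------------------------------------
# demo preset: the benchmark shape (18 genomes, 4-leaf snake clade, 766-nt
# query, 17-nt clade deletion)

ZRS_DEMO_QUERY_LENGTH = 766
ZRS_DEMO_DELETION_START = 380
ZRS_DEMO_SNAKES = frozenset({"boa", "python", "cobra", "viper"})

# Shallow vertebrate-style tree: 14 ordinary genomes plus a 4-leaf snake
# clade; branch lengths are low (<= ~0.1 substitutions/site root-to-tip) so
# every ortholog stays recoverable by the default search thresholds.
ZRS_DEMO_NEWICK = (
    "((((human:0.01,chimp:0.01):0.01,macaque:0.02):0.02,"
    "((mouse:0.03,rat:0.03):0.02,rabbit:0.04):0.01):0.01,"
    "((((dog:0.02,cat:0.02):0.01,horse:0.03):0.01,(cow:0.03,pig:0.03):0.01):0.01,"
    "(elephant:0.04,(opossum:0.05,"
    "(chicken:0.05,((boa:0.01,python:0.01):0.01,(cobra:0.01,viper:0.01):0.01):0.04"
    "):0.02):0.01):0.01):0.01);"
)


def random_query(length: int, seed: int, label: str = "query") -> QueryElement:
    """A uniform random DNA query of the given length."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    return QueryElement(id=label, seq=_codes_to_seq(rng.integers(0, 4, size=length)))


def zrs_demo_spec(
    seed: int,
    background_length: int = 10_000,
    query: QueryElement | None = None,
) -> SimSpec:
    """The default demo: 18 genomes, snake clade with the 17-nt deletion."""
    if query is None:
        query = random_query(ZRS_DEMO_QUERY_LENGTH, seed)
    return SimSpec(
        query=query,
        tree=parse_newick(ZRS_DEMO_NEWICK),
        model=GtrGammaModel(),
        seed=seed,
        deletion_clade=ZRS_DEMO_SNAKES,
        deletion_span=(ZRS_DEMO_DELETION_START, DELETION_LENGTH_DEFAULT),
        background_length=background_length,
    )


def write_simulation(
    spec: SimSpec, outdir: str | Path
) -> dict[str, object]:
    """Write genomes as FASTA plus the query and a JSON truth sidecar.

    Returns the truth dictionary (query path, genome paths, insertion
    coordinates, tree, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes, truth = simulate_genomes(spec)
    query_path = outdir / "query.fasta"
    write_fasta([(spec.query.id, spec.query.seq)], query_path)
    genome_paths = {}
    for genome in genomes:
        path = outdir / f"{genome.genome_id}.fasta"
        write_fasta(genome.contigs, path)
        genome_paths[genome.genome_id] = str(path)
    sidecar = {
        "seed": spec.seed,
        "query": str(query_path),
        "query_length": spec.query.length,
        "tree": spec.tree.newick(),
        "deletion_clade": sorted(spec.deletion_clade),
        "deletion_span": list(spec.deletion_span),
        "background_length": spec.background_length,
        "genomes": genome_paths,
        "insertions": {k: [list(span) for span in v] for k, v in truth.items()},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return sidecar
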
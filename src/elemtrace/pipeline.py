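"""End-to-end orchestration: search -> MSA -> GFA -> tree -> conservation.

Runs every stage with one configuration and a stable output layout:

    out/{hits.tsv, msa.fasta, msa.phy, graph.gfa, tree_best.nwk,
         tree_support.nwk, tree_bootstraps.nwk, tree_info.txt,
         conserved.bed, scores.tsv, report.json, run.log}

Every output is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import conservation as cons
from . import gfa as gfa_mod
from . import msa as msa_mod
from . import phylo
from . import search as search_mod
from .search import FilterConfig, ScoringScheme
from .sequence_io import (
    DataError,
    GenomeRecord,
    load_query,
    read_genome,
    reverse_complement,
    write_fasta,
    write_phylip,
)

log = logging.getLogger("elemtrace")


@dataclass
class RunConfig:
    """All knobs of one run; defaults mirror the per-stage defaults."""

    max_evalue: float = 1e-5
    min_coverage: float = 0.3
    min_pct_identity: float = 0.0
    ortholog_mode: str = "best"
    k: int = 1
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    xdrop: float = search_mod.DEFAULT_XDROP
    min_raw_score: int = search_mod.MIN_RAW_SCORE
    msa_k: int = msa_mod.DEFAULT_K
    alpha: float = 1.0
    n_categories: int = 4
    n_bootstrap: int = 100
    seed: int = 0
    p_high: float = cons.P_HIGH_DEFAULT
    p_low: float = cons.P_LOW_DEFAULT
    switch_prob: float = cons.SWITCH_PROB_DEFAULT

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            max_evalue=self.max_evalue,
            min_coverage=self.min_coverage,
            min_pct_identity=self.min_pct_identity,
            ortholog_mode=self.ortholog_mode,
            k=self.k,
        )

    def scoring_scheme(self) -> ScoringScheme:
        return ScoringScheme(
            match=self.match,
            mismatch=self.mismatch,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    seed: int
    config: dict
    query_id: str
    query_length: int
    genome_stats: dict
    n_genomes_retained: int
    msa_rows: int = 0
    msa_cols: int = 0
    n_segments: int = 0
    n_links: int = 0
    n_conserved_elements: int = 0
    files: dict = field(default_factory=dict)
    stopped_after_search: bool = False

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _extract_homologs(
    selected: dict[str, list[search_mod.Hsp]],
    genomes: dict[str, GenomeRecord],
    multi: bool,
) -> list[tuple[str, str]]:
    """Query-oriented homolog sequences, one row per retained hit.

    Minus-strand hits are reverse-complemented so all rows read in query
    orientation.  Rows are labeled genome_id, or genome_id_1.. in hit-rank
    order when a genome keeps several hits.
    """
    rows: list[tuple[str, str]] = []
    for genome_id in sorted(selected):
        contigs = dict(genomes[genome_id].contigs)
        hits = selected[genome_id]
        for rank, hsp in enumerate(hits, start=1):
            seq = contigs[hsp.contig][hsp.s_start : hsp.s_end]
            if hsp.strand == "-":
                seq = reverse_complement(seq)
            label = f"{genome_id}_{rank}" if (multi and len(hits) > 1) else genome_id
            rows.append((label, seq))
    return rows


def run_pipeline(
    query_path: str | Path,
    genome_paths: list[str | Path],
    config: RunConfig,
    outdir: str | Path,
) -> RunReport:
    """Execute the full workflow; see the module docstring for the layout.

    Unreadable genome files are logged and skipped.  If fewer than two
    genomes retain a hit the run stops after the search stage with a clear
    report and no downstream files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(query_path, genome_paths, config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(query_path, genome_paths, config: RunConfig, outdir: Path) -> RunReport:
    query = load_query(query_path)
    log.info("query %s: %d nt", query.id, query.length)

    genomes: dict[str, GenomeRecord] = {}
    for path in sorted(map(str, genome_paths)):
        try:
            g = read_genome(path)
        except (OSError, DataError) as exc:
            log.error("skipping genome file %s: %s", path, exc)
            continue
        if g.genome_id in genomes:
            log.error("duplicate genome id %s from %s; skipping", g.genome_id, path)
            continue
        genomes[g.genome_id] = g
    if not genomes:
        raise DataError("no readable genome files")

    scheme = config.scoring_scheme()
    fcfg = config.filter_config()
    db_length = sum(g.total_length for g in genomes.values())

    all_hsps: list[search_mod.Hsp] = []
    filtered_by_genome: dict[str, list[search_mod.Hsp]] = {}
    genome_stats: dict[str, dict] = {}
    for genome_id in sorted(genomes):
        hsps = search_mod.search_genome(
            query,
            genomes[genome_id],
            scheme,
            xdrop=config.xdrop,
            min_raw_score=config.min_raw_score,
            db_length=db_length,
        )
        kept = search_mod.filter_hits(hsps, fcfg)
        all_hsps.extend(hsps)
        filtered_by_genome[genome_id] = kept
        genome_stats[genome_id] = {
            "n_hsps": len(hsps),
            "n_pass_filter": len(kept),
            "best_evalue": min((h.evalue for h in kept), default=None),
            "best_bit_score": max((h.bit_score for h in kept), default=None),
        }
        log.info("genome %s: %d HSPs, %d pass filters", genome_id, len(hsps), len(kept))

    selected = search_mod.select_orthologs(filtered_by_genome, fcfg)
    retained = [h for hits in selected.values() for h in hits]
    for genome_id, stats in genome_stats.items():
        stats["n_retained"] = len(selected.get(genome_id, []))

    hits_path = outdir / "hits.tsv"
    search_mod.write_hit_log(all_hsps, retained, hits_path, query_id=query.id)

    report = RunReport(
        seed=config.seed,
        config=dataclasses.asdict(config),
        query_id=query.id,
        query_length=query.length,
        genome_stats=genome_stats,
        n_genomes_retained=len(selected),
        files={"hits": str(hits_path)},
    )

    if len(selected) < 2:
        log.warning(
            "only %d genome(s) retained a hit; stopping after search", len(selected)
        )
        report.stopped_after_search = True
        report.to_json(outdir / "report.json")
        report.files["report"] = str(outdir / "report.json")
        return report

    # ---- multiple sequence alignment
    homologs = _extract_homologs(
        selected, genomes, multi=config.ortholog_mode != "best"
    )
    seqs = [(query.id, query.seq)] + homologs
    alignment = msa_mod.build_msa(seqs, scheme, k=config.msa_k)
    msa_path = outdir / "msa.fasta"
    phy_path = outdir / "msa.phy"
    write_fasta(alignment.rows, msa_path)
    write_phylip(alignment, phy_path)
    report.msa_rows = alignment.n_rows
    report.msa_cols = alignment.n_cols
    report.files.update({"msa_fasta": str(msa_path), "msa_phylip": str(phy_path)})

    # ---- variation graph
    graph = gfa_mod.msa_to_gfa(alignment)
    originals = {name: seq.replace(msa_mod.GAP, "") for name, seq in alignment.rows}
    if not gfa_mod.validate_paths(graph, originals):
        raise DataError("internal error: GFA paths do not respell the alignment rows")
    gfa_path = outdir / "graph.gfa"
    gfa_mod.write_gfa(graph, gfa_path)
    report.n_segments = len(graph.segments)
    report.n_links = len(graph.links)
    report.files["gfa"] = str(gfa_path)

    # ---- phylogeny with bootstrap
    model = phylo.GtrGammaModel.from_msa(
        alignment, alpha=config.alpha, n_categories=config.n_categories
    )
    result = phylo.bootstrap_support(
        alignment, model, n_replicates=config.n_bootstrap, seed=config.seed
    )
    tree_files = phylo.write_tree_files(result, outdir)
    report.files.update(tree_files)

    # ---- conservation
    track = cons.column_score(alignment)
    elements = cons.call_elements(
        track,
        p_high=config.p_high,
        p_low=config.p_low,
        switch_prob=config.switch_prob,
    )
    bed_path = outdir / "conserved.bed"
    scores_path = outdir / "scores.tsv"
    cons.write_bed(elements, track, query.id, bed_path, scores_path)
    report.n_conserved_elements = len(elements)
    report.files.update({"bed": str(bed_path), "scores": str(scores_path)})

    report.to_json(outdir / "report.json")
    report.files["report"] = str(outdir / "report.json")
    log.info(
        "done: %d rows x %d cols, %d segments, %d conserved elements",
        report.msa_rows,
        report.msa_cols,
        report.n_segments,
        report.n_conserved_elements,
    )
    return report
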
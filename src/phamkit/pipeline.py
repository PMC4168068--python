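"""End-to-end orchestration: config in, report tables out.

run_pipeline executes genome stats -> all-vs-all protein similarity ->
pham clustering and its tables -> core-gene matrix and 40% grouping ->
optional terminase NJ tree and packaging calls -> optional morphology
summaries, writing each module's table plus a run manifest. Outputs are
write-once; rerunning the same config into a fresh directory reproduces
the bundle byte for byte (no timestamps are recorded).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .core_genes import CoreScoreParams, core_percentage_matrix, group_by_core_threshold
from .genome_io import Genome, read_genbank, stats_table
from .morphology import read_measurements_tsv, summary_table
from .phams import (
    PhamThresholds,
    build_similarity_graph,
    cluster_phams,
    edges_to_frame,
    genome_map_data,
    partition_to_frame,
    pham_domain_coverage,
    pham_summary,
    shared_pham_table,
)
from .phylogeny import (
    infer_packaging,
    neighbor_joining,
    packaging_to_frame,
    terminase_distances,
    tree_to_newick,
)
from .similarity import ScoringParams
from .synthetic import CohortParams, generate_cohort

log = logging.getLogger("phamkit")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    genomes_dir: str | None = None
    simulate: dict | None = None  # CohortParams fields; used when no genomes_dir
    domains_tsv: str | None = None
    measurements_tsv: str | None = None
    terminases_tsv: str | None = None  # columns: phage, gene_id
    known_packaging_tsv: str | None = None  # columns: phage, strategy
    focal_group: list[str] | None = None
    evalue_max: float = 1e-50
    identity_min_pct: float = 32.5
    core_score_threshold: float = 75.0
    core_group_cutoff_pct: float = 40.0
    out_dir: str = "phamkit_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _write_text(path: Path, text: str) -> None:
    if path.exists():
        raise PipelineError(f"refusing to overwrite existing output {path}")
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)


def _write_frame(path: Path, frame, index: bool = False) -> None:
    _write_text(path, frame.to_csv(sep="\t", index=index))


def load_genomes(config: PipelineConfig) -> list[Genome]:
    if config.genomes_dir:
        paths = sorted(Path(config.genomes_dir).glob("*.gb*"))
        if len(paths) < 1:
            raise PipelineError(f"no GenBank files under {config.genomes_dir}")
        return [read_genbank(p) for p in paths]
    sim = dict(config.simulate or {})
    sim.setdefault("seed", config.seed)
    genomes, _ = generate_cohort(CohortParams(**sim))
    return genomes


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns the manifest dict."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_echo = asdict(config)
    config_echo["out_dir"] = None  # run location, not part of the result
    manifest: dict = {
        "phamkit_version": __version__,
        "config": config_echo,
        "outputs": [],
    }

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"].append(name)
        log.info("wrote %s", path)

    try:
        genomes = load_genomes(config)
    except Exception as exc:
        raise PipelineError(f"stage load_genomes: {exc}") from exc
    if len(genomes) < 2:
        raise PipelineError("stage load_genomes: need at least two genomes")
    names = [g.name for g in genomes]
    phage_of = {gene.gene_id: g.name for g in genomes for gene in g.genes}

    try:
        emit("genome_stats.tsv", lambda p: _write_frame(p, stats_table(genomes)))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage genome_stats: {exc}") from exc

    thresholds = PhamThresholds(
        evalue_max=config.evalue_max, identity_min_pct=config.identity_min_pct
    )
    scoring = ScoringParams()
    try:
        proteins = [(gene.gene_id, gene.aa_seq) for g in genomes for gene in g.genes]
        edges = build_similarity_graph(proteins, thresholds, scoring)
        emit("edges.tsv", lambda p: _write_frame(p, edges_to_frame(edges)))
        partition = cluster_phams(edges, [gid for gid, _ in proteins])
        emit(
            "phams.tsv",
            lambda p: _write_frame(p, partition_to_frame(partition, phage_of)),
        )
        summary = pham_summary(partition)
        emit(
            "pham_summary.json",
            lambda p: _write_text(
                p, json.dumps(summary.__dict__, indent=2, sort_keys=True)
            ),
        )
        focal = set(config.focal_group or names)
        rows = shared_pham_table(partition, genomes, focal)
        import pandas as pd

        emit(
            "shared_phams.tsv",
            lambda p: _write_frame(p, pd.DataFrame([r.__dict__ for r in rows])),
        )
        maps = {g.name: genome_map_data(g, partition) for g in genomes}
        emit(
            "genome_maps.json",
            lambda p: _write_text(p, json.dumps(maps, indent=2, sort_keys=True)),
        )
        if config.domains_tsv:
            dom = pd.read_csv(config.domains_tsv, sep="\t")
            hits: dict[str, list[str]] = {}
            for _, row in dom.iterrows():
                hits.setdefault(str(row["protein_id"]), []).append(str(row["domain"]))
            emit(
                "domain_coverage.json",
                lambda p: _write_text(
                    p,
                    json.dumps(
                        {"pct_phams_with_domain": pham_domain_coverage(partition, hits)}
                    ),
                ),
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage pham_clustering: {exc}") from exc

    try:
        matrix = core_percentage_matrix(
            genomes, CoreScoreParams(config.core_score_threshold), scoring
        )
        emit("coregenes.tsv", lambda p: _write_frame(p, matrix.as_frame(), index=True))
        groups = group_by_core_threshold(matrix, config.core_group_cutoff_pct)
        emit(
            "core_groups.json",
            lambda p: _write_text(p, json.dumps(groups, indent=2)),
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage core_genes: {exc}") from exc

    if config.terminases_tsv:
        try:
            import pandas as pd

            term = pd.read_csv(config.terminases_tsv, sep="\t")
            terminase_ids = dict(zip(term["phage"].astype(str), term["gene_id"].astype(str)))
            seq_of = {gene.gene_id: gene.aa_seq for g in genomes for gene in g.genes}
            prots = [
                (phage, seq_of[gid])
                for phage, gid in sorted(terminase_ids.items())
                if gid in seq_of
            ]
            if len(prots) >= 3:
                tree = neighbor_joining(terminase_distances(prots, scoring))
                emit(
                    "terminase_tree.nwk",
                    lambda p: _write_text(p, tree_to_newick(tree) + "\n"),
                )
            known = {}
            if config.known_packaging_tsv:
                kp = pd.read_csv(config.known_packaging_tsv, sep="\t")
                known = dict(zip(kp["phage"].astype(str), kp["strategy"].astype(str)))
            calls = infer_packaging(partition, terminase_ids, known)
            emit(
                "packaging_calls.tsv",
                lambda p: _write_frame(
                    p, packaging_to_frame(calls, partition, terminase_ids)
                ),
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage terminase_phylogeny: {exc}") from exc

    if config.measurements_tsv:
        try:
            measurements = read_measurements_tsv(config.measurements_tsv)
            emit(
                "morphology_summary.tsv",
                lambda p: _write_frame(p, summary_table(measurements), index=True),
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage morphology: {exc}") from exc

    _write_text(out / "manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
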
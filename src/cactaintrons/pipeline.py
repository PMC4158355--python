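"""End-to-end orchestration of the boundary-evolution analysis.

A :class:`PipelineConfig` names the inputs and knobs; :func:`run_pipeline`
executes the stages that the inputs allow and writes all artifacts plus a
machine-readable ``summary.json`` and a ``MANIFEST`` into the output
directory:

* with an alignment, residue scores and exon models (or protein-space
  boundary annotations): trim -> coordinate maps -> projection;
* with a pre-projected boundary table: that table is consumed directly;
* always: pairwise distances, threshold derivation (when intron lengths
  are known) or the configured threshold, clustering, region calling,
  gap statistics, classification;
* with a tree: character matrix and parsimony reconstruction of
  ancestral intron configurations and gain/loss events.

Any stage error propagates with the stage name and input path; partial
outputs are retained and the MANIFEST marks the run incomplete.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from cactaintrons import annotate, io, project, reconstruct, regions, trim

log = logging.getLogger("cactaintrons")


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and parameters for a pipeline run."""

    out_dir: Path
    alignment: Optional[Path] = None
    scores: Optional[Path] = None
    exons: Optional[Path] = None
    boundary_table: Optional[Path] = None
    tree: Optional[Path] = None
    intronless: tuple[str, ...] = ()
    trim_config: trim.TrimConfig = field(default_factory=trim.TrimConfig)
    threshold: Optional[int] = None  # None: derive from intron lengths
    min_region_size: int = 4
    gain_cost: float = 2.0
    loss_cost: float = 1.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("out_dir", "alignment", "scores", "exons", "boundary_table", "tree"):
            if raw.get(key) is not None:
                kwargs[key] = Path(raw[key])
        for key in ("threshold", "min_region_size", "gain_cost", "loss_cost", "log_level"):
            if raw.get(key) is not None:
                kwargs[key] = raw[key]
        if raw.get("intronless"):
            kwargs["intronless"] = tuple(raw["intronless"])
        tc = raw.get("trim", {})
        if tc:
            kwargs["trim_config"] = trim.TrimConfig(**tc)
        if "out_dir" not in kwargs:
            raise ValueError(f"{path}: config must set out_dir")
        return cls(**kwargs)


def _require(path: Optional[Path], stage: str) -> Path:
    if path is None:
        raise StageError(stage, "required input not configured")
    if not Path(path).exists():
        raise StageError(stage, f"input file not found: {path}")
    return Path(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns the summary dict.

    Raises :class:`StageError` on failure after writing a MANIFEST that
    marks the run incomplete.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict = {"stages": []}

    def emit(name: str) -> None:
        manifest.append(name)

    def finish(complete: bool) -> None:
        with open(out / "MANIFEST", "w") as fh:
            fh.write(f"status\t{'complete' if complete else 'INCOMPLETE'}\n")
            for name in manifest:
                fh.write(f"output\t{name}\n")

    try:
        intron_lengths: list[int] = []
        if config.boundary_table is not None:
            path = _require(config.boundary_table, "load_boundaries")
            table = io.read_boundary_table(path)
            log.info("stage=load_boundaries records=%d", len(table))
        else:
            msa_path = _require(config.alignment, "read_alignment")
            alignment = io.read_alignment_fasta(msa_path)
            scores_path = _require(config.scores, "read_scores")
            res_scores = io.read_residue_scores(scores_path, alignment)
            log.info(
                "stage=trim mode=%s tau=%s cutoff=%s",
                config.trim_config.mode,
                config.trim_config.residue_threshold,
                config.trim_config.default_column_cutoff,
            )
            if config.trim_config.mode == "custom":
                trimmed = trim.trim_custom(alignment, res_scores, config.trim_config)
            else:
                trimmed = trim.trim_default_guidance(
                    alignment, scores=res_scores, config=config.trim_config
                )
            trim.write_column_map(trimmed, out / "column_map.tsv")
            emit("column_map.tsv")
            io.write_alignment_fasta(trim.apply_trim(alignment, trimmed), out / "trimmed_msa.fasta")
            emit("trimmed_msa.fasta")
            summary["trim"] = {
                "n_columns": trimmed.n_columns,
                "removed": trimmed.n_removed,
                "kept": trimmed.n_kept,
            }
            summary["stages"].append("trim")

            exon_path = _require(config.exons, "annotate")
            models = annotate.read_exon_models(exon_path)
            boundaries = [b for m in models for b in annotate.exons_to_boundaries(m)]
            intron_lengths = [b.intron_len_aa for b in boundaries if b.intron_len_aa > 0]
            maps = trim.build_coordinate_maps(alignment, trimmed)
            table = project.project_boundaries(boundaries, maps)
            summary["stages"].append("project")

        io.write_boundary_table(table, out / "boundary_table.tsv")
        emit("boundary_table.tsv")

        counts = annotate.summarize_boundaries(table)
        summary["boundaries"] = {
            "total": counts.total,
            "projected": counts.projected,
            "removed": counts.removed,
        }
        summary["stages"].append("summarize")

        if config.threshold is not None:
            threshold = config.threshold
        elif intron_lengths:
            threshold = regions.derive_threshold(intron_lengths)
        else:
            threshold = regions.ClusterConfig().threshold
        cconfig = regions.ClusterConfig(
            threshold=threshold, min_region_size=config.min_region_size
        )
        log.info("stage=cluster threshold=%d min_region_size=%d", threshold, config.min_region_size)
        projected = table.projected()
        distances = regions.pairwise_distances(projected)
        regions.write_distance_matrix(distances, out / "distances.tsv")
        emit("distances.tsv")
        clusters = regions.cluster_boundaries(projected, cconfig)
        region_set = regions.call_regions(clusters, cconfig)
        classification = regions.classify_boundaries(region_set, table)
        regions.write_regions(region_set, classification, out / "regions.tsv")
        emit("regions.tsv")
        gaps = regions.region_gap_stats(region_set, table)
        summary["clustering"] = {
            "threshold": threshold,
            "min_region_size": config.min_region_size,
            "n_clusters": len(clusters),
            "n_regions": len(region_set.regions),
            "regions": {
                r.label: {
                    "span": list(r.span),
                    "size": r.cluster.size,
                    "gaps": list(gaps[r.label]),
                }
                for r in region_set.regions
            },
        }
        summary["stages"].append("cluster")

        if config.tree is not None:
            tree_path = _require(config.tree, "reconstruct")
            tree = io.read_newick_tree(tree_path)
            taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
            matrix = reconstruct.build_character_matrix(
                table, region_set, taxa, intronless=config.intronless
            )
            rconfig = reconstruct.ReconstructionConfig(
                gain_cost=config.gain_cost, loss_cost=config.loss_cost
            )
            log.info("stage=reconstruct gain_cost=%s loss_cost=%s", config.gain_cost, config.loss_cost)
            recon = reconstruct.parsimony_reconstruct(tree, matrix, rconfig)
            events, root_summary = reconstruct.enumerate_events(recon)
            reconstruct.write_events(events, out / "events.tsv")
            emit("events.tsv")
            summary["reconstruction"] = root_summary
            summary["stages"].append("reconstruct")

        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        emit("summary.json")
        finish(complete=True)
        return summary
    except StageError:
        finish(complete=False)
        raise
    except Exception as exc:
        finish(complete=False)
        raise StageError("pipeline", str(exc)) from exc
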
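"""Reproducible end-to-end runs: matrix in, standard-format bundle out.

A :class:`RunConfig` (built directly or loaded from a YAML file) selects the
input matrix, metric, bootstrap settings, and which stages to run;
:func:`run_pipeline` executes the stages in order and writes every output in
its declared text format, together with a JSON manifest recording inputs,
seed and settings.  Re-running with an unchanged config and inputs yields
identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import __version__
from .distances import distance_matrix, write_distances
from .matrix import matrix_summary, nexus_export, read_matrix
from .ordination import heatmap_table, hclust_order, pcoa
from .treelikeness import taxon_scores
from .trees import (
    bootstrap_support,
    gold_standard_score,
    load_gold_standard,
    newick_write,
    upgma,
)

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES", "PipelineError"]

ALL_STAGES = ("summary", "dist", "tree", "boot", "pcoa", "heatmap", "delta",
              "gold", "nexus")

# printed precision: distances 3 d.p., percentages nearest integer, scores 3 d.p.
DIST_FMT = "%.3f"
SCORE_FMT = "%.3f"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    matrix_path: str
    orientation: str = "languages-as-rows"
    metric: str = "jaccard"
    bootstrap_reps: int = 100
    seed: int = 0
    gold_standard_path: str | None = None   # None = packaged group table
    include_altaic: bool = False
    output_dir: str = "pcmphylo_out"
    stages: tuple = ALL_STAGES
    shades_per_half: int = 5

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = RunConfig(**raw)
        if not Path(cfg.matrix_path).exists():
            raise FileNotFoundError(f"matrix file not found: {cfg.matrix_path}")
        return cfg


def _load_groups(config: RunConfig):
    if config.gold_standard_path is None:
        return load_gold_standard(include_altaic=config.include_altaic)
    from .trees import CladeGroup

    with open(config.gold_standard_path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    groups = [CladeGroup.of(g["name"], g["members"]) for g in raw["groups"]]
    if not config.include_altaic:
        groups = [g for g in groups if g.name != "Altaic"]
    return groups


def run_pipeline(config: RunConfig) -> dict:
    """Run the selected stages; returns a manifest dict (also written as JSON).

    Stage failures raise :class:`PipelineError` naming the stage; outputs of
    stages already completed are preserved.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "pcmphylo",
        "version": __version__,
        "inputs": {"matrix": str(config.matrix_path),
                   "orientation": config.orientation},
        "seed": config.seed,
        "settings": {k: v for k, v in asdict(config).items()
                     if k not in ("matrix_path", "orientation")},
        "stages_run": [],
        "outputs": {},
        "warnings": [],
    }

    def record(stage: str, **files) -> None:
        manifest["stages_run"].append(stage)
        manifest["outputs"].update({k: str(v) for k, v in files.items()})

    stage = "read"
    try:
        m = read_matrix(config.matrix_path, orientation=config.orientation)

        D = None

        def dist():
            nonlocal D
            if D is None:
                D = distance_matrix(m, metric=config.metric)
            return D

        for stage in config.stages:
            if stage == "summary":
                rep = matrix_summary(m)
                rep.to_frame().to_csv(out / "summary.csv")
                rep.plus_per_language.to_csv(out / "plus_per_language.csv")
                rep.pair_overlap.to_csv(out / "pair_overlap.csv")
                record(stage, summary=out / "summary.csv",
                       plus_per_language=out / "plus_per_language.csv",
                       pair_overlap=out / "pair_overlap.csv")
            elif stage == "dist":
                write_distances(dist(), out / "distances.csv", format="csv")
                write_distances(dist(), out / "distances.phy", format="phylip-square")
                record(stage, distances_csv=out / "distances.csv",
                       distances_phylip=out / "distances.phy")
            elif stage == "tree":
                tree = upgma(dist())
                newick_write(tree, out / "upgma.nwk")
                record(stage, upgma=out / "upgma.nwk")
            elif stage == "boot":
                boot = bootstrap_support(m, metric=config.metric,
                                         n_reps=config.bootstrap_reps,
                                         seed=config.seed)
                newick_write(boot.tree, out / "upgma_bootstrap.nwk")
                boot.support_table().to_csv(out / "bootstrap_support.csv", index=False)
                if boot.n_discarded:
                    manifest["warnings"].append(
                        f"boot: {boot.n_discarded}/{boot.n_requested} replicates "
                        f"discarded (undefined distances)")
                manifest["bootstrap"] = {"requested": boot.n_requested,
                                         "retained": boot.n_retained,
                                         "discarded": boot.n_discarded}
                record(stage, upgma_bootstrap=out / "upgma_bootstrap.nwk",
                       bootstrap_support=out / "bootstrap_support.csv")
            elif stage == "pcoa":
                ordn = pcoa(dist())
                ordn.coordinates_frame().to_csv(out / "pcoa_coordinates.csv")
                ordn.summary_frame().to_csv(out / "pcoa_eigen.csv")
                record(stage, pcoa_coordinates=out / "pcoa_coordinates.csv",
                       pcoa_eigen=out / "pcoa_eigen.csv")
            elif stage == "heatmap":
                order = hclust_order(dist())
                mat, bins = heatmap_table(dist(), order,
                                          shades_per_half=config.shades_per_half)
                mat.round(3).to_csv(out / "heatmap_matrix.csv")
                bins.to_csv(out / "heatmap_bins.csv")
                record(stage, heatmap_matrix=out / "heatmap_matrix.csv",
                       heatmap_bins=out / "heatmap_bins.csv")
            elif stage == "delta":
                tl = taxon_scores(dist())
                tl.per_taxon.round(3).to_csv(out / "treelikeness_per_taxon.csv")
                tl.summary_frame().round(3).to_csv(out / "treelikeness_summary.csv")
                tl.least_treelike(10).round(3).to_csv(out / "least_treelike.csv")
                record(stage, treelikeness_per_taxon=out / "treelikeness_per_taxon.csv",
                       treelikeness_summary=out / "treelikeness_summary.csv",
                       least_treelike=out / "least_treelike.csv")
            elif stage == "gold":
                groups = _load_groups(config)
                table, frac = gold_standard_score(upgma(dist()), groups)
                table.to_csv(out / "gold_standard_scores.csv", index=False)
                manifest["gold_standard"] = {
                    "n_groups": int(len(table)),
                    "n_recovered": int(table["recovered"].sum()),
                    "fraction": round(frac, 3),
                    "percent": round(100 * frac),
                }
                record(stage, gold_standard_scores=out / "gold_standard_scores.csv")
            elif stage == "nexus":
                (out / "matrix.nex").write_text(nexus_export(m), encoding="utf-8")
                record(stage, nexus=out / "matrix.nex")
            else:
                raise ValueError(f"unknown stage {stage!r}")
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
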
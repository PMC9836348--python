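"""End-to-end screen pipeline: simulate -> quantify -> score -> hits -> cluster -> enrich.

Runs are driven by a :class:`RunConfig` (YAML round-trippable). Every
stochastic stage derives its own seed from the global seed and the stage
name with a stable hash, so toggling one stage never shifts another
stage's randomness. All outputs are plain text (TSV/JSON) plus a score
distribution plot, and a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, hits as hits_mod, network, quantify as quantify_mod, scoring, simulate
from .simulate import ArtifactParams, ValidationError

log = logging.getLogger("sgascreen")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: crc32 of "<seed>:<stage>" (below 2**31)."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) % (2**31)


@dataclass
class RunConfig:
    """All pipeline parameters; round-trips losslessly through YAML."""

    seed: int = 0
    out_dir: str = "sga_run"
    # stage toggles
    do_simulate: bool = True
    do_quantify: bool = False
    do_score: bool = True
    do_hits: bool = True
    do_cluster: bool = True
    do_enrich: bool = True
    # simulate
    n_genes: int = 500
    frac_suppressor: float = 0.1
    frac_enhancer: float = 0.1
    effect_low: float = 0.0
    effect_high: float = 2.5
    suppressor_high: float = 0.3
    enhancer_low: float = 1.7
    m_drug_query: float = 2.0
    controls_per_plate: int = 16
    n_replicates: int = 16
    row_gradient: float = 0.15
    col_gradient: float = 0.15
    edge_effect: float = 0.8
    noise_cv: float = 0.1
    missing_prob: float = 0.01
    base_size: float = 300.0
    # inputs for non-simulated runs
    score_table_path: str | None = None
    edge_list_path: str | None = None
    annotation_path: str | None = None
    phenotype_path: str | None = None
    # scoring / hits
    s_max: float = 2.0
    k_sd: list[float] = field(default_factory=lambda: [1.0, 1.5])
    hit_k_sd: float = 1.5
    # clustering
    min_confidence: float = 0.4
    k_clusters: int | None = None
    k_min: int = 1
    k_max: int = 10
    gap_B: int = 50
    # enrichment
    fdr_max: float = 0.05
    min_genes: int = 1
    top_n: int = 10

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunReport:
    """Summary of a pipeline run (also written as report.json)."""

    summary: dict
    out_dir: Path


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_manifest(out: Path, completed: list[str], failed: str | None = None) -> None:
    lines = [f"completed: {', '.join(completed) if completed else '(none)'}"]
    if failed:
        lines.append(f"failed: {failed}")
        lines.append("outputs are partial")
    (out / "MANIFEST").write_text("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages, writing TSV/JSON/PNG outputs to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    for key, value in sorted(dataclasses.asdict(config).items()):
        log.info("param %s = %r", key, value)

    summary: dict = {"seed": config.seed}
    completed: list[str] = []
    truth = None
    score_df = None
    hit_sets: dict = {}
    stage = "setup"
    try:
        if config.do_simulate:
            stage = "simulate"
            seed = stage_seed(config.seed, stage)
            log.info("stage %s seed %d", stage, seed)
            truth = simulate.generate_truth(
                config.n_genes, config.frac_suppressor, config.frac_enhancer,
                config.effect_low, config.effect_high, seed=seed,
                suppressor_high=config.suppressor_high,
                enhancer_low=config.enhancer_low,
                m_drug_query=config.m_drug_query,
            )
            layouts = simulate.replicate_layouts(
                simulate.layout_plates(truth, config.controls_per_plate, seed=seed),
                config.n_replicates,
            )
            artifacts = ArtifactParams(
                row_gradient=config.row_gradient, col_gradient=config.col_gradient,
                edge_effect=config.edge_effect, noise_cv=config.noise_cv,
                missing_prob=config.missing_prob, base_size=config.base_size,
            )
            colonies = simulate.simulate_screen(truth, layouts, artifacts, seed=seed)
            truth.write_tsv(out / "truth.tsv")
            simulate.write_colony_tsv(colonies, out / "colonies.tsv")
            summary["n_genes"] = config.n_genes
            summary["n_plates"] = len(layouts)
            completed.append(stage)

            if config.do_quantify:
                stage = "quantify"
                counts_rows = []
                for lay in layouts:
                    for cls in simulate.STRAIN_CLASSES:
                        for cond in simulate.CONDITIONS:
                            img = simulate.render_plate_image(colonies, lay.plate_id, cond, cls)
                            counts = quantify_mod.quantify_plate(img)
                            frame = quantify_mod.counts_to_frame(counts)
                            frame.insert(0, "plate", lay.plate_id)
                            frame["strain_class"] = cls
                            frame["condition"] = cond
                            counts_rows.append(frame)
                pd.concat(counts_rows).to_csv(out / "quantified.tsv", sep="\t", index=False)
                completed.append(stage)

        if config.do_score:
            stage = "score"
            if config.do_simulate:
                normalized = scoring.normalize_plates(colonies)
                result = scoring.score_table(normalized, s_max=config.s_max)
                result.write_tsv(out / "scores.tsv")
                result.invalid.to_csv(out / "invalid_genes.tsv", sep="\t", index=False)
                score_df = result.scores
                summary["n_invalid"] = int(len(result.invalid))
            elif config.score_table_path:
                score_df = scoring.read_score_tsv(config.score_table_path)
            else:
                raise ValidationError("score stage needs simulation or score_table_path")
            summary["n_scored"] = int(len(score_df))
            completed.append(stage)

        if config.do_hits:
            stage = "hits"
            if score_df is None:
                raise ValidationError("hits stage needs scores")
            dist = hits_mod.score_stats(score_df)
            summary["score_mean"] = dist.mean
            summary["score_sd"] = dist.sd
            summary["score_min"] = dist.min
            summary["score_max"] = dist.max
            summary["hits"] = {}
            hit_sets = {}
            for k in config.k_sd:
                hs = hits_mod.classify_hits(score_df, k, dist=dist)
                hit_sets[k] = hs
                summary["hits"][str(k)] = {
                    "lower": hs.lower, "upper": hs.upper,
                    "n_suppressors": len(hs.suppressors),
                    "n_enhancers": len(hs.enhancers),
                }
                pd.DataFrame({"gene": hs.suppressors}).to_csv(
                    out / f"suppressors_k{k}.tsv", sep="\t", index=False)
                pd.DataFrame({"gene": hs.enhancers}).to_csv(
                    out / f"enhancers_k{k}.tsv", sep="\t", index=False)
            if config.phenotype_path:
                ann = hits_mod.read_annotations(config.phenotype_path)
                ct = hits_mod.crosstab_phenotypes(hit_sets[min(config.k_sd)], ann)
                summary["phenotype_crosstab"] = ct.counts()
            completed.append(stage)

        cluster_frames = {}
        if config.do_cluster:
            stage = "cluster"
            seed = stage_seed(config.seed, stage)
            log.info("stage %s seed %d", stage, seed)
            hs = hit_sets.get(config.hit_k_sd)
            whitelist = hs.genes if hs is not None else None
            if config.edge_list_path:
                net = network.read_edge_list(config.edge_list_path,
                                             min_confidence=config.min_confidence,
                                             node_whitelist=whitelist)
            elif config.do_simulate and hs is not None:
                edges, modules = simulate.simulate_module_network(
                    sorted(hs.genes), seed=stage_seed(config.seed, "network"))
                edges.to_csv(out / "edges.tsv", sep="\t", index=False)
                net = network.build_network(
                    edges.itertuples(index=False, name=None),
                    min_confidence=config.min_confidence, node_whitelist=whitelist)
            else:
                raise ValidationError("cluster stage needs an edge list or a simulated screen")
            assignment, gap = network.cluster_network(
                net, k=config.k_clusters, k_range=(config.k_min, config.k_max),
                seed=seed, B=config.gap_B)
            assignment.to_frame().to_csv(out / "clusters.tsv", sep="\t", index=False)
            if gap is not None:
                gap.write_tsv(out / "gap.tsv")
                summary["gap_chosen_k"] = int(gap.chosen_k)
            summary["k_clusters"] = int(assignment.k)
            summary["n_clustered_genes"] = len(assignment.labels)
            for c in range(1, assignment.k + 1):
                cluster_frames[c] = assignment.members(c)
            completed.append(stage)

        if config.do_enrich:
            stage = "enrich"
            if config.annotation_path:
                ann_set = enrichment.AnnotationSet.from_tsv(config.annotation_path)
            elif config.do_simulate and config.do_cluster:
                _, modules = simulate.simulate_module_network(
                    sorted(hit_sets[config.hit_k_sd].genes),
                    seed=stage_seed(config.seed, "network"))
                pairs_df = simulate.simulate_annotations(
                    modules, background=truth.genes,
                    seed=stage_seed(config.seed, "annotations"))
                pairs_df.to_csv(out / "annotations.tsv", sep="\t", index=False)
                ann_set = enrichment.AnnotationSet.from_pairs(
                    pairs_df.itertuples(index=False, name=None))
            else:
                raise ValidationError("enrich stage needs annotations")
            summary["enrichment"] = {}
            for c, members in sorted(cluster_frames.items()):
                rows = enrichment.enrich_gene_set(members, ann_set)
                ranked = enrichment.curate_rank(
                    rows, annotations=ann_set, fdr_max=config.fdr_max,
                    min_genes=config.min_genes, top_n=config.top_n)
                ranked.to_csv(out / f"enrichment_cluster{c}.tsv", sep="\t", index=False)
                summary["enrichment"][str(c)] = [
                    {"term": r.term, "k": int(r.k), "strength": round(float(r.strength), 2),
                     "fdr": float(r.fdr)}
                    for r in ranked.itertuples()
                ]
            completed.append(stage)

        if score_df is not None:
            write_report_plot(score_df, summary, out / "score_distribution.png")
    except Exception as exc:  # noqa: BLE001 - abort names the failing stage
        _write_manifest(out, completed, failed=stage)
        log.removeHandler(handler)
        handler.close()
        raise StageFailure(stage, exc) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _write_manifest(out, completed)
    log.removeHandler(handler)
    handler.close()
    return RunReport(summary=summary, out_dir=out)


def write_report_plot(score_df: pd.DataFrame, summary: dict, path) -> None:
    """Ascending score curve with dashed SD-cutoff lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = np.sort(score_df["score"].to_numpy(float))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.arange(1, len(scores) + 1), scores, lw=1.2, color="black")
    styles = {"1.0": ("tab:blue", "1.0 SD"), "1.5": ("tab:red", "1.5 SD")}
    for k, block in summary.get("hits", {}).items():
        color, label = styles.get(k, ("gray", f"{k} SD"))
        ax.axhline(block["lower"], ls="--", color=color, lw=0.8, label=label)
        ax.axhline(block["upper"], ls="--", color=color, lw=0.8)
    ax.set_xlabel("genes (ascending score)")
    ax.set_ylabel("interaction score")
    if summary.get("hits"):
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
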
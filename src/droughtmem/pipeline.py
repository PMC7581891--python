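"""End-to-end orchestration: simulate -> design -> normalize -> diff ->
classify -> enrich -> network, with a JSON manifest of outputs.

Single-process and deterministic: one top-level seed fans out to fixed
per-stage seeds; rerunning with the same config yields byte-identical
outputs and manifest checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from droughtmem import (
    GoAnnotation,
    SimulationConfig,
    assemble_chip,
    background_correct,
    classify_memory,
    classify_response,
    cluster_tree,
    filter_significant,
    map_orthologs,
    moderated_differential,
    parse_gene_models,
    pearson_network,
    quantile_normalize,
    recovery_flag,
    select_representative,
    simulate_expression,
    simulate_genome,
    simulate_go,
    summarize_counts,
)
from droughtmem.enrichment import enrich_with_fdr, score_matrix
from droughtmem.memory_classifier import category_members
from droughtmem.preprocess_stats import ExpressionMatrix, log2_transform
from droughtmem.synthetic_data import simulate_alignment

ALL_STAGES = ("simulate", "design", "normalize", "diff", "classify",
              "enrich", "network")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


@dataclass
class RunConfig:
    """Pipeline thresholds and paths; defaults are the study thresholds
    (fourfold screens, adjusted p < 0.05, |level| > 1, |r| >= 0.65,
    alignment score >= 70, 100 randomizations)."""

    outdir: str = "droughtmem_run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    n_genes: int = 200
    fold: float = 4.0
    alpha: float = 0.05
    level_cut: float = 1.0
    abs_r: float = 0.65
    score_threshold: float = 70.0
    randomizations: int = 100
    quantile: bool = True  # between-array quantile normalization
    matrix: str | None = None   # pre-existing inputs for ingest-style runs
    samples: str | None = None

    def __post_init__(self) -> None:
        for name in ("fold", "alpha", "level_cut", "abs_r", "randomizations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order and return the run manifest.

    Stage outputs land under ``config.outdir``. Any stage error raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {
            "fold": config.fold,
            "alpha": config.alpha,
            "level_cut": config.level_cut,
            "abs_r": config.abs_r,
            "score_threshold": config.score_threshold,
            "randomizations": config.randomizations,
        },
        "stages": {},
    }
    sim_cfg = SimulationConfig(seed=config.seed, n_genes=config.n_genes)
    state: dict = {}

    def record(stage: str, paths: list[Path]) -> None:
        manifest["stages"][stage] = {
            str(p.relative_to(out)): _sha256(p) for p in sorted(paths)
        }

    # downstream stages imply their prerequisites on in-memory state
    effective = set(config.stages)
    if effective & {"diff", "classify", "enrich", "network"}:
        effective.add("normalize")
    if effective & {"enrich", "network"}:
        effective.add("classify")

    def run_stage(stage, fn):
        if stage not in effective:
            return
        try:
            record(stage, fn())
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise PipelineError(stage, str(exc)) from exc

    def stage_simulate() -> list[Path]:
        gff3, fasta, truth_exons = simulate_genome(sim_cfg)
        (out / "genome.gff3").write_text(gff3)
        (out / "genome.fasta").write_text(fasta)
        truth_exons.to_csv(out / "truth_exons.tsv", sep="\t", index=False)
        genes, _ = parse_gene_models(gff3, fasta)
        reps = [select_representative(g).transcript_id for g in genes]
        matrix, truth = simulate_expression(sim_cfg, reps)
        matrix.to_tsv(out / "raw_matrix.tsv")
        matrix.sample_meta.to_csv(out / "samples.tsv", sep="\t",
                                  index_label="sample_id")
        truth.to_csv(out / "truth.tsv", sep="\t", index_label="transcript_id")
        anno = simulate_go(
            sim_cfg, reps,
            planted_genes=list(truth.index[truth["memory_label"] == "DIMT"]),
        )
        with open(out / "go.tsv", "w") as fh:
            for term in anno.terms:
                for gene in sorted(anno.term_genes[term]):
                    fh.write(f"{term}\t{gene}\n")
        (out / "alignment.tsv").write_text(simulate_alignment(sim_cfg, reps))
        state.update(genes=genes, matrix=matrix, truth=truth, anno=anno)
        return [out / n for n in (
            "genome.gff3", "genome.fasta", "truth_exons.tsv", "raw_matrix.tsv",
            "samples.tsv", "truth.tsv", "go.tsv", "alignment.tsv",
        )]

    def stage_design() -> list[Path]:
        genes = state.get("genes")
        if genes is None:
            genes, _ = parse_gene_models(
                str(out / "genome.gff3"), str(out / "genome.fasta")
            )
        chip = assemble_chip(genes)
        chip.to_tsv(out / "chip_manifest.tsv")
        chip.to_fasta(out / "probes.fasta")
        return [out / "chip_manifest.tsv", out / "probes.fasta"]

    def _load_matrix() -> ExpressionMatrix:
        if "matrix" in state:
            return state["matrix"]
        matrix_path = config.matrix or out / "raw_matrix.tsv"
        samples_path = config.samples or out / "samples.tsv"
        return ExpressionMatrix.from_tsv(matrix_path, samples_path)

    def stage_normalize() -> list[Path]:
        raw = _load_matrix()
        norm = log2_transform(background_correct(raw))
        if config.quantile:
            norm = quantile_normalize(norm)
        norm.to_tsv(out / "normalized.tsv")
        state["norm"] = norm
        return [out / "normalized.tsv"]

    def stage_diff() -> list[Path]:
        norm = state["norm"]
        diff = moderated_differential(norm)
        diff.to_tsv(out / "differential.tsv")
        kept = filter_significant(diff, alpha=config.alpha,
                                  level_cut=config.level_cut)
        pd.Series(kept, name="transcript_id").to_csv(
            out / "significant.tsv", sep="\t", index=False
        )
        state["diff"] = diff
        return [out / "differential.tsv", out / "significant.tsv"]

    def stage_classify() -> list[Path]:
        norm = state["norm"]
        controls = [i for i in norm.values.index if str(i).startswith("CTRL_")]
        c = classify_response(norm, fold=config.fold)
        c = classify_memory(c, norm, control_rows=controls)
        c.table["recovered_at_WT2"] = recovery_flag(norm)
        c.to_tsv(out / "classification.tsv")
        counts = summarize_counts(c)
        (out / "counts.json").write_text(json.dumps(counts, indent=2))
        state["classification"] = c
        return [out / "classification.tsv", out / "counts.json"]

    def stage_enrich() -> list[Path]:
        anno = state.get("anno") or GoAnnotation.from_tsv(out / "go.tsv")
        members = category_members(state["classification"])
        tables, paths = {}, []
        for i, cls in enumerate(("DIT", "DRT", "DIMT", "DRMT")):
            genes = [g for g in members[cls] if g in anno.universe]
            if not genes:
                continue
            tables[cls] = enrich_with_fdr(
                genes, anno, n_randomizations=config.randomizations,
                seed=config.seed + 101 + i,
            )
            p = out / f"enrichment_{cls}.tsv"
            tables[cls].to_csv(p, sep="\t")
            paths.append(p)
        if tables:
            directions = {"DIT": "induced", "DIMT": "induced",
                          "DRT": "repressed", "DRMT": "repressed"}
            scores = score_matrix(tables, directions)
            scores.to_csv(out / "enrichment_scores.tsv", sep="\t")
            paths.append(out / "enrichment_scores.tsv")
        return paths

    def stage_network() -> list[Path]:
        norm = state["norm"]
        members = category_members(state["classification"])
        genes = members["DIMT"] + members["DRMT"]
        if len(genes) < 2:  # fall back to the most variable transcripts
            genes = list(
                norm.values.var(axis=1).sort_values(ascending=False).index[:20]
            )
        net = pearson_network(norm.values.loc[genes], threshold=config.abs_r)
        net.edges().to_csv(out / "network_edges.tsv", sep="\t", index=False)
        net.components_frame().to_csv(out / "network_components.tsv",
                                      sep="\t", index=False)
        (out / "network_tree.nwk").write_text(cluster_tree(net) + "\n")
        orth = map_orthologs(str(out / "alignment.tsv"),
                             score_threshold=config.score_threshold)
        pd.DataFrame(
            [{"query": q, "subject": s} for q, s in sorted(orth.best.items())]
        ).to_csv(out / "orthologs.tsv", sep="\t", index=False)
        return [out / n for n in (
            "network_edges.tsv", "network_components.tsv",
            "network_tree.nwk", "orthologs.tsv",
        )]

    started = time.time()
    run_stage("simulate", stage_simulate)
    run_stage("design", stage_design)
    run_stage("normalize", stage_normalize)
    run_stage("diff", stage_diff)
    run_stage("classify", stage_classify)
    run_stage("enrich", stage_enrich)
    run_stage("network", stage_network)
    manifest["elapsed_s"] = round(time.time() - started, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
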
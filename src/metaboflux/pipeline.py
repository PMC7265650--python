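"""End-to-end orchestration: multi-layer networks and the full demo run.

``run_combined_network`` learns a single decomposable model over several
omics layers (metabolites + genes, or metabolites + pathway flux
activities) after per-feature z-standardization within each layer — the
layers live on different scales, and although Pearson correlation is
scale-free per pair, making the standardization explicit keeps the
combined matrix and its exports interpretable.  Node attributes record the
layer of every feature so layer mixing (cross-layer edges, per-layer leaf
status) is directly inspectable.

``run_all`` wires the stages together on synthetic data and writes a run
directory with a manifest (parameters, seeds, input checksums) so a run is
reproducible from its config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity import assign_function, branch_decompose, compare_groups, node_activity
from .fluxmodel import per_sample_fba
from .ggm import DecomposableGraph, export_graphml, learn_network
from .omics import OmicsMatrix, SampleAnnotation
from .preprocess import filter_detection, impute_downshifted_normal
from .simulate import (SimulationConfig, make_toy_model, pathway_annotation,
                       simulate_omics, simulate_survival)
from .survival import SurvivalData, build_predictor, loocv_permutation, rank_features

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Declarative configuration of a full synthetic-cohort run.

    ``seed`` fans out to per-stage seeds through fixed offsets (documented
    in :func:`stage_seed`) so stages stay independently reproducible.
    """

    out_dir: str
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_fraction: float = 0.75
    impute_width: float = 0.3
    impute_shift: float = 1.8
    branches: int = 5
    k_signature: int = 5
    n_perm: int = 1000
    fba_variant: str = "pfba"

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["simulation"] = self.simulation.to_dict()
        return doc


_STAGE_OFFSETS = {"simulate": 1, "impute": 2, "survival": 3, "permutation": 4}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed: splitmix-style hash of (seed, stage)."""
    h = hashlib.sha256(f"{seed}:{_STAGE_OFFSETS[stage]}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def combine_layers(matrices: list[OmicsMatrix], layer_tags: list[str]
                   ) -> tuple[OmicsMatrix, dict[str, str]]:
    """Z-standardize each feature per layer, prefix ids, row-concatenate.

    All layers must share the sample set (order may differ; columns are
    aligned to the first layer).  Returns the stacked matrix and the
    feature -> layer tag map.
    """
    if len(matrices) != len(layer_tags):
        raise PipelineError("one tag per layer required")
    ref = matrices[0].sample_ids
    layer_of: dict[str, str] = {}
    frames = []
    for mat, tag in zip(matrices, layer_tags):
        if set(mat.sample_ids) != set(ref):
            missing = set(ref) ^ set(mat.sample_ids)
            raise PipelineError(f"layer {tag!r} sample set differs: {sorted(missing)[:5]}")
        if not mat.fully_observed:
            raise PipelineError(f"layer {tag!r} must be fully observed (impute first)")
        df = mat.to_frame()[ref]
        mu = df.mean(axis=1)
        sd = df.std(axis=1, ddof=1)
        if (sd == 0).any():
            bad = sd.index[sd == 0][:3].tolist()
            raise PipelineError(f"zero-variance features in layer {tag!r}: {bad}")
        z = df.sub(mu, axis=0).div(sd, axis=0)
        z.index = [f"{tag}:{f}" for f in z.index]
        for f in z.index:
            layer_of[f] = tag
        frames.append(z)
    stacked = pd.concat(frames, axis=0)
    if stacked.index.duplicated().any():
        raise PipelineError("layer-prefixed feature ids collide")
    return OmicsMatrix.from_frame(stacked, log_transformed=True), layer_of


def run_combined_network(matrices: list[OmicsMatrix], layer_tags: list[str]
                         ) -> tuple[DecomposableGraph, dict]:
    """Learn one decomposable model over several standardized layers.

    Returns the graph plus a report: feature -> layer map, cross-layer edge
    count and list, and per-layer degree / leaf summaries.
    """
    stacked, layer_of = combine_layers(matrices, layer_tags)
    graph, trace = learn_network(stacked)
    cross = [e for e in graph.edges if layer_of[e[0]] != layer_of[e[1]]]
    degrees = dict(graph.graph.degree())
    per_layer = {}
    for tag in layer_tags:
        feats = [f for f, t in layer_of.items() if t == tag]
        per_layer[tag] = {
            "n_features": len(feats),
            "mean_degree": float(np.mean([degrees[f] for f in feats])),
            "n_leaves": int(sum(degrees[f] <= 1 for f in feats)),
        }
    report = {
        "layer_of": layer_of,
        "n_cross_layer_edges": len(cross),
        "cross_layer_edges": cross,
        "per_layer": per_layer,
        "bic_trace_length": len(trace),
    }
    return graph, report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> Path:
    """Execute simulate -> preprocess -> ggm -> activity -> fba -> survival.

    Writes all stage outputs plus ``manifest.json`` into ``config.out_dir``
    and returns that directory.  Any stage failure aborts the run with a
    pointer to the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": config.to_dict(), "stages": {}}

    def record(stage: str, files: list[Path]):
        manifest["stages"][stage] = {f.name: _sha256(f) for f in files}

    try:
        # --- simulate -------------------------------------------------
        sim = config.simulation
        model = make_toy_model(stage_seed(config.seed, "simulate"),
                               n_pathways=max(2, min(sim.n_pathways, 4)),
                               reactions_per_pathway=3)
        metabolites, genes, annotation = simulate_omics(sim, gene_ids=model.genes)
        surv = simulate_survival(
            metabolites.copy(values=np.nan_to_num(metabolites.values, nan=10.0),
                             observed_mask=np.ones_like(metabolites.observed_mask)),
            sim.prognostic_features, sim.censor_rate,
            stage_seed(config.seed, "survival"))
        annotation = SampleAnnotation(annotation.sample_ids, annotation.group,
                                      pd.Series(surv.time, index=surv.sample_ids),
                                      pd.Series(surv.event, index=surv.sample_ids))
        model.to_json(out / "toy_model.json")
        metabolites.write_tsv(out / "metabolites_raw.tsv")
        genes.write_tsv(out / "genes.tsv")
        annotation.write_tsv(out / "samples.tsv")
        pathway_annotation(sim).to_frame().to_csv(out / "pathways.tsv", sep="\t")
        record("simulate", [out / f for f in
                            ("toy_model.json", "metabolites_raw.tsv", "genes.tsv",
                             "samples.tsv", "pathways.tsv")])

        # --- preprocess (matrices are generated on the log2 scale) ----
        filtered, report = filter_detection(metabolites, config.min_fraction)
        imputed = impute_downshifted_normal(filtered, config.impute_width,
                                            config.impute_shift,
                                            stage_seed(config.seed, "impute"))
        imputed.write_tsv(out / "metabolites_preprocessed.tsv")
        (out / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=2))
        record("preprocess", [out / "metabolites_preprocessed.tsv",
                              out / "filter_report.json"])

        # --- ggm + activity -------------------------------------------
        graph, trace = learn_network(imputed)
        branches = min(config.branches, graph.graph.number_of_nodes())
        partition = branch_decompose(graph, branches)
        partition = assign_function(partition, pathway_annotation(sim))
        acts = node_activity(imputed, partition)
        stats = compare_groups(acts, annotation)
        export_graphml(graph, out / "network.graphml",
                       node_attributes={"branch": partition.branch_of,
                                        "function": {f: partition.dominant_label[b] or ""
                                                     for f, b in partition.branch_of.items()}})
        acts.to_csv(out / "node_activities.tsv", sep="\t")
        stats.to_csv(out / "node_stats.tsv", sep="\t")
        record("ggm_activity", [out / "network.graphml", out / "node_activities.tsv",
                                out / "node_stats.tsv"])

        # --- fba -------------------------------------------------------
        growth, flux_acts = per_sample_fba(model, genes, variant=config.fba_variant)
        growth.to_csv(out / "growth.tsv", sep="\t", header=True)
        flux_acts.to_csv(out / "flux_activities.tsv", sep="\t")
        record("fba", [out / "growth.tsv", out / "flux_activities.tsv"])

        # --- survival ---------------------------------------------------
        ranked = rank_features(imputed, surv)
        ranked.to_csv(out / "ranked_features.tsv", sep="\t", index=False)
        predictor = build_predictor(imputed, surv, config.k_signature)
        cv_classes, logrank_p, perm_p = loocv_permutation(
            imputed, surv, config.k_signature, config.n_perm,
            stage_seed(config.seed, "permutation"))
        predictor.cv_classes = cv_classes
        predictor.permutation_p = perm_p
        predictor.n_permutations = config.n_perm
        predictor.to_json(out / "predictor.json")
        cv_classes.to_frame().to_csv(out / "cv_classes.tsv", sep="\t")
        manifest["survival"] = {"cv_logrank_p": logrank_p, "permutation_p": perm_p}
        record("survival", [out / "predictor.json", out / "cv_classes.tsv",
                            out / "ranked_features.tsv"])
    except Exception as err:
        failed = len(manifest["stages"])
        stage_names = ["simulate", "preprocess", "ggm_activity", "fba", "survival"]
        stage = stage_names[min(failed, len(stage_names) - 1)]
        raise PipelineError(f"stage {stage!r} failed: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
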
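"""End-to-end orchestration: select -> integrate -> network -> score -> associate.

A run takes a :class:`RunConfig`, executes the stages in order on simulated
or user-supplied inputs, writes every stage output under the run directory
and records a provenance manifest (parameters, seed, per-stage row counts,
output hashes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as mio
from .association import (
    bh_summary,
    matched_comparison,
    proliferation_correlation,
    stage_trend,
    survival_by_quartile,
)
from .integration import integrate, spearman_pairs, union_candidates
from .network import (
    assign_direction_weights,
    build_network,
    connectivity_report,
    detect_modules,
    overconnected_mirs,
    round_report,
)
from .scoring import score_samples, signature_from_modules
from .selection import detect_expressed, factorial_select
from .simulate import SimulationConfig, simulate_cohort, simulate_experiment, \
    simulate_predictions

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Stage parameters; defaults follow the published analysis thresholds."""

    outdir: str = "run"
    alpha_mir: float = 0.01
    alpha_mrna: float = 0.001
    detection_threshold: float = 6.0
    rho_cutoff: float = -0.9
    q_cutoff: float = 0.05
    correlation_axis: str = "samples"
    module_method: str = "greedy"
    n_top: int = 4
    degree_threshold: int = 50
    normalization: str = "zscore_per_mir"
    covariates: tuple = ("size_cat", "stage_cat")
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        cfg = cls(**d)
        cfg.simulation = SimulationConfig(**sim) if isinstance(sim, dict) else sim
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline on simulated inputs and return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    sim.validate()
    manifest: dict = {
        "seed": config.seed,
        "parameters": {k: v for k, v in dataclasses.asdict(config).items()
                       if k != "simulation"},
        "simulation": dataclasses.asdict(sim),
        "stages": {},
    }

    # --- simulate -------------------------------------------------------
    mir_mat, mrna_mat, truth = simulate_experiment(sim)
    sources = simulate_predictions(truth, sim)
    mio.write_expression(mir_mat, outdir / "mir_expression.tsv",
                         outdir / "mir_samples.tsv")
    mio.write_expression(mrna_mat, outdir / "mrna_expression.tsv",
                         outdir / "mrna_samples.tsv")
    mio.write_ground_truth(truth, outdir / "ground_truth.json")
    for i, src in enumerate(sources, 1):
        mio.write_edge_list(src, outdir / f"predictions_source{i}.tsv")
    manifest["stages"]["simulate"] = {
        "n_mirs": mir_mat.n_features, "n_mrnas": mrna_mat.n_features,
        "n_samples": mir_mat.n_samples,
        "prediction_sizes": [len(s) for s in sources],
    }

    # --- select ---------------------------------------------------------
    detected = detect_expressed(mir_mat, config.detection_threshold)
    mir_det = mir_mat.subset_features(sorted(detected))
    diff_mir = factorial_select(mir_det, config.alpha_mir)
    diff_mrna = factorial_select(mrna_mat, config.alpha_mrna)
    selected_mirs = diff_mir.index[diff_mir["selected"]]
    selected_mrnas = diff_mrna.index[diff_mrna["selected"]]
    diff_mir.to_csv(outdir / "differential_mir.tsv", sep="\t",
                    index_label="feature_id")
    diff_mrna.to_csv(outdir / "differential_mrna.tsv", sep="\t",
                     index_label="feature_id")
    manifest["stages"]["select"] = {
        "n_total_mirs": mir_mat.n_features,
        "n_detected_mirs": len(detected),
        "n_selected_mirs": len(selected_mirs),
        "n_selected_mrnas": len(selected_mrnas),
    }

    # --- integrate ------------------------------------------------------
    candidates = union_candidates(
        sources, known_mirs=selected_mirs, known_mrnas=selected_mrnas)
    if len(candidates) == 0:
        logger.warning("no candidates after selection; writing empty outputs")
        (outdir / "integrated_edges.tsv").write_text(
            "mir_id\tmrna_id\trho\tp_corr\tq_corr\tsources\n")
        manifest["stages"]["integrate"] = {"n_edges": 0}
        _finish(manifest, outdir)
        return manifest
    scored_pairs = spearman_pairs(mir_mat, mrna_mat, candidates,
                                  axis=config.correlation_axis)
    edges, counts = integrate(scored_pairs, config.rho_cutoff, config.q_cutoff)
    mio.write_edge_list(edges, outdir / "integrated_edges.tsv")
    manifest["stages"]["integrate"] = counts
    if counts["n_edges"] == 0:
        logger.warning("no integrated edges; downstream stages skipped")
        _finish(manifest, outdir)
        return manifest

    # --- network --------------------------------------------------------
    net = build_network(edges)
    modules = detect_modules(net, method=config.module_method,
                             n_top=config.n_top, seed=config.seed)
    modules = assign_direction_weights(modules, diff_mir)
    report = connectivity_report(net, modules)
    over = overconnected_mirs(net, config.degree_threshold)
    round_report(report).to_csv(outdir / "connectivity_report.tsv", sep="\t",
                                index_label="stratum")
    mio.write_modules(modules, outdir / "modules.tsv")
    mio.write_graphml(net, outdir / "network.graphml", modules)
    mio.write_sif(net, outdir / "network.sif")
    manifest["stages"]["network"] = {
        "n_modules": len(modules.modules),
        "n_overconnected": len(over),
        "direction_weights": modules.direction_weight,
    }

    # --- score ----------------------------------------------------------
    sig_modules = {lab: {m for m in modules.members(lab) if m in net.mir_nodes}
                   for lab in modules.modules}
    cohort, clinical, cohort_truth = simulate_cohort(
        modules.direction_weight, sim,
        signature_mirs={m: lab for lab, ms in sig_modules.items() for m in ms},
    )
    mio.write_expression(cohort, outdir / "cohort_expression.tsv",
                         outdir / "cohort_samples.tsv")
    mio.write_clinical(clinical, outdir / "clinical.tsv")
    sig = signature_from_modules(modules, over)
    sig = sig.restricted(set(cohort.feature_ids))
    scores = score_samples(cohort, sig, normalization=config.normalization)
    mio.write_scores(scores, outdir / "scores.tsv")
    manifest["stages"]["score"] = {
        "n_samples": len(scores), "n_signature_mirs": len(sig.mir_ids),
        "n_impact_mirs": len(sig.impact_subset),
    }

    # --- associate ------------------------------------------------------
    reports = {}
    errors = {}

    def _try(name, fn):
        try:
            reports[name] = fn()
        except (ValueError, KeyError) as err:
            logger.warning("association %s skipped: %s", name, err)
            errors[name] = str(err)

    _try("stage_trend", lambda: stage_trend(scores, clinical,
                                            stage_field="stage_cat",
                                            score_col="general_score"))
    _try("matched", lambda: matched_comparison(scores, clinical,
                                               score_col="impact_score"))
    _try("proliferation", lambda: proliferation_correlation(
        scores, clinical, score_col="impact_score"))

    def _survival():
        rep, km = survival_by_quartile(scores, clinical,
                                       covariates=config.covariates,
                                       score_col="general_score")
        for name, curve in km.items():
            curve.to_csv(outdir / f"km_{name}.tsv", sep="\t", index_label="time")
        return rep

    _try("survival", _survival)
    manifest["stages"]["associate"] = {
        name: {"p": rep.p, "statistic": rep.statistic}
        for name, rep in reports.items()
    }
    if errors:
        manifest["stages"]["associate"]["errors"] = errors
    if reports:
        bh_summary(reports).to_csv(outdir / "associations.tsv", sep="\t",
                                   index_label="analysis")
    if "survival" in reports:
        manifest["stages"]["associate"]["survival_extra"] = \
            reports["survival"].extra

    _finish(manifest, outdir)
    return manifest


def _finish(manifest: dict, outdir: Path) -> None:
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    logger.info("run complete: %s", outdir / "manifest.json")
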
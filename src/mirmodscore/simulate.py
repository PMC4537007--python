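"""Synthetic-data generation with planted ground truth.

Three generators emulate the pipeline's input classes:

* :func:`simulate_experiment` -- a 2x2 factorial treatment experiment
  (vehicle / ATRA / Lapatinib / ATRA+Lapatinib, ``n_replicates`` each) with
  planted treatment-regulated miRs organized in modules, and target mRNAs
  whose profiles are anti-correlated with their regulating miRs.
* :func:`simulate_predictions` -- per-source miR->mRNA candidate edge lists
  with controllable sensitivity and false-positive rate, standing in for
  sequence-based prediction tools.
* :func:`simulate_cohort` -- a tumor cohort whose miR expression encodes a
  latent signature score that decreases with progression and drives survival
  through an exponential hazard; a fraction of cases carry matched normals.

All noise is additive Gaussian on the log2 scale.  Each output block draws
from its own child RNG stream spawned from the master seed, so adding one
block never perturbs the others.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    ClinicalTable,
    ExpressionMatrix,
    GroundTruth,
    SIZE_LEVELS,
    STAGE_LEVELS,
    PROGRESSION_LEVELS,
)

logger = logging.getLogger(__name__)

# per-module (atra, lapatinib, interaction) log2 effect patterns for the
# default 4-module layout: Module-1 up mostly by Lapatinib (enhanced in
# combination), Module-2 down mostly by ATRA, Module-3 up mostly by ATRA,
# Module-4 pushed in opposite directions by the two drugs
DEFAULT_EFFECTS = (
    (0.4, 1.5, 0.5),
    (-1.5, -0.3, -0.4),
    (1.5, 0.3, 0.4),
    (-1.2, 1.2, 0.0),
)


@dataclass
class SimulationConfig:
    """All knobs of the generators, with defaults defining the study conditions."""

    n_mirs: int = 240
    n_mrnas: int = 1200
    n_replicates: int = 5
    n_modules: int = 4
    mirs_per_module: tuple = (8, 6, 5, 4)
    targets_per_module: tuple = (65, 55, 33, 25)
    #: per-module (atra, lapatinib, interaction) additive log2 effects
    effect_size_log2: tuple = DEFAULT_EFFECTS
    #: scale of the (negated) effect planted on true target mRNAs
    target_coupling: float = 1.0
    #: SD of a per-sample module-activity component shared (with opposite
    #: sign) by a module's miRs and targets; models coordinated biological
    #: variability and makes planted pairs anti-correlated beyond treatment
    module_activity_sd: float = 0.25
    noise_sd: float = 0.2
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    detection_threshold: float = 6.0
    #: fraction of non-planted features generated below the detection threshold
    undetected_fraction: float = 0.3
    pred_sensitivity: float = 0.8
    pred_fpr: float = 0.001
    n_pred_sources: int = 3
    cohort_n: int = 500
    matched_fraction: float = 102 / 993
    #: log2 drop of the latent score per ordinal step of size/stage category
    stage_effect: float = 0.5
    #: loading of the latent score on each signature miR (log2 units per SD)
    signature_loading: float = 1.0
    cohort_noise_sd: float = 0.4
    #: shift of matched-normal miR levels in the direction of the miR weight
    normal_shift: float = 1.0
    prolif_slope: float = 0.6
    hazard_log_hr_per_sd: float = 0.7
    baseline_hazard: float = 0.12
    censor_horizon: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_mirs", "n_mrnas", "n_replicates", "n_modules",
                     "n_pred_sources", "cohort_n"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive count")
        for name in ("pred_sensitivity", "pred_fpr", "matched_fraction",
                     "undetected_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("noise_sd", "cohort_noise_sd", "module_activity_sd",
                     "baseline_sd", "baseline_hazard", "censor_horizon"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if len(self.mirs_per_module) != self.n_modules:
            raise ValueError("mirs_per_module length must equal n_modules")
        if len(self.targets_per_module) != self.n_modules:
            raise ValueError("targets_per_module length must equal n_modules")
        if len(self.effect_size_log2) != self.n_modules:
            raise ValueError("effect_size_log2 length must equal n_modules")
        if sum(self.mirs_per_module) > self.n_mirs:
            raise ValueError("mirs_per_module sums beyond n_mirs")
        if sum(self.targets_per_module) > self.n_mrnas:
            raise ValueError("targets_per_module sums beyond n_mrnas")


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _design(n_replicates: int) -> pd.DataFrame:
    rows = []
    for (a, l), cond in zip(
        ((0, 0), (1, 0), (0, 1), (1, 1)), ("V", "A", "L", "AL")
    ):
        for r in range(1, n_replicates + 1):
            rows.append({"sample": f"{cond}{r}", "ATRA": a, "Lapatinib": l,
                         "replicate": r})
    return pd.DataFrame(rows).set_index("sample")


def _module_labels(n_modules: int) -> list[str]:
    return [f"Module-{k + 1}" for k in range(n_modules)]


def simulate_experiment(config: SimulationConfig):
    """Generate paired miR and mRNA treatment matrices with planted structure.

    Returns ``(mir_matrix, mrna_matrix, truth)``.  Planted miRs of module *k*
    share the module's (ATRA, Lapatinib, interaction) effect pattern up to a
    positive per-feature multiplier; each planted target mRNA carries the
    negated pattern, so true (miR, target) profiles anti-correlate across
    samples.  Non-planted features are pure noise around their baselines.
    """
    config.validate()
    rng_mir, rng_mrna, rng_shared = _streams(config.seed, 3)

    sheet = _design(config.n_replicates)
    n_samples = len(sheet)
    a = sheet["ATRA"].to_numpy()
    l = sheet["Lapatinib"].to_numpy()
    labels = _module_labels(config.n_modules)

    # per-sample, per-module design response + shared activity component
    patterns = np.asarray(config.effect_size_log2, dtype=float)  # (M, 3)
    base_resp = (patterns[:, 0][:, None] * a
                 + patterns[:, 1][:, None] * l
                 + patterns[:, 2][:, None] * (a * l))        # (M, S)
    activity = rng_shared.normal(0.0, config.module_activity_sd,
                                 size=(config.n_modules, n_samples))
    module_signal = base_resp + activity                      # (M, S)

    mir_ids = [f"miR-{i:04d}" for i in range(1, config.n_mirs + 1)]
    mrna_ids = [f"gene-{i:05d}" for i in range(1, config.n_mrnas + 1)]

    truth = GroundTruth()
    module_of_mir: dict[str, int] = {}
    pos = 0
    for k, m in enumerate(config.mirs_per_module):
        for j in range(m):
            mid = mir_ids[pos + j]
            module_of_mir[mid] = k
            truth.module_of[mid] = labels[k]
            truth.regulated_mirs[mid] = {
                "atra": int(np.sign(patterns[k, 0])),
                "lapatinib": int(np.sign(patterns[k, 1])),
                "interaction": int(np.sign(patterns[k, 2])),
            }
        pos += m
    module_of_target: dict[str, int] = {}
    pos = 0
    for k, m in enumerate(config.targets_per_module):
        for j in range(m):
            gid = mrna_ids[pos + j]
            module_of_target[gid] = k
            truth.module_of[gid] = labels[k]
        pos += m
    truth.edges = {
        (mid, gid)
        for mid, km in module_of_mir.items()
        for gid, kt in module_of_target.items()
        if km == kt
    }

    def _matrix(ids, module_of, sign, rng):
        n = len(ids)
        planted = np.array([f in module_of for f in ids])
        base = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
        # planted features must sit safely above the detection threshold
        base[planted] = np.maximum(base[planted], config.detection_threshold + 1.0)
        # push a fraction of non-planted features below detection
        npl = np.where(~planted)[0]
        n_und = int(round(config.undetected_fraction * len(npl)))
        und = rng.choice(npl, size=n_und, replace=False) if n_und else []
        base[und] = config.detection_threshold - np.abs(
            rng.normal(2.0, 0.5, size=n_und)
        )
        values = np.tile(base[:, None], (1, n_samples))
        mult = rng.uniform(0.8, 1.2, size=n)
        for i, f in enumerate(ids):
            k = module_of.get(f)
            if k is not None:
                values[i] += sign * mult[i] * module_signal[k]
        values += rng.normal(0.0, config.noise_sd, size=values.shape)
        return pd.DataFrame(values, index=ids, columns=sheet.index)

    mir_matrix = ExpressionMatrix(
        _matrix(mir_ids, module_of_mir, +1.0, rng_mir), sheet.copy()
    )
    mrna_matrix = ExpressionMatrix(
        _matrix(mrna_ids, {g: k for g, k in module_of_target.items()},
                -config.target_coupling, rng_mrna),
        sheet.copy(),
    )
    logger.info(
        "simulated experiment: %d miRs (%d planted), %d mRNAs (%d planted), "
        "%d samples", config.n_mirs, len(module_of_mir), config.n_mrnas,
        len(module_of_target), n_samples,
    )
    return mir_matrix, mrna_matrix, truth


def simulate_predictions(truth: GroundTruth, config: SimulationConfig,
                         mir_ids=None, mrna_ids=None) -> list[pd.DataFrame]:
    """Generate per-source candidate edge lists from the planted edge set.

    Each source independently lists every true edge with probability
    ``pred_sensitivity`` and every non-edge with probability ``pred_fpr``.
    Returns one two-column DataFrame (``mir_id``, ``mrna_id``) per source.
    """
    config.validate()
    if not truth.edges:
        raise ValueError("ground truth carries no planted edges")
    if mir_ids is None:
        mir_ids = sorted({m for m, _ in truth.edges})
    if mrna_ids is None:
        mrna_ids = sorted({g for _, g in truth.edges})
    mir_ids = list(mir_ids)
    mrna_ids = list(mrna_ids)
    true_edges = sorted(truth.edges)
    n_pairs = len(mir_ids) * len(mrna_ids)
    n_non = n_pairs - len(true_edges)
    true_flat = {
        mir_ids.index(m) * len(mrna_ids) + mrna_ids.index(g)
        for m, g in true_edges
        if m in set(mir_ids) and g in set(mrna_ids)
    }

    rngs = _streams(config.seed + 1_000_003, config.n_pred_sources)
    sources = []
    for rng in rngs:
        keep = rng.random(len(true_edges)) < config.pred_sensitivity
        edges = [e for e, k in zip(true_edges, keep) if k]
        if config.pred_fpr > 0 and n_non > 0:
            n_fp = rng.binomial(n_non, config.pred_fpr)
            # sample flat indices, reject collisions with true edges
            chosen: set[int] = set()
            while len(chosen) < n_fp:
                cand = rng.integers(0, n_pairs, size=2 * (n_fp - len(chosen)) + 8)
                for c in cand:
                    c = int(c)
                    if c not in true_flat and c not in chosen:
                        chosen.add(c)
                        if len(chosen) == n_fp:
                            break
            edges += [
                (mir_ids[c // len(mrna_ids)], mrna_ids[c % len(mrna_ids)])
                for c in sorted(chosen)
            ]
        sources.append(pd.DataFrame(edges, columns=["mir_id", "mrna_id"]))
    logger.info("simulated %d prediction sources, sizes %s",
                len(sources), [len(s) for s in sources])
    return sources


def simulate_cohort(module_weights: dict, config: SimulationConfig,
                    signature_mirs: dict | None = None):
    """Generate a clinical cohort driven by a planted signature score.

    Parameters
    ----------
    module_weights
        module label -> +1/-1 direction weight (e.g. from a
        :class:`~mirmodscore.network.ModuleAssignment` or the fixed
        +1/+1 for Modules 1,3 and -1 for Modules 2,4 convention).
    signature_mirs
        miR id -> module label for the signature members; defaults to four
        synthetic miRs per module.

    The latent per-tumor score is standard normal minus ``stage_effect`` per
    ordinal step of the size/stage categories; signature miR expression loads
    on it with sign = the miR's module weight; proliferation correlates
    negatively with it; survival is exponential with
    log-hazard = -``hazard_log_hr_per_sd`` x standardized score, censored at
    ``censor_horizon``.  ``round(cohort_n * matched_fraction)`` tumors get a
    matched normal whose signature miRs are shifted by ``normal_shift`` in the
    direction of their weight.
    """
    config.validate()
    if not module_weights:
        raise ValueError("module_weights is empty")
    bad = {m: w for m, w in module_weights.items() if w not in (-1, 1)}
    if bad:
        raise ValueError(f"direction weights must be +1/-1, got {bad}")
    if signature_mirs is None:
        signature_mirs = {
            f"miR-{lab}-{j}": lab
            for lab in module_weights for j in range(1, 5)
        }
    unknown = {m for m, lab in signature_mirs.items() if lab not in module_weights}
    if unknown:
        raise ValueError(f"signature miRs reference unweighted modules: {sorted(unknown)}")

    rng_clin, rng_expr, rng_surv = _streams(config.seed + 2_000_003, 3)
    n = config.cohort_n
    tumor_ids = [f"T{i:04d}" for i in range(1, n + 1)]

    # ordinal categories first, then a latent score decreasing in them
    size_idx = rng_clin.choice(4, size=n, p=(0.35, 0.4, 0.15, 0.1))
    stage_idx = np.clip(
        size_idx + rng_clin.choice((-1, 0, 1), size=n, p=(0.2, 0.6, 0.2)), 0, 3
    )
    z = rng_clin.normal(0.0, 1.0, size=n)
    score = z - config.stage_effect * (size_idx + stage_idx) / 2.0
    score = (score - score.mean()) / score.std(ddof=0)
    proliferation = (-config.prolif_slope * score
                     + rng_clin.normal(0, np.sqrt(1 - min(config.prolif_slope ** 2, 1)),
                                       size=n))
    prog = np.select(
        [stage_idx == 0, stage_idx <= 2], ["DCIS", "IDC"], default="MET"
    )

    lam = config.baseline_hazard * np.exp(-config.hazard_log_hr_per_sd * score)
    t_event = rng_surv.exponential(1.0 / lam)
    os_time = np.minimum(t_event, config.censor_horizon)
    os_event = (t_event <= config.censor_horizon).astype(int)

    n_matched = int(round(config.matched_fraction * n))
    matched = rng_clin.choice(n, size=n_matched, replace=False) if n_matched else []

    clin = pd.DataFrame({
        "tissue": "tumor",
        "pair_id": pd.array([None] * n, dtype=object),
        "progression_stage": prog,
        "size_cat": [SIZE_LEVELS[i] for i in size_idx],
        "stage_cat": [STAGE_LEVELS[i] for i in stage_idx],
        "proliferation": proliferation,
        "os_time": os_time,
        "os_event": os_event,
    }, index=pd.Index(tumor_ids, name="sample"))

    sig_ids = list(signature_mirs)
    weights = np.array([module_weights[signature_mirs[m]] for m in sig_ids],
                       dtype=float)
    mu = rng_expr.normal(config.baseline_mean, config.baseline_sd, size=len(sig_ids))
    tumor_expr = (mu[:, None]
                  + weights[:, None] * config.signature_loading * score[None, :]
                  + rng_expr.normal(0, config.cohort_noise_sd,
                                    size=(len(sig_ids), n)))

    columns = list(tumor_ids)
    expr_blocks = [tumor_expr]
    normal_rows = []
    for idx in matched:
        tid = tumor_ids[idx]
        nid = f"N{tid[1:]}"
        pid = f"P{tid[1:]}"
        clin.loc[tid, "pair_id"] = pid
        normal_expr = (tumor_expr[:, idx]
                       + weights * config.normal_shift
                       + rng_expr.normal(0, config.cohort_noise_sd, size=len(sig_ids)))
        expr_blocks.append(normal_expr[:, None])
        columns.append(nid)
        normal_rows.append(pd.Series({
            "tissue": "normal", "pair_id": pid,
            "progression_stage": "NT", "size_cat": None, "stage_cat": None,
            "proliferation": np.nan, "os_time": np.nan, "os_event": np.nan,
        }, name=nid))
    if normal_rows:
        clin = pd.concat([clin, pd.DataFrame(normal_rows)])

    values = pd.DataFrame(np.hstack(expr_blocks), index=sig_ids, columns=columns)
    cohort = ExpressionMatrix(values, clin.copy())
    truth = GroundTruth(
        module_of={m: signature_mirs[m] for m in sig_ids},
        true_scores=pd.Series(score, index=tumor_ids, name="true_score"),
    )
    logger.info("simulated cohort: %d tumors, %d matched normals, %d signature miRs",
                n, len(normal_rows), len(sig_ids))
    return cohort, ClinicalTable(clin), truth
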
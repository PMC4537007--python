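"""Signed miR-signature similarity scores.

For a signature of miRs with per-miR weights w_i in {+1, -1} (the sign of
the miR's module regulation by the drug combination) and normalized
expression x_i in a test sample, the similarity score is the signed sum

    score = sum_i w_i * x_i .

The *general score* sums over all signature miRs; the *impact score* over
the over-connected subset (degree > 50 in the integrated network) only.
Per-module scores restrict the sum to a single module's miRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix
from .network import ModuleAssignment

logger = logging.getLogger(__name__)

NORMALIZATION_MODES = ("zscore_per_mir", "log2_ratio_vs_matched_normal", "raw")


@dataclass
class SignatureDefinition:
    mir_ids: list
    weight_of: dict                 # miR -> +1/-1
    impact_subset: set = field(default_factory=set)
    module_of: dict = field(default_factory=dict)   # miR -> module label

    def __post_init__(self) -> None:
        bad = {m: w for m, w in self.weight_of.items() if w not in (-1, 1)}
        if bad:
            raise ValueError(f"weights must be +1/-1: {bad}")
        missing = set(self.mir_ids) - set(self.weight_of)
        if missing:
            raise ValueError(f"miRs without weights: {sorted(missing)[:5]}")
        extra = set(self.impact_subset) - set(self.mir_ids)
        if extra:
            raise ValueError(f"impact subset outside signature: {sorted(extra)[:5]}")

    def restricted(self, mirs) -> "SignatureDefinition":
        mirs = [m for m in self.mir_ids if m in set(mirs)]
        return SignatureDefinition(
            mir_ids=mirs,
            weight_of={m: self.weight_of[m] for m in mirs},
            impact_subset=set(self.impact_subset) & set(mirs),
            module_of={m: v for m, v in self.module_of.items() if m in set(mirs)},
        )


def signature_from_modules(modules: ModuleAssignment,
                           overconnected) -> SignatureDefinition:
    """Signature of all module miRs, weighted by their module's direction."""
    if not modules.direction_weight:
        raise ValueError("module assignment carries no direction weights")
    mir_ids, weight_of, module_of = [], {}, {}
    for lab in modules.modules:
        w = modules.direction_weight[lab]
        for m in sorted(modules.members(lab)):
            module_of[m] = lab
            weight_of[m] = w
            mir_ids.append(m)
    # only miRs can be signature members: callers pass module miR sets
    return SignatureDefinition(
        mir_ids=mir_ids, weight_of=weight_of,
        impact_subset=set(overconnected) & set(mir_ids), module_of=module_of,
    )


def normalize_cohort(cohort: ExpressionMatrix, mode: str = "zscore_per_mir",
                     clinical: ClinicalTable | None = None) -> ExpressionMatrix:
    """Normalize cohort expression prior to scoring.

    ``zscore_per_mir`` standardizes each miR across cohort samples;
    ``log2_ratio_vs_matched_normal`` subtracts each sample's matched
    normal (requires pair ids and drops unmatched samples with a logged
    count); ``raw`` passes through.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if mode == "raw":
        return cohort
    if mode == "zscore_per_mir":
        v = cohort.values
        sd = v.std(axis=1, ddof=0)
        sd = sd.replace(0, 1.0)
        z = v.sub(v.mean(axis=1), axis=0).div(sd, axis=0)
        return ExpressionMatrix(z, cohort.sample_sheet.copy())
    # log2 ratio vs matched normal
    if clinical is None:
        clinical = ClinicalTable(cohort.sample_sheet)
    pairs = clinical.matched_pairs()
    if len(pairs) == 0:
        raise ValueError("log2_ratio normalization requires matched pairs")
    keep, ref = [], []
    for _, row in pairs.iterrows():
        if row["tumor"] in cohort.sample_ids and row["normal"] in cohort.sample_ids:
            keep.append(row["tumor"])
            ref.append(row["normal"])
    dropped = cohort.n_samples - len(keep)
    if dropped:
        logger.info("log2_ratio normalization: dropped %d unpaired samples", dropped)
    v = cohort.values[keep].to_numpy() - cohort.values[ref].to_numpy()
    return ExpressionMatrix(
        pd.DataFrame(v, index=cohort.feature_ids, columns=keep),
        cohort.sample_sheet.loc[keep].copy(),
    )


def score_samples(cohort: ExpressionMatrix, sig: SignatureDefinition,
                  normalization: str = "zscore_per_mir",
                  clinical: ClinicalTable | None = None) -> pd.DataFrame:
    """Similarity scores per sample: general, impact and per-module columns.

    Signature miRs absent from the cohort are dropped (logged); at least
    one must be present.  Returns a DataFrame indexed by sample id with
    columns ``general_score``, ``impact_score``, ``score_<module>``, plus
    the ``normalization_mode`` and effective signature size used.
    """
    norm = normalize_cohort(cohort, normalization, clinical)
    present = [m for m in sig.mir_ids if m in norm.feature_ids]
    if not present:
        raise ValueError("no signature miR present in the cohort matrix")
    if len(present) < len(sig.mir_ids):
        logger.warning("dropped %d signature miRs absent from cohort",
                       len(sig.mir_ids) - len(present))
    eff = sig.restricted(present)

    def _score(mirs) -> np.ndarray:
        mirs = list(mirs)
        if not mirs:
            return np.full(norm.n_samples, np.nan)
        w = np.array([eff.weight_of[m] for m in mirs], dtype=float)
        x = norm.values.loc[mirs].to_numpy()
        return w @ x

    out = pd.DataFrame(index=norm.sample_ids)
    out["general_score"] = _score(eff.mir_ids)
    out["impact_score"] = _score(sorted(eff.impact_subset))
    for lab in sorted(set(eff.module_of.values())):
        mirs = [m for m in eff.mir_ids if eff.module_of.get(m) == lab]
        out[f"score_{lab}"] = _score(mirs)
    out["normalization_mode"] = normalization
    out["n_signature_mirs"] = len(eff.mir_ids)
    logger.info("scored %d samples with %d/%d signature miRs (%s)",
                len(out), len(eff.mir_ids), len(sig.mir_ids), normalization)
    return out
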
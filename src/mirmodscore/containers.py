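"""Core data containers shared across the pipeline.

Expression data is held as a plain features x samples :class:`pandas.DataFrame`
of log2 intensities together with a sample sheet describing either the 2x2
treatment design (columns ``ATRA``, ``Lapatinib``, ``replicate``) or the
clinical role of each cohort sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical names for the four cells of the 2x2 treatment design
CONDITIONS = ("vehicle", "atra", "lapatinib", "combo")


def condition_labels(sample_sheet: pd.DataFrame) -> pd.Series:
    """Map each sample of a 2x2 design sheet to its condition name."""
    missing = [c for c in ("ATRA", "Lapatinib") if c not in sample_sheet.columns]
    if missing:
        raise ValueError(f"sample sheet lacks design columns: {missing}")
    a = sample_sheet["ATRA"].astype(int)
    l = sample_sheet["Lapatinib"].astype(int)
    lab = pd.Series("vehicle", index=sample_sheet.index, dtype=object)
    lab[(a == 1) & (l == 0)] = "atra"
    lab[(a == 0) & (l == 1)] = "lapatinib"
    lab[(a == 1) & (l == 1)] = "combo"
    return lab


@dataclass
class ExpressionMatrix:
    """Log2 expression values (features in rows) plus per-sample annotations.

    Parameters
    ----------
    values
        features x samples log2 matrix; index = feature ids, columns = sample ids.
    sample_sheet
        one row per sample, indexed by sample id.  For treatment experiments it
        carries ``ATRA``/``Lapatinib``/``replicate``; for cohorts it carries
        clinical fields.
    detected
        optional boolean per-feature flag (set by the detectable-expression
        filter).
    """

    values: pd.DataFrame
    sample_sheet: pd.DataFrame
    detected: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        missing = self.values.columns.difference(self.sample_sheet.index)
        if len(missing):
            raise ValueError(
                f"sample sheet does not cover samples: {list(missing)[:5]}"
            )
        # align sheet to matrix column order
        self.sample_sheet = self.sample_sheet.loc[self.values.columns]

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(ids)], self.sample_sheet.copy())

    def condition_means(self) -> pd.DataFrame:
        """Per-condition mean expression (features x 4 conditions)."""
        labels = condition_labels(self.sample_sheet)
        groups = {c: self.values.loc[:, labels[labels == c].index].mean(axis=1)
                  for c in CONDITIONS if (labels == c).any()}
        return pd.DataFrame(groups)


# ordered level sets for the clinical categorical fields
PROGRESSION_LEVELS = ("NT", "DCIS", "IDC", "MET")
SIZE_LEVELS = ("T1", "T2", "T3", "T4")
STAGE_LEVELS = ("I", "II", "III", "IV")

CLINICAL_COLUMNS = (
    "tissue", "pair_id", "progression_stage", "size_cat", "stage_cat",
    "proliferation", "os_time", "os_event",
)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations for a cohort.

    ``table`` is indexed by sample id and may contain any subset of
    :data:`CLINICAL_COLUMNS`; analyses check for the columns they need.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in clinical table")
        if "os_time" in self.table.columns:
            t = self.table["os_time"].dropna()
            if (t < 0).any():
                raise ValueError("negative survival times")
        if "tissue" in self.table.columns:
            bad = set(self.table["tissue"].dropna()) - {"normal", "tumor"}
            if bad:
                raise ValueError(f"unknown tissue labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def matched_pairs(self) -> pd.DataFrame:
        """Return one row per complete (normal, tumor) pair: columns normal, tumor."""
        if "pair_id" not in self.table.columns or "tissue" not in self.table.columns:
            raise ValueError("clinical table lacks pair_id/tissue columns")
        t = self.table.dropna(subset=["pair_id"])
        rows = []
        for pid, grp in t.groupby("pair_id"):
            tissues = grp["tissue"]
            if set(tissues) == {"normal", "tumor"}:
                rows.append({
                    "pair_id": pid,
                    "normal": tissues[tissues == "normal"].index[0],
                    "tumor": tissues[tissues == "tumor"].index[0],
                })
        return pd.DataFrame(rows, columns=["pair_id", "normal", "tumor"])


@dataclass
class GroundTruth:
    """Planted structure carried alongside simulated data.

    Attributes
    ----------
    regulated_mirs
        miR id -> {"atra": sign, "lapatinib": sign, "interaction": sign}
        (signs in {-1, 0, +1}).
    edges
        set of planted (mir_id, mrna_id) regulatory pairs.
    module_of
        node id -> module label for every planted module member.
    true_scores
        per-sample latent signature score for simulated cohorts (None for
        treatment experiments).
    """

    regulated_mirs: dict = field(default_factory=dict)
    edges: set = field(default_factory=set)
    module_of: dict = field(default_factory=dict)
    true_scores: pd.Series | None = None
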
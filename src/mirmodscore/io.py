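"""Readers and writers for the pipeline's text formats.

All tabular formats are TSV; graphs are written as SIF and GraphML with
node kind / module attributes.  Writers and readers round-trip exactly.
"""

from __future__ import annotations

import json
import logging

import networkx as nx
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix, GroundTruth
from .network import BipartiteNetwork, ModuleAssignment

logger = logging.getLogger(__name__)


def write_expression(matrix: ExpressionMatrix, values_path, sheet_path) -> None:
    matrix.values.to_csv(values_path, sep="\t", index_label="feature_id")
    matrix.sample_sheet.to_csv(sheet_path, sep="\t", index_label="sample")


def read_expression(values_path, sheet_path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="feature_id")
    sheet = pd.read_csv(sheet_path, sep="\t", index_col="sample")
    return ExpressionMatrix(values, sheet)


def write_edge_list(edges: pd.DataFrame, path) -> None:
    cols = [c for c in ("mir_id", "mrna_id", "rho", "p_corr", "q_corr", "sources")
            if c in edges.columns]
    out = edges[cols].copy()
    if "sources" in out.columns:
        out["sources"] = out["sources"].map(
            lambda s: ",".join(s) if not isinstance(s, str) else s)
    out.to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for i, row in enumerate(df.itertuples(index=False), 2):
        if pd.isna(getattr(row, "mir_id", None)) or pd.isna(getattr(row, "mrna_id", None)):
            raise ValueError(f"{path}:{i}: malformed edge row")
    if "sources" in df.columns:
        df["sources"] = df["sources"].map(
            lambda s: tuple(str(s).split(",")) if pd.notna(s) else ())
    return df


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.table.to_csv(path, sep="\t", index_label="sample")


def read_clinical(path) -> ClinicalTable:
    return ClinicalTable(pd.read_csv(path, sep="\t", index_col="sample"))


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index_label="sample")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_sif(net: BipartiteNetwork, path,
              interaction: str = "targets") -> None:
    with open(path, "w") as fh:
        for mir, mrna in sorted(net.edges):
            fh.write(f"{mir}\t{interaction}\t{mrna}\n")


def write_graphml(net: BipartiteNetwork, path,
                  modules: ModuleAssignment | None = None) -> None:
    g = net.graph.copy()
    if modules is not None:
        for n in g.nodes:
            g.nodes[n]["module"] = modules.module_of.get(n, "no_module")
    nx.write_graphml(g, path)


def read_graphml(path) -> BipartiteNetwork:
    g = nx.read_graphml(path)
    return BipartiteNetwork(nx.Graph(g))


def write_modules(modules: ModuleAssignment, path) -> None:
    rows = [{"node": n, "module": lab} for n, lab in sorted(modules.module_of.items())]
    df = pd.DataFrame(rows)
    df["direction_weight"] = df["module"].map(
        lambda lab: modules.direction_weight.get(lab, ""))
    df.to_csv(path, sep="\t", index=False)


def read_modules(path) -> ModuleAssignment:
    df = pd.read_csv(path, sep="\t")
    module_of = dict(zip(df["node"], df["module"]))
    labels = sorted({m for m in df["module"] if m != "no_module"},
                    key=lambda s: (len(s), s))
    weights = {}
    for lab in labels:
        vals = df.loc[df["module"] == lab, "direction_weight"].dropna().unique()
        vals = [v for v in vals if str(v).strip() != ""]
        if vals:
            weights[lab] = int(float(vals[0]))
    return ModuleAssignment(module_of=module_of, modules=labels,
                            direction_weight=weights)


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Persist planted structure as a documented JSON schema."""
    payload = {
        "schema": "mirmodscore-ground-truth-v1",
        "regulated_mirs": truth.regulated_mirs,
        "edges": sorted(map(list, truth.edges)),
        "module_of": truth.module_of,
        "true_scores": (truth.true_scores.to_dict()
                        if truth.true_scores is not None else None),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    scores = payload.get("true_scores")
    return GroundTruth(
        regulated_mirs=payload["regulated_mirs"],
        edges={tuple(e) for e in payload["edges"]},
        module_of=payload["module_of"],
        true_scores=pd.Series(scores) if scores is not None else None,
    )
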
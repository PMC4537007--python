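"""Hypergeometric over-representation of a query gene set in a collection.

Generalizes process-network enrichment of module target genes to any
user-supplied GMT collection.  The p-value for a set with ``n_total``
members in a background of size ``M`` and a query of size ``N`` is the
upper-tail hypergeometric probability of observing >= ``n_hit`` overlaps;
FDR is Benjamini-Hochberg over the collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .integration import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    sets: dict          # set name -> set of gene ids
    background: set     # gene id universe

    def __post_init__(self) -> None:
        if not self.background:
            raise ValueError("empty background universe")
        self.background = set(self.background)
        clipped = {}
        for name, genes in self.sets.items():
            genes = set(genes) & self.background
            if len(genes) < len(set(self.sets[name])):
                logger.warning("set %r: dropped members outside background", name)
            clipped[name] = genes
        self.sets = clipped


def enrich(query, collection: GeneSetCollection,
           fdr_cutoff: float = 0.05) -> pd.DataFrame:
    """Over-representation of ``query`` in each collection set.

    Query ids outside the background are dropped with a logged count.
    Returns rows sorted by FDR with columns ``set_name``, ``n_total``,
    ``n_hit``, ``p_hyper``, ``fdr``, ``significant`` (strict
    fdr < ``fdr_cutoff``).
    """
    query = set(query)
    in_bg = query & collection.background
    if len(in_bg) < len(query):
        logger.warning("dropped %d query genes outside the background",
                       len(query) - len(in_bg))
    M = len(collection.background)
    N = len(in_bg)
    rows = []
    for name, genes in collection.sets.items():
        k = len(genes & in_bg)
        # P(X >= k) for X ~ Hypergeom(M, |set|, N)
        p = float(stats.hypergeom.sf(k - 1, M, len(genes), N))
        rows.append({"set_name": name, "n_total": len(genes), "n_hit": k,
                     "p_hyper": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p_hyper"].to_numpy()) if len(out) else []
    out["significant"] = out["fdr"] < fdr_cutoff
    out = out.sort_values(["fdr", "p_hyper", "set_name"]).reset_index(drop=True)
    logger.info("enrichment: %d / %d sets significant at FDR < %g",
                int(out["significant"].sum()), len(out), fdr_cutoff)
    return out


def read_gmt(path, background=None) -> GeneSetCollection:
    """Read a GMT file (set name, description, members per tab-separated line).

    When ``background`` is None the union of all set members is used.
    """
    sets = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            parts = line.rstrip("\r\n").split("\t")
            if len(parts) < 3:
                if line.strip():
                    raise ValueError(f"{path}:{i}: malformed GMT line")
                continue
            sets[parts[0]] = set(filter(None, parts[2:]))
    if background is None:
        background = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets=sets, background=set(background))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")
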
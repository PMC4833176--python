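"""Correlation-threshold co-expression networks from expression matrices.

The expression matrix convention throughout the package is a pandas
DataFrame of non-negative RPKM values with genes as the index and samples as
columns.  Network construction follows three steps: an expression filter
(RPKM >= 1 in >= 5% of samples by default), pairwise Pearson correlation of
(by default log2(x+1)-transformed) profiles, and edge retention either at a
fixed correlation cutoff (r >= 0.7 by default) or as the strongest fraction
of all pairs.  Both retention modes report the achieved edge fraction and
the implied r cutoff so they can be cross-checked against one another.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRANSFORMS = ("log2p1", "none")
THRESHOLD_MODES = ("absolute_r", "top_fraction")


def validate_expression(expr: pd.DataFrame, require_nonnegative: bool = True) -> None:
    if expr.index.duplicated().any():
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in expression matrix: {dupes[:5]}")
    if require_nonnegative and (expr.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative (RPKM-like)")


def filter_expressed(
    expr: pd.DataFrame, min_rpkm: float = 1.0, min_fraction: float = 0.05
) -> pd.DataFrame:
    """Keep genes with value >= ``min_rpkm`` in >= ceil(min_fraction * S)
    samples; both comparisons are inclusive."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    validate_expression(expr)
    needed = math.ceil(min_fraction * expr.shape[1])
    kept = expr[(expr >= min_rpkm).sum(axis=1) >= needed]
    if kept.empty:
        logger.warning("expression filter removed every gene")
    return kept


def correlation_edges(expr: pd.DataFrame, transform: str = "log2p1") -> pd.DataFrame:
    """Dense gene-by-gene Pearson correlation matrix.

    Zero-variance genes get NaN rows/columns; they can never form edges.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; expected one of {TRANSFORMS}")
    # RPKM non-negativity only matters when the log transform is applied;
    # plain correlation accepts any real-valued profiles
    validate_expression(expr, require_nonnegative=(transform == "log2p1"))
    if expr.shape[1] < 3:
        raise ValueError(f"need >= 3 samples to correlate, got {expr.shape[1]}")
    values = expr.to_numpy(dtype=float)
    if transform == "log2p1":
        values = np.log2(values + 1.0)
    constant = values.std(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    return pd.DataFrame(r, index=expr.index, columns=expr.index)


@dataclass
class CoexpressionNetwork:
    """Undirected weighted graph over gene ids.

    ``graph`` stores retained edges with a ``weight`` attribute; nodes are
    all genes with a defined (finite-variance) expression profile, so
    isolated nodes are allowed.  ``r_cutoff`` and ``achieved_fraction``
    record the retention rule actually applied.
    """

    graph: nx.Graph
    r_cutoff: float | None = None
    achieved_fraction: float | None = None
    n_boundary_ties: int = 0

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, a: str, b: str) -> float:
        """Edge weight, or 0.0 when the pair is not connected."""
        data = self.graph.get_edge_data(a, b)
        return 0.0 if data is None else data["weight"]

    def write_edgelist(self, path: str | Path) -> None:
        rows = sorted(
            (min(a, b), max(a, b), w) for a, b, w in self.graph.edges(data="weight")
        )
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"]).to_csv(
            path, sep="\t", index=False
        )

    def write_nodes(self, path: str | Path) -> None:
        pd.DataFrame({"gene_id": sorted(self.graph.nodes)}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read_edgelist(
        cls, edge_path: str | Path, node_path: str | Path | None = None
    ) -> "CoexpressionNetwork":
        df = pd.read_csv(edge_path, sep="\t", dtype={"gene_a": str, "gene_b": str})
        g = nx.Graph()
        if node_path is not None:
            g.add_nodes_from(pd.read_csv(node_path, sep="\t", dtype=str)["gene_id"])
        g.add_weighted_edges_from(df.itertuples(index=False, name=None))
        return cls(graph=g)


def threshold_network(
    r: pd.DataFrame, mode: str = "absolute_r", value: float = 0.7
) -> CoexpressionNetwork:
    """Retain the strongest edges of a correlation matrix.

    ``absolute_r`` keeps pairs with signed r >= value (negative correlations
    are never edges); ``top_fraction`` keeps the floor(value * n_pairs)
    largest-r pairs, extending through ties at the boundary value.
    """
    if mode not in THRESHOLD_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {THRESHOLD_MODES}")
    if not 0 < value < 1:
        raise ValueError("value must lie in (0, 1)")
    genes = np.asarray(r.index)
    mat = r.to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(genes), k=1)
    weights = mat[iu, ju]
    finite = np.isfinite(weights)
    iu, ju, weights = iu[finite], ju[finite], weights[finite]
    n_pairs = weights.size

    n_boundary_ties = 0
    if mode == "absolute_r":
        cutoff = value
        keep = weights >= cutoff
    else:
        target = int(math.floor(value * n_pairs))
        if target == 0 or n_pairs == 0:
            keep = np.zeros(n_pairs, dtype=bool)
            cutoff = None
        else:
            order = np.argsort(weights)[::-1]
            cutoff = float(weights[order[target - 1]])
            keep = weights >= cutoff
            n_boundary_ties = int(keep.sum()) - target
            if n_boundary_ties:
                logger.info(
                    "kept %d tied pair(s) at the top-fraction boundary r = %g",
                    n_boundary_ties,
                    cutoff,
                )

    graph = nx.Graph()
    # nodes: every gene with a defined correlation profile (zero-variance
    # genes were masked to NaN, including the diagonal)
    defined = np.isfinite(np.diag(mat))
    graph.add_nodes_from(genes[defined])
    for i, j, w in zip(iu[keep], ju[keep], weights[keep]):
        graph.add_edge(genes[i], genes[j], weight=float(w))
    achieved = graph.number_of_edges() / n_pairs if n_pairs else 0.0
    return CoexpressionNetwork(
        graph=graph,
        r_cutoff=cutoff,
        achieved_fraction=achieved,
        n_boundary_ties=n_boundary_ties,
    )


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    validate_expression(expr)
    return expr
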
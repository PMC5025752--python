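"""Signed co-expression networks, the pan-cancer consensus, and
cancer-specific subnetworks.

Per cancer, genes (restricted to that cancer's DEGs vs normal) are linked
when their Pearson correlation over tumor samples ranks in the top 0.5%
positive or top 0.5% negative of all pairs; isolated nodes are dropped. The
consensus (pan-cancer) network keeps edges recurring in at least
``min_recurrence`` per-cancer networks. Cancer-specific subnetworks are the
largest connected component of a supplied curated interaction network
induced on the cancer's specific gene set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, canonical_pair

__all__ = [
    "CoexpressionNetwork",
    "ConsensusNetwork",
    "pcc_matrix",
    "threshold_edges",
    "consensus_network",
    "largest_connected_component",
    "cancer_specific_subnetwork",
]


@dataclass
class CoexpressionNetwork:
    """Signed thresholded co-expression edges for one cancer type.

    ``edges`` maps a canonical (a < b) gene pair to (sign, pcc).
    """

    cancer_type: str
    edges: dict[tuple[str, str], tuple[str, float]]

    @property
    def nodes(self) -> set[str]:
        return {g for pair in self.edges for g in pair}

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, s, r) for (a, b), (s, r) in sorted(self.edges.items())]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "sign", "pcc"])


@dataclass
class ConsensusNetwork:
    """Recurrence-annotated merged edges across per-cancer networks."""

    edges: dict[tuple[str, str], tuple[int, bool]]  # pair -> (recurrence, sign_agreement)
    min_recurrence: int

    @property
    def nodes(self) -> set[str]:
        return {g for pair in self.edges for g in pair}

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for (a, b), (rec, agree) in self.edges.items():
            g.add_edge(a, b, recurrence=rec, sign_agreement=agree)
        return g

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, r, s) for (a, b), (r, s) in sorted(self.edges.items())]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "recurrence", "sign_agreement"])


def pcc_matrix(logcpm: ExpressionMatrix, gene_subset=None) -> pd.DataFrame:
    """Symmetric Pearson correlation grid between genes.

    Needs at least three samples; genes with zero variance are excluded
    with a warning.
    """
    values = logcpm.values
    if gene_subset is not None:
        genes = [g for g in gene_subset if g in values.index]
        values = values.loc[genes]
    if values.shape[1] < 3:
        raise ValueError("correlation needs at least three samples")
    sd = values.to_numpy().std(axis=1)
    if (sd == 0).any():
        dropped = [g for g, s in zip(values.index, sd) if s == 0]
        warnings.warn(f"excluding {len(dropped)} zero-variance genes from correlation")
        values = values.loc[sd > 0]
    r = np.corrcoef(values.to_numpy())
    r = (r + r.T) / 2.0  # exact symmetry (corrcoef can differ in the last ulp)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=values.index, columns=values.index)


def threshold_edges(
    pcc_grid: pd.DataFrame, q: float = 0.005, cancer_type: str = ""
) -> CoexpressionNetwork:
    """Keep the top-``q`` fraction of positive and of negative correlations.

    k = floor(q · C(n, 2)) pairs are retained per sign: the k largest r as
    '+' edges and the k smallest as '−' edges; ties break by canonical pair
    order, and a pair qualifying for both lists (massive ties) is kept as
    '+'. Nodes left without any retained edge are dropped.
    """
    genes = list(pcc_grid.index)
    n = len(genes)
    if n < 2:
        raise ValueError("need at least two genes to threshold edges")
    n_pairs = n * (n - 1) // 2
    k = math.floor(q * n_pairs)
    if k == 0:
        warnings.warn("edge quota floor(q*C(n,2)) is zero; empty network")
        return CoexpressionNetwork(cancer_type, {})
    iu, ju = np.triu_indices(n, k=1)
    r = pcc_grid.to_numpy()[iu, ju]
    names = np.asarray(genes, dtype=str)
    ga, gb = names[iu].copy(), names[ju].copy()
    swap = ga > gb
    ga[swap], gb[swap] = gb[swap], ga[swap]
    # primary key: correlation; ties resolved by canonical pair order
    pos_order = np.lexsort((gb, ga, -r))
    neg_order = np.lexsort((gb, ga, r))
    edges: dict[tuple[str, str], tuple[str, float]] = {}
    for idx in pos_order[:k]:
        edges[(ga[idx], gb[idx])] = ("+", float(r[idx]))
    for idx in neg_order[:k]:
        edges.setdefault((ga[idx], gb[idx]), ("-", float(r[idx])))
    return CoexpressionNetwork(cancer_type, edges)


def consensus_network(
    networks: list[CoexpressionNetwork],
    min_recurrence: int = 3,
    require_sign_match: bool = False,
) -> ConsensusNetwork:
    """Merge per-cancer networks into the recurrence-filtered consensus.

    An edge's recurrence is the number of input networks containing its
    pair (sign-respecting when ``require_sign_match``: the count is then the
    best single-sign recurrence). Pairs with recurrence ≥ ``min_recurrence``
    are kept, with a flag recording whether all contributing networks agreed
    on the sign.
    """
    if len(networks) < min_recurrence:
        raise ValueError("fewer input networks than the recurrence threshold")
    counts: dict[tuple[str, str], list[str]] = {}
    for net in networks:
        for pair, (sign, _) in net.edges.items():
            counts.setdefault(pair, []).append(sign)
    edges = {}
    for pair, signs in counts.items():
        agree = len(set(signs)) == 1
        rec = max(signs.count("+"), signs.count("-")) if require_sign_match else len(signs)
        if rec >= min_recurrence:
            edges[pair] = (rec, agree)
    return ConsensusNetwork(edges, min_recurrence)


def largest_connected_component(graph: nx.Graph) -> nx.Graph:
    """The connected component with most nodes; size ties break toward the
    component containing the lexicographically smallest node id."""
    if graph.number_of_nodes() == 0:
        return nx.Graph()
    components = sorted(
        nx.connected_components(graph), key=lambda c: (-len(c), min(map(str, c)))
    )
    return graph.subgraph(components[0]).copy()


def cancer_specific_subnetwork(
    specific_genes: set[str], interaction_network: nx.Graph | pd.DataFrame
) -> nx.Graph:
    """Largest connected component of the interaction network induced on a
    cancer's specific genes.

    ``interaction_network`` may be a graph or an edge-list DataFrame
    (gene_a, gene_b). Returns an empty graph with a warning when no
    specific gene has any interaction.
    """
    if isinstance(interaction_network, pd.DataFrame):
        g = nx.from_pandas_edgelist(interaction_network, "gene_a", "gene_b")
    else:
        g = interaction_network
    induced = g.subgraph(n for n in specific_genes if n in g)
    induced = induced.edge_subgraph(induced.edges())  # drop isolated nodes
    if induced.number_of_nodes() == 0:
        warnings.warn("no specific gene is connected in the interaction network")
        return nx.Graph()
    return largest_connected_component(induced)
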
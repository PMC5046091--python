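"""Hypergeometric over-representation analysis and term-centered subnetworks.

Query gene sets (here: protein-coding nodes of a regulatory network) are
tested against a gene-set collection with the upper hypergeometric tail
P(X >= k) and Benjamini–Hochberg adjustment; terms with adjusted value
<= 0.05 are called enriched.  For each enriched term a subnetwork is built
from the term's genes present in the network plus their first neighbours,
with seed-incident edges; miRNA membership of these subnetworks links
miRNAs to the term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mircnet.io_formats import GeneSetCollection
from mircnet.network_loops import RegNetwork, SignedEdge

logger = logging.getLogger(__name__)


@dataclass
class Subnetwork:
    seed_genes: frozenset[str]
    nodes: frozenset[str]
    edges: tuple[SignedEdge, ...]
    mirnas_present: frozenset[str]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeometric_enrichment(
    query: Iterable[str],
    sets: GeneSetCollection,
    background: Iterable[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of ``query`` in every term with overlap >= 1.

    Both the query and each term are intersected with the background first.
    Returns a DataFrame sorted by p with columns term_id, term_name, k, K,
    n, N, p_value, q_value, enriched (q <= fdr).
    """
    background = {g.upper() for g in background}
    if not background:
        raise ValueError("background gene set is empty")
    query = {g.upper() for g in query} & background
    N, n = len(background), len(query)
    rows = []
    for term_id, (term_name, genes) in sets.items():
        genes_bg = genes & background
        k = len(genes_bg & query)
        if k == 0:
            continue
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "k": k,
                "K": len(genes_bg),
                "n": n,
                "N": N,
                "p_value": hypergeometric_pvalue(k, len(genes_bg), n, N),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "term_name", "k", "K", "n", "N",
                     "p_value", "q_value", "enriched"]
        )
    df = pd.DataFrame(rows)
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    df["enriched"] = df["q_value"] <= fdr
    return df.sort_values(["p_value", "term_id"]).reset_index(drop=True)


def extract_subnetwork(
    net: RegNetwork,
    term_genes: Iterable[str],
    include_neighbor_edges: bool = False,
) -> Subnetwork:
    """Term genes present in the network, their first neighbours, and edges.

    By default only seed-incident edges are kept; with
    ``include_neighbor_edges`` every network edge whose both endpoints fall
    inside the induced node set is included.
    """
    term_genes = {g.upper() for g in term_genes}
    seed = frozenset(n for n in net.nodes if n.upper() in term_genes)
    if not seed:
        logger.warning("no term genes present in the network; empty subnetwork")
        return Subnetwork(frozenset(), frozenset(), (), frozenset())
    neighbors: set[str] = set()
    seed_edges = []
    for e in net.edges:
        if e.src in seed or e.dst in seed:
            seed_edges.append(e)
            neighbors.update((e.src, e.dst))
    nodes = frozenset(seed | neighbors)
    if include_neighbor_edges:
        edges = tuple(e for e in net.edges if e.src in nodes and e.dst in nodes)
    else:
        edges = tuple(seed_edges)
    mirnas = frozenset(n for n in nodes if "mirna" in net.nodes.get(n, frozenset()))
    return Subnetwork(seed, nodes, edges, mirnas)


def mirna_term_matrix(
    subnetworks: Mapping[str, Subnetwork], mirnas: Sequence[str] | None = None
) -> pd.DataFrame:
    """Presence table (term × miRNA): cell true iff the miRNA is in the
    term's subnetwork node set."""
    if mirnas is None:
        mirnas = sorted({m for sn in subnetworks.values() for m in sn.mirnas_present})
    data = {
        term: [m in sn.nodes for m in mirnas] for term, sn in subnetworks.items()
    }
    return pd.DataFrame(data, index=pd.Index(mirnas, name="mirna")).T
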
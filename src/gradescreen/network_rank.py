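"""Hub-gene ranking by a Z-score-weighted five-centrality composite.

A protein–protein interaction network (STRING-style TSV edge list with
confidence scores on 0–1000) is thresholded at combined score ≥ 400,
then each gene receives five centralities — betweenness, closeness, degree,
eigenvector, PageRank — which are standardized to Z-scores across the
network and combined as

    composite = 0.25·z_betw + 0.25·z_close + 0.20·z_deg
              + 0.15·z_eig + 0.15·z_pr

Genes are ranked by composite (descending, ties broken alphabetically) and
the top 30 flagged as hub candidates.  Conventions: the thresholded graph is
undirected and unweighted; betweenness and degree are normalized; closeness
uses the Wasserman–Faust per-component scaling; eigenvector centrality is
the Perron vector of the adjacency matrix (dense symmetric
eigendecomposition, unit Euclidean norm); PageRank uses damping 0.85.
Z-scores use the sample (n−1) standard deviation; a zero-variance index
contributes zero for every gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

DEFAULT_SCORE_THRESHOLD = 400  # STRING combined score, inclusive
DEFAULT_TOP_K = 30

#: (betweenness, closeness, degree, eigenvector, pagerank)
DEFAULT_CENTRALITY_WEIGHTS = (0.25, 0.25, 0.20, 0.15, 0.15)

CENTRALITY_NAMES = ("betweenness", "closeness", "degree", "eigenvector", "pagerank")


@dataclass(frozen=True)
class CentralityRecord:
    gene: str
    raw: dict[str, float]
    z: dict[str, float]
    composite: float
    rank: int
    top_k: bool


@dataclass(frozen=True)
class TopologyStats:
    density: float
    average_path_length: float  # on the largest connected component
    clustering_coefficient: float  # global transitivity


def read_edge_list(
    path: str | Path,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    nodes_path: Optional[str | Path] = None,
) -> nx.Graph:
    """Load a TSV edge list (geneA, geneB, combined_score) into an undirected graph.

    Edges with score below the (inclusive) threshold, self-loops, and
    duplicates are dropped; a duplicated undirected pair keeps its maximum
    score.  Isolated genes are included only when listed in ``nodes_path``
    (one symbol per line).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    required = {"geneA", "geneB", "combined_score"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"edge list {path} needs columns geneA, geneB, combined_score; "
            f"got {list(df.columns)}"
        )
    bad = df[pd.to_numeric(df["combined_score"], errors="coerce").isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad.index[:10]]  # +2: header + 1-based
        raise ValueError(f"malformed combined_score at line(s) {lines} in {path}")
    g = nx.Graph()
    for a, b, s in df[["geneA", "geneB", "combined_score"]].itertuples(index=False):
        score = float(s)
        if a == b or score < score_threshold:
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], score)
        else:
            g.add_edge(a, b, score=score)
    if nodes_path is not None:
        for line in Path(nodes_path).read_text().splitlines():
            sym = line.strip()
            if sym:
                g.add_node(sym)
    return g


def _eigenvector_centrality(g: nx.Graph, nodes: list[str]) -> dict[str, float]:
    """Perron vector of the adjacency matrix, non-negative, unit 2-norm."""
    a = nx.to_numpy_array(g, nodelist=nodes)
    vals, vecs = np.linalg.eigh(a)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.abs(v)  # Perron vector is entrywise non-negative
    norm = np.linalg.norm(v)
    if norm > 0:
        v = v / norm
    return dict(zip(nodes, v.tolist()))


def compute_centralities(g: nx.Graph) -> pd.DataFrame:
    """Raw betweenness/closeness/degree/eigenvector/PageRank per node."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(g.nodes())
    betw = nx.betweenness_centrality(g, normalized=True)
    close = nx.closeness_centrality(g, wf_improved=True)
    n = g.number_of_nodes()
    deg = {v: (g.degree(v) / (n - 1) if n > 1 else 0.0) for v in nodes}
    eig = _eigenvector_centrality(g, nodes)
    pr = nx.pagerank(g, alpha=0.85, tol=1e-12, max_iter=1000)
    return pd.DataFrame(
        {
            "betweenness": [betw[v] for v in nodes],
            "closeness": [close[v] for v in nodes],
            "degree": [deg[v] for v in nodes],
            "eigenvector": [eig[v] for v in nodes],
            "pagerank": [pr[v] for v in nodes],
        },
        index=pd.Index(nodes, name="gene"),
    )


def zscore_table(raw: pd.DataFrame) -> pd.DataFrame:
    """Column-wise Z-scores with sample (n−1) sd; zero-variance columns map to 0.

    "Zero variance" is judged with a small relative tolerance: a column whose
    sd is below 1e-12·max(1, |mean|) is constant up to floating-point noise
    (e.g. eigenvector values on a vertex-transitive graph) and standardizing
    it would amplify that noise into arbitrary ±z values.
    """
    if len(raw) < 2:
        raise ValueError("Z-scores need at least 2 nodes")
    z = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        x = raw[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd <= 1e-12 * max(1.0, abs(float(x.mean()))):
            z[col] = np.zeros_like(x)
        else:
            z[col] = (x - x.mean()) / sd
    return z


def composite_rank(
    z: pd.DataFrame,
    weights: Sequence[float] = DEFAULT_CENTRALITY_WEIGHTS,
    top_k: int = DEFAULT_TOP_K,
    raw: Optional[pd.DataFrame] = None,
) -> list[CentralityRecord]:
    """Weighted composite per gene, ranked descending with alphabetical tie-break."""
    w = dict(zip(CENTRALITY_NAMES, weights))
    composite = sum(w[c] * z[c] for c in CENTRALITY_NAMES)
    order = sorted(z.index, key=lambda gene: (-composite[gene], gene))
    records = []
    for rank, gene in enumerate(order, start=1):
        records.append(
            CentralityRecord(
                gene=gene,
                raw={c: float(raw.loc[gene, c]) for c in CENTRALITY_NAMES}
                if raw is not None
                else {},
                z={c: float(z.loc[gene, c]) for c in CENTRALITY_NAMES},
                composite=float(composite[gene]),
                rank=rank,
                top_k=rank <= top_k,
            )
        )
    return records


def rank_genes(
    g: nx.Graph,
    weights: Sequence[float] = DEFAULT_CENTRALITY_WEIGHTS,
    top_k: int = DEFAULT_TOP_K,
) -> list[CentralityRecord]:
    """Full pipeline: centralities, Z-scores, weighted composite, ranking."""
    raw = compute_centralities(g)
    z = zscore_table(raw)
    return composite_rank(z, weights=weights, top_k=top_k, raw=raw)


def topology_stats(g: nx.Graph) -> TopologyStats:
    """Density, average path length (largest component), global clustering."""
    if g.number_of_nodes() < 2:
        raise ValueError("topology statistics need at least 2 nodes")
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    apl = nx.average_shortest_path_length(sub) if len(comp) > 1 else 0.0
    return TopologyStats(
        density=nx.density(g),
        average_path_length=apl,
        clustering_coefficient=nx.transitivity(g),
    )


def records_to_frame(records: list[CentralityRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"gene": r.gene, "rank": r.rank, "composite": r.composite, "top_k": r.top_k}
        row.update({c: r.raw.get(c, float("nan")) for c in CENTRALITY_NAMES})
        row.update({f"z_{c}": r.z[c] for c in CENTRALITY_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)
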
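"""Pair feature engineering: statistical and graph-theoretic descriptors.

Each miRNA-disease pair is described by the concatenation of three feature
families computed from the binary association matrix A and the fused
multi-similarity matrices MMS (miRNAs) and DMS (diseases):

* type 1 - per-entity statistics: association count, mean similarity to the
  other entities, and a fixed-width histogram of the similarity row.
* type 2 - per-entity graph descriptors on the similarity graph whose edges
  join entities more similar than the off-diagonal mean: degree, the k_sim
  largest similarities, betweenness and closeness centrality.
* type 3 - per-pair descriptors: neighbour-association counts crossing the
  two similarity graphs, and both endpoints' centralities in the bipartite
  association graph.

With the defaults (5 histogram bins, k_sim=20) the feature vector has
2*(2+5) + 2*(3+20) + (2+4) = 66 components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .io import AssociationMatrix, PairFeatureTable, SimilarityMatrix

__all__ = [
    "FeatureConfig",
    "EntityGraph",
    "build_entity_graph",
    "type1_features",
    "type2_features",
    "type3_features",
    "bipartite_centralities",
    "assemble_pair_features",
    "sample_negatives",
    "FEATURE_BLOCKS",
]

FEATURE_BLOCKS = ("type1", "type2", "type3")


@dataclass
class FeatureConfig:
    k_sim: int = 20
    hist_bins: int = 5
    negative_ratio: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_sim < 1:
            raise ValueError("k_sim must be >= 1")
        if self.hist_bins < 1:
            raise ValueError("hist_bins must be >= 1")
        if self.negative_ratio <= 0:
            raise ValueError("negative_ratio must be positive")


@dataclass
class EntityGraph:
    """Similarity-threshold graph over one entity class (no self-loops)."""

    graph: nx.Graph
    source_role: str
    betweenness: dict[str, float] = field(default_factory=dict)
    closeness: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.betweenness:
            self.betweenness = nx.betweenness_centrality(self.graph, normalized=True)
        if not self.closeness:
            self.closeness = nx.closeness_centrality(self.graph, wf_improved=True)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def neighbors(self, node: str) -> list[str]:
        return list(self.graph.neighbors(node))


def build_entity_graph(sim: SimilarityMatrix) -> EntityGraph:
    """Edge (i,j) iff sim[i,j] strictly exceeds the mean off-diagonal similarity."""
    n = sim.n
    g = nx.Graph()
    g.add_nodes_from(sim.ids)
    if n > 1:
        off = ~np.eye(n, dtype=bool)
        thr = sim.values[off].mean()
        rows, cols = np.nonzero(np.triu(sim.values > thr, k=1))
        g.add_edges_from((sim.ids[i], sim.ids[j]) for i, j in zip(rows, cols))
    return EntityGraph(g, sim.role)


def _entity_axis(entity: str, A: AssociationMatrix) -> tuple[int, int]:
    """(axis, index): axis 0 for a miRNA (row), 1 for a disease (column)."""
    if entity in A.mirna_ids:
        return 0, A.mirna_ids.index(entity)
    if entity in A.disease_ids:
        return 1, A.disease_ids.index(entity)
    raise KeyError(f"unknown entity {entity!r}")


def type1_features(
    entity: str,
    A: AssociationMatrix,
    sim: SimilarityMatrix,
    cfg: FeatureConfig,
) -> np.ndarray:
    """[association count, mean similarity, similarity histogram] for one entity.

    Self-similarity is excluded from both the mean and the histogram; bins
    partition [0,1] into cfg.hist_bins equal widths with the last bin closed.
    """
    axis, idx = _entity_axis(entity, A)
    profile = A.values[idx, :] if axis == 0 else A.values[:, idx]
    num_ass = float((profile == 1).sum())
    i = sim.ids.index(entity)
    others = np.delete(sim.values[i], i)
    me_sim = float(others.mean()) if others.size else 0.0
    edges = np.linspace(0.0, 1.0, cfg.hist_bins + 1)
    hist, _ = np.histogram(others, bins=edges)
    return np.concatenate(([num_ass, me_sim], hist.astype(float)))


def type2_features(
    entity: str,
    graph: EntityGraph,
    sim: SimilarityMatrix,
    cfg: FeatureConfig,
) -> np.ndarray:
    """[degree, top-k similarities (desc, zero-padded), betweenness, closeness]."""
    deg = float(graph.graph.degree(entity))
    i = sim.ids.index(entity)
    others = np.delete(sim.values[i], i)
    top = np.sort(others)[::-1][: cfg.k_sim]
    ksim = np.zeros(cfg.k_sim)
    ksim[: top.size] = top
    bt = graph.betweenness.get(entity, 0.0)
    cl = graph.closeness.get(entity, 0.0)
    return np.concatenate(([deg], ksim, [bt, cl]))


def bipartite_centralities(
    A: AssociationMatrix,
) -> tuple[dict[str, float], dict[str, float]]:
    """Normalized betweenness and closeness of every entity in the bipartite
    graph whose edges are the known associations (entries equal to 1)."""
    g = nx.Graph()
    g.add_nodes_from(("m", m) for m in A.mirna_ids)
    g.add_nodes_from(("d", d) for d in A.disease_ids)
    rows, cols = np.nonzero(A.values == 1)
    g.add_edges_from(
        (("m", A.mirna_ids[i]), ("d", A.disease_ids[j])) for i, j in zip(rows, cols)
    )
    bt = nx.betweenness_centrality(g, normalized=True)
    cl = nx.closeness_centrality(g, wf_improved=True)
    strip = lambda d: {k[1]: v for k, v in d.items()}
    return strip(bt), strip(cl)


def type3_features(
    pair: tuple[str, str],
    A: AssociationMatrix,
    mg: EntityGraph,
    dg: EntityGraph,
    bipartite: tuple[dict[str, float], dict[str, float]] | None = None,
) -> np.ndarray:
    """Pair-level descriptors crossing the similarity graphs and A.

    [count of the disease's similarity-graph neighbours associated with the
    miRNA, count of the miRNA's neighbours associated with the disease, then
    betweenness and closeness of the miRNA node and of the disease node in
    the bipartite association graph].
    """
    m, d = pair
    mi = A.mirna_ids.index(m)
    dj = A.disease_ids.index(d)
    d_neighbors = dg.neighbors(d)
    m_d_nb = float(
        sum(A.values[mi, A.disease_ids.index(x)] == 1 for x in d_neighbors)
    )
    m_neighbors = mg.neighbors(m)
    d_m_nb = float(
        sum(A.values[A.mirna_ids.index(x), dj] == 1 for x in m_neighbors)
    )
    if bipartite is None:
        bipartite = bipartite_centralities(A)
    bt, cl = bipartite
    return np.array([m_d_nb, d_m_nb, bt[m], cl[m], bt[d], cl[d]])


def _feature_names(cfg: FeatureConfig) -> list[str]:
    names: list[str] = []
    for side in ("m", "d"):
        names += [f"type1.{side}.num_ass", f"type1.{side}.me_sim"]
        names += [f"type1.{side}.dis_sim_{b}" for b in range(cfg.hist_bins)]
    for side in ("m", "d"):
        names += [f"type2.{side}.num_nb"]
        names += [f"type2.{side}.k_sim_{k}" for k in range(cfg.k_sim)]
        names += [f"type2.{side}.bt", f"type2.{side}.cl"]
    names += [
        "type3.m_d_nb",
        "type3.d_m_nb",
        "type3.m.bt",
        "type3.m.cl",
        "type3.d.bt",
        "type3.d.cl",
    ]
    return names


def block_columns(feature_names: Sequence[str], blocks: Iterable[str]) -> list[str]:
    """Feature names belonging to the given type blocks, in original order."""
    prefixes = tuple(f"{b}." for b in blocks)
    return [n for n in feature_names if n.startswith(prefixes)]


def assemble_pair_features(
    A: AssociationMatrix,
    MMS: SimilarityMatrix,
    DMS: SimilarityMatrix,
    cfg: FeatureConfig,
    pair_list: Sequence[tuple[str, str]],
    labels: Sequence[int] | None = None,
) -> PairFeatureTable:
    """Build the full feature table for an ordered pair list.

    ``labels`` marks positives (1) / negatives (0); when omitted, labels are
    taken from A itself.  Per-entity descriptors are computed once per entity
    and shared across pairs.
    """
    if not pair_list:
        raise ValueError("pair_list must be nonempty")
    mg = build_entity_graph(MMS)
    dg = build_entity_graph(DMS)
    bip = bipartite_centralities(A)

    t1: dict[str, np.ndarray] = {}
    t2: dict[str, np.ndarray] = {}
    for m in {p[0] for p in pair_list}:
        t1[m] = type1_features(m, A, MMS, cfg)
        t2[m] = type2_features(m, mg, MMS, cfg)
    for d in {p[1] for p in pair_list}:
        t1[d] = type1_features(d, A, DMS, cfg)
        t2[d] = type2_features(d, dg, DMS, cfg)

    rows = [
        np.concatenate(
            (t1[m], t1[d], t2[m], t2[d], type3_features((m, d), A, mg, dg, bip))
        )
        for m, d in pair_list
    ]
    X = np.vstack(rows)
    if labels is None:
        labels = [int(A.values[A.mirna_ids.index(m), A.disease_ids.index(d)] == 1)
                  for m, d in pair_list]
    lab = np.asarray(labels, dtype=int)
    Y = np.column_stack((lab, 1 - lab)).astype(float)
    return PairFeatureTable(X, Y, list(pair_list), _feature_names(cfg))


def sample_negatives(
    A: AssociationMatrix,
    n_pos: int,
    cfg: FeatureConfig,
) -> list[tuple[str, str]]:
    """Uniform sample (without replacement) of zero-entry pairs.

    Draws ceil(negative_ratio * n_pos) pairs, reproducibly from cfg.rng_seed.
    """
    n_neg = int(np.ceil(cfg.negative_ratio * n_pos))
    rows, cols = np.nonzero(A.values == 0)
    if len(rows) < n_neg:
        raise ValueError(
            f"only {len(rows)} zero-entry pairs available, {n_neg} requested"
        )
    rng = np.random.default_rng(cfg.rng_seed)
    take = rng.choice(len(rows), size=n_neg, replace=False)
    return [(A.mirna_ids[rows[k]], A.disease_ids[cols[k]]) for k in take]
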
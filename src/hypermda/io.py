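"""Domain containers and TSV readers/writers.

All on-disk artifacts are tab-separated UTF-8 text.  Matrix files carry the
row identifiers in the first column and the column identifiers in the header
row (first header cell empty); floats are written with 10 significant digits
so that write/read round-trips are bit-exact.  Matrices are stored dense:
the method operates at desk scale (hundreds to a few thousand entities).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "DiseaseDAG",
    "PairFeatureTable",
    "ScoreMatrix",
    "FormatError",
    "read_association_tsv",
    "write_association_tsv",
    "read_similarity_tsv",
    "write_similarity_tsv",
    "read_dag_edges",
    "write_dag_edges",
    "write_scores_tsv",
    "write_feature_tsv",
]

_FLOAT_FMT = "%.10g"

#: similarity matrix roles recognised throughout the package
SIMILARITY_ROLES = frozenset(
    {"SM", "SD", "SD1", "SD2", "GIM", "GID", "MMS", "DMS"}
)


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the format contract."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)
    return ids


@dataclass
class AssociationMatrix:
    """Binary (or unit-interval, after profile completion) miRNA x disease matrix.

    Rows are miRNA interaction profiles, columns are disease interaction
    profiles.  Raw input must be strictly 0/1; WKNNP completion produces
    values in [0, 1].
    """

    values: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("association matrix must be 2-dimensional")
        self.mirna_ids = _check_unique(self.mirna_ids, "miRNA")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        nm, nd = self.values.shape
        if nm != len(self.mirna_ids) or nd != len(self.disease_ids):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.mirna_ids)} miRNAs x {len(self.disease_ids)} diseases"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("association matrix contains non-finite entries")
        if self.values.min() < 0 or self.values.max() > 1:
            bad = np.argwhere((self.values < 0) | (self.values > 1))[0]
            raise FormatError(
                f"association entry out of [0,1] at row "
                f"{self.mirna_ids[bad[0]]!r}, column {self.disease_ids[bad[1]]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def is_binary(self) -> bool:
        return bool(np.all((self.values == 0) | (self.values == 1)))

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            self.values.copy(), list(self.mirna_ids), list(self.disease_ids)
        )

    def positive_pairs(self) -> list[tuple[str, str]]:
        """All (mirna_id, disease_id) pairs with entry exactly 1."""
        rows, cols = np.nonzero(self.values == 1)
        return [(self.mirna_ids[i], self.disease_ids[j]) for i, j in zip(rows, cols)]

    def index_of(self, pair: tuple[str, str]) -> tuple[int, int]:
        m, d = pair
        try:
            return self.mirna_ids.index(m), self.disease_ids.index(d)
        except ValueError as exc:
            raise KeyError(f"unknown pair {pair!r}") from exc


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with entries in [0, 1]."""

    values: np.ndarray
    ids: list[str]
    role: str = "SM"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = _check_unique(self.ids, "similarity")
        if self.role not in SIMILARITY_ROLES:
            raise FormatError(f"unknown similarity role {self.role!r}")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise FormatError(
                f"similarity matrix shape {self.values.shape} does not match "
                f"{n} identifiers"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("similarity matrix contains non-finite entries")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            bad = np.argwhere((self.values < 0) | (self.values > 1))[0]
            raise FormatError(
                f"similarity entry out of [0,1] at {self.ids[bad[0]]!r}, "
                f"{self.ids[bad[1]]!r}"
            )
        asym = float(np.abs(self.values - self.values.T).max()) if n else 0.0
        if asym > 1e-10:
            raise FormatError(f"similarity matrix asymmetric (max |M-M^T| = {asym:g})")
        # store an exactly symmetric matrix
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.ids)

    def reindex(self, ids: Sequence[str]) -> "SimilarityMatrix":
        """Reorder to the given identifier list, erroring on missing ids."""
        pos = {k: i for i, k in enumerate(self.ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise FormatError(f"identifiers missing from similarity matrix: {missing[:5]}")
        idx = np.array([pos[i] for i in ids])
        return SimilarityMatrix(self.values[np.ix_(idx, idx)], list(ids), self.role)


@dataclass
class DiseaseDAG:
    """A disease hierarchy given as parent->child edges.

    ``ancestors(d)`` returns T(d): the ancestor-closed term set containing d
    itself and everything reachable by repeatedly following child->parent.
    """

    nodes: list[str]
    edges: list[tuple[str, str]]
    _graph: nx.DiGraph = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = _check_unique(self.nodes, "DAG term")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for parent, child in self.edges:
            if parent not in g or child not in g:
                raise FormatError(f"edge ({parent!r}, {child!r}) references unknown term")
            g.add_edge(parent, child)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise FormatError(f"disease hierarchy contains a cycle through {cycle[0][0]!r}")
        self._graph = g

    def ancestors(self, term: str) -> frozenset[str]:
        """T(term): the term itself plus all its ancestors."""
        if term not in self._graph:
            raise KeyError(f"unknown term {term!r}")
        return frozenset(nx.ancestors(self._graph, term)) | {term}

    def children(self, term: str) -> list[str]:
        return sorted(self._graph.successors(term))

    def dag_of(self, diseases: Sequence[str] | None = None) -> dict[str, frozenset[str]]:
        """Map disease -> T(disease) for the given diseases (default: all nodes)."""
        if diseases is None:
            diseases = self.nodes
        return {d: self.ancestors(d) for d in diseases}


@dataclass
class PairFeatureTable:
    """Feature matrix X and one-hot labels Y for an ordered list of pairs.

    Y has two columns: column 0 flags a known (positive) association,
    column 1 an unknown/negative one; each row sums to 1.
    """

    X: np.ndarray
    Y: np.ndarray
    pairs: list[tuple[str, str]]
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        n = len(self.pairs)
        if self.X.shape[0] != n or self.Y.shape[0] != n:
            raise FormatError("X/Y row count does not match number of pairs")
        if self.X.shape[1] != len(self.feature_names):
            raise FormatError("feature_names length does not match X columns")
        if not np.all(np.isfinite(self.X)):
            i, j = np.argwhere(~np.isfinite(self.X))[0]
            raise FormatError(
                f"non-finite feature {self.feature_names[j]!r} for pair {self.pairs[i]!r}"
            )
        if self.Y.size and not np.allclose(self.Y.sum(axis=1), 1.0):
            raise FormatError("label rows must each sum to 1 (one-hot)")

    @property
    def n(self) -> int:
        return len(self.pairs)

    def labels(self) -> np.ndarray:
        """1 for positive pairs (column 0 hot), 0 otherwise."""
        return (self.Y[:, 0] > 0.5).astype(int)

    def select_columns(self, names: Sequence[str]) -> "PairFeatureTable":
        pos = {k: i for i, k in enumerate(self.feature_names)}
        idx = [pos[n] for n in names]
        return PairFeatureTable(self.X[:, idx], self.Y, list(self.pairs), list(names))


@dataclass
class ScoreMatrix:
    """Association scores for an ordered list of query pairs."""

    scores: np.ndarray
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        if self.scores.shape[0] != len(self.pairs):
            raise FormatError("one score per query pair required")
        if not np.all(np.isfinite(self.scores)):
            raise FormatError("scores contain non-finite values")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_matrix_frame(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse TSV {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_association_tsv(path) -> AssociationMatrix:
    """Read a binary association matrix (header = disease ids, index = miRNA ids)."""
    df = _read_matrix_frame(path)
    values = df.to_numpy(dtype=float)
    mask = (values != 0) & (values != 1)
    if mask.any():
        i, j = np.argwhere(mask)[0]
        raise FormatError(
            f"non-binary entry {values[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    return AssociationMatrix(values, list(df.index), list(df.columns))


def write_association_tsv(assoc: AssociationMatrix, path) -> None:
    df = pd.DataFrame(assoc.values, index=assoc.mirna_ids, columns=assoc.disease_ids)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_similarity_tsv(path, role: str = "SM") -> SimilarityMatrix:
    """Read a square similarity matrix; mild asymmetry (<= 1e-8) is symmetrized."""
    df = _read_matrix_frame(path)
    if list(df.index) != list(df.columns):
        raise FormatError("similarity matrix header and index identifiers differ")
    values = df.to_numpy(dtype=float)
    if values.size and (np.nanmin(values) < 0 or np.nanmax(values) > 1):
        raise FormatError("similarity entries must lie in [0,1]")
    asym = float(np.abs(values - values.T).max()) if values.size else 0.0
    if asym > 1e-8:
        raise FormatError(f"similarity matrix asymmetric beyond tolerance ({asym:g} > 1e-08)")
    values = (values + values.T) / 2.0
    return SimilarityMatrix(values, list(df.index), role)


def write_similarity_tsv(sim: SimilarityMatrix, path) -> None:
    df = pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_dag_edges(path) -> DiseaseDAG:
    """Read a two-column parent\\tchild edge list into a disease hierarchy."""
    df = pd.read_csv(path, sep="\t", header=None, names=["parent", "child"], dtype=str)
    if df.isna().any().any():
        raise FormatError("DAG edge list must have exactly two columns per row")
    edges = [(str(p), str(c)) for p, c in zip(df["parent"], df["child"])]
    nodes: list[str] = []
    seen: set[str] = set()
    for p, c in edges:
        for t in (p, c):
            if t not in seen:
                seen.add(t)
                nodes.append(t)
    return DiseaseDAG(nodes, edges)


def write_dag_edges(dag: DiseaseDAG, path) -> None:
    pd.DataFrame(dag.edges).to_csv(path, sep="\t", header=False, index=False)


def write_scores_tsv(scores: ScoreMatrix, path) -> None:
    df = pd.DataFrame(
        {
            "mirna": [m for m, _ in scores.pairs],
            "disease": [d for _, d in scores.pairs],
            "score": scores.scores,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_feature_tsv(table: PairFeatureTable, path) -> None:
    df = pd.DataFrame(table.X, columns=table.feature_names)
    df.insert(0, "mirna", [m for m, _ in table.pairs])
    df.insert(1, "disease", [d for _, d in table.pairs])
    df.insert(2, "label", table.labels())
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
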
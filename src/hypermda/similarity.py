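"""Disease semantic similarity, WKNNP profile completion, Gipk kernels, fusion.

Two semantic contribution models are supported.  Model 1 scores each term of
a disease's ancestor set T(d) by a corpus-frequency information content,
-log(#DAGs containing the term / #diseases); model 2 scores it by a
per-generation decay delta_sc applied along the child->parent recursion.
Disease similarity is the normalised contribution overlap of the two
ancestor sets.  The Gaussian interaction-profile kernel (Gipk) similarity of
two entities is exp(-gamma * ||profile_i - profile_j||^2) with gamma the
reciprocal mean squared profile norm.  Base and kernel similarities are
fused by taking the kernel value where the base similarity is exactly zero
and the average elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import AssociationMatrix, DiseaseDAG, SimilarityMatrix

__all__ = [
    "SemanticContribution",
    "GipkParams",
    "WknnpConfig",
    "d1_contribution",
    "d2_contribution",
    "semantic_similarity",
    "disease_semantic_matrices",
    "fuse_sd",
    "wknnp_complete",
    "gipk_bandwidth",
    "gipk_similarity",
    "fuse_multi_similarity",
    "build_multi_similarities",
]


@dataclass
class SemanticContribution:
    """Per-term semantic contributions of a single disease's ancestor set."""

    d1: dict[str, float] = field(default_factory=dict)
    d2: dict[str, float] = field(default_factory=dict)
    dv1: float = 0.0
    dv2: float = 0.0
    delta_sc: float = 0.5


@dataclass
class GipkParams:
    """Gaussian interaction-profile kernel bandwidth."""

    gamma: float

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError("kernel bandwidth gamma must be positive")


@dataclass
class WknnpConfig:
    """Weighted K-nearest-neighbour profile completion parameters.

    K neighbours are ranked by similarity (descending, self excluded, ties
    broken by ascending index) and weighted by decay**rank * similarity.
    """

    K: int = 20
    decay: float = 0.8

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (0 < self.decay <= 1):
            raise ValueError("decay must lie in (0, 1]")


# ---------------------------------------------------------------------------
# semantic similarity
# ---------------------------------------------------------------------------

def d1_contribution(term: str, corpus: Mapping[str, frozenset[str]]) -> float:
    """Frequency-based (model 1) contribution of a term across disease DAGs.

    ``corpus`` maps each disease to its ancestor-closed term set T(d);
    the contribution is -log(count of T(d) containing the term / #diseases),
    natural log.
    """
    if not corpus:
        raise ValueError("empty DAG corpus")
    count = sum(1 for terms in corpus.values() if term in terms)
    if count == 0:
        raise ValueError(f"term {term!r} occurs in no disease DAG")
    return float(-np.log(count / len(corpus)))


def d2_contribution(disease: str, dag: DiseaseDAG, delta_sc: float = 0.5) -> SemanticContribution:
    """Decay-based (model 2) contributions over T(disease).

    The disease's own term contributes 1; every other term t in T(disease)
    contributes max over its children t' within T(disease) of
    delta_sc * contribution(t').
    """
    if not (0 < delta_sc <= 1):
        raise ValueError("delta_sc must lie in (0, 1]")
    terms = dag.ancestors(disease)
    d2: dict[str, float] = {disease: 1.0}

    def contrib(t: str) -> float:
        if t in d2:
            return d2[t]
        vals = [delta_sc * contrib(c) for c in dag.children(t) if c in terms]
        d2[t] = max(vals) if vals else 0.0
        return d2[t]

    for t in terms:
        contrib(t)
    return SemanticContribution(
        d2=d2, dv2=float(sum(d2.values())), delta_sc=delta_sc
    )


def _contributions(
    disease: str,
    dag: DiseaseDAG,
    corpus: Mapping[str, frozenset[str]],
    model: int,
    delta_sc: float,
) -> tuple[dict[str, float], float]:
    if model == 1:
        terms = dag.ancestors(disease)
        d1 = {t: d1_contribution(t, corpus) for t in terms}
        return d1, float(sum(d1.values()))
    if model == 2:
        sc = d2_contribution(disease, dag, delta_sc)
        return sc.d2, sc.dv2
    raise ValueError(f"model must be 1 or 2, got {model}")


def semantic_similarity(
    di: str,
    dj: str,
    dag: DiseaseDAG,
    corpus: Mapping[str, frozenset[str]],
    model: int = 1,
    delta_sc: float = 0.5,
) -> float:
    """Similarity of two diseases as normalised shared-ancestor contribution.

    sum over t in T(di) & T(dj) of (D_di(t) + D_dj(t)), divided by
    DV(di) + DV(dj), under the chosen contribution model.
    """
    ci, dvi = _contributions(di, dag, corpus, model, delta_sc)
    cj, dvj = _contributions(dj, dag, corpus, model, delta_sc)
    denom = dvi + dvj
    if denom == 0:
        warnings.warn(f"zero semantic value for both {di!r} and {dj!r}; similarity set to 0")
        return 0.0
    shared = set(ci) & set(cj)
    return float(sum(ci[t] + cj[t] for t in shared) / denom)


def disease_semantic_matrices(
    dag: DiseaseDAG,
    diseases: Sequence[str],
    delta_sc: float = 0.5,
) -> tuple[SimilarityMatrix, SimilarityMatrix, SimilarityMatrix]:
    """SD1, SD2 and their average SD over an ordered disease list."""
    corpus = dag.dag_of(diseases)
    n = len(diseases)
    contribs = {
        m: [
            _contributions(d, dag, corpus, m, delta_sc) for d in diseases
        ]
        for m in (1, 2)
    }
    mats = []
    for m in (1, 2):
        vals = np.zeros((n, n))
        for i in range(n):
            ci, dvi = contribs[m][i]
            for j in range(i, n):
                cj, dvj = contribs[m][j]
                denom = dvi + dvj
                if denom == 0:
                    s = 0.0
                else:
                    shared = set(ci) & set(cj)
                    s = sum(ci[t] + cj[t] for t in shared) / denom
                vals[i, j] = vals[j, i] = s
        mats.append(SimilarityMatrix(np.clip(vals, 0.0, 1.0), list(diseases), f"SD{m}"))
    sd1, sd2 = mats
    return sd1, sd2, fuse_sd(sd1, sd2)


def fuse_sd(sd1: SimilarityMatrix, sd2: SimilarityMatrix) -> SimilarityMatrix:
    """Average the two semantic-model similarity matrices elementwise."""
    if sd1.ids != sd2.ids:
        raise ValueError("SD1 and SD2 identifier lists differ")
    return SimilarityMatrix((sd1.values + sd2.values) / 2.0, list(sd1.ids), "SD")


# ---------------------------------------------------------------------------
# WKNNP completion
# ---------------------------------------------------------------------------

def _wknnp_estimate(A: np.ndarray, S: np.ndarray, cfg: WknnpConfig) -> np.ndarray:
    """Row-side neighbour estimate: weighted average of the K most similar rows."""
    n = A.shape[0]
    K = cfg.K
    if K >= n:
        warnings.warn(f"WKNNP K={K} >= {n} entities; truncated to {n - 1}")
        K = max(n - 1, 1)
    est = np.zeros_like(A, dtype=float)
    for i in range(n):
        sims = S[i].copy()
        sims[i] = -np.inf  # exclude self
        # descending similarity, ties broken by ascending index
        order = np.lexsort((np.arange(n), -sims))[:K]
        w = cfg.decay ** np.arange(len(order)) * S[i, order]
        denom = w.sum()
        if denom > 0:
            est[i] = w @ A[order] / denom
    return est


def wknnp_complete(
    A: AssociationMatrix,
    SM: SimilarityMatrix,
    SD: SimilarityMatrix,
    cfg: WknnpConfig | None = None,
) -> AssociationMatrix:
    """Complete the association matrix from similar neighbours' profiles.

    Row estimates use the miRNA similarity, column estimates the disease
    similarity; the output is max(A, (row + col)/2) clipped to [0,1], so known
    associations are preserved and entries never decrease.
    """
    cfg = cfg or WknnpConfig()
    if SM.ids != A.mirna_ids or SD.ids != A.disease_ids:
        raise ValueError("similarity identifiers do not match the association matrix")
    row_est = _wknnp_estimate(A.values, SM.values, cfg)
    col_est = _wknnp_estimate(A.values.T, SD.values, cfg).T
    out = np.maximum(A.values, (row_est + col_est) / 2.0)
    return AssociationMatrix(np.clip(out, 0.0, 1.0), list(A.mirna_ids), list(A.disease_ids))


# ---------------------------------------------------------------------------
# Gipk
# ---------------------------------------------------------------------------

def gipk_bandwidth(profiles: np.ndarray) -> GipkParams:
    """Bandwidth gamma = 1 / mean squared profile norm."""
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 1:
        raise ValueError("need at least one profile")
    mean_sq = float((profiles ** 2).sum(axis=1).mean())
    if mean_sq == 0:
        raise ValueError("all interaction profiles are zero; bandwidth undefined")
    return GipkParams(gamma=1.0 / mean_sq)


def gipk_similarity(
    profiles: np.ndarray, ids: Sequence[str], role: str = "GIM"
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over profile rows."""
    profiles = np.asarray(profiles, dtype=float)
    gamma = gipk_bandwidth(profiles).gamma
    sq = (profiles ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(d2, 0.0, out=d2)
    vals = np.exp(-gamma * d2)
    np.fill_diagonal(vals, 1.0)
    return SimilarityMatrix(np.clip((vals + vals.T) / 2.0, 0.0, 1.0), list(ids), role)


def fuse_multi_similarity(
    base: SimilarityMatrix, gipk: SimilarityMatrix, role: str | None = None
) -> SimilarityMatrix:
    """Kernel value where the base similarity is zero, average elsewhere."""
    if base.ids != gipk.ids:
        raise ValueError("base and kernel similarity identifiers differ")
    fused = np.where(base.values == 0, gipk.values, (base.values + gipk.values) / 2.0)
    if role is None:
        role = "MMS" if base.role in ("SM", "MMS") else "DMS"
    return SimilarityMatrix(fused, list(base.ids), role)


def build_multi_similarities(
    A: AssociationMatrix,
    SM: SimilarityMatrix,
    SD: SimilarityMatrix,
    wknnp: WknnpConfig | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix, AssociationMatrix]:
    """Full preprocessing chain: WKNNP -> Gipk -> fusion.

    Returns (MMS, DMS, completed A).  The kernel is computed on the
    WKNNP-completed matrix; fusion keeps the base similarity where available.
    """
    A_c = wknnp_complete(A, SM, SD, wknnp)
    gim = gipk_similarity(A_c.values, A.mirna_ids, "GIM")
    gid = gipk_similarity(A_c.values.T, A.disease_ids, "GID")
    mms = fuse_multi_similarity(SM, gim, "MMS")
    dms = fuse_multi_similarity(SD, gid, "DMS")
    return mms, dms, A_c
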
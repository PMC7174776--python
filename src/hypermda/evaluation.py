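"""Cross-validation drivers: LOOCV, repeated k-fold, and feature ablation.

The protocols are strict by default: for every fold the left-out known
associations are zeroed in the association matrix *before* WKNNP completion,
kernel similarity, fusion, feature construction and standardisation, so no
test information reaches the trained model.  A ``fast`` mode computes the
similarity matrices once on the full matrix (accepting mild leakage) for
exploratory runs on large inputs.

The ranking quality measure is the rank (Mann-Whitney) AUC: the probability
that a random known association outscores a random candidate (unknown)
pair, with half-credit for ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import chl
from .chl import CHLConfig
from .features import (
    FEATURE_BLOCKS,
    FeatureConfig,
    assemble_pair_features,
    block_columns,
    sample_negatives,
)
from .hypergraph import HypergraphConfig, build_kmeans_hypergraph, build_knn_hypergraph
from .io import AssociationMatrix, DiseaseDAG, PairFeatureTable, SimilarityMatrix
from .similarity import WknnpConfig, build_multi_similarities, disease_semantic_matrices

__all__ = [
    "PipelineConfig",
    "CVResult",
    "auc_rank",
    "prepare_fold",
    "train_and_score",
    "loocv",
    "kfold_cv",
    "feature_ablation",
]

#: optional replacement for the trained scorer in CV drivers; receives the
#: train and query tables and must return one score per query pair.
ScoreFn = Callable[[PairFeatureTable, PairFeatureTable], np.ndarray]


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end pipeline, with method defaults."""

    delta_sc: float = 0.5
    wknnp: WknnpConfig = field(default_factory=WknnpConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    hypergraph: HypergraphConfig = field(default_factory=HypergraphConfig)
    chl: CHLConfig = field(default_factory=CHLConfig)
    feature_blocks: tuple[str, ...] = FEATURE_BLOCKS
    strict: bool = True
    rng_seed: int = 0


@dataclass
class CVResult:
    auc_values: list[float]
    mean_auc: float
    sd_auc: float
    fold_assignments: dict[tuple[str, str], int]
    protocol: str
    repeats: int

    def __post_init__(self) -> None:
        if any(not (0.0 <= a <= 1.0) for a in self.auc_values):
            raise ValueError("AUC values must lie in [0, 1]")
        vals = np.asarray(self.auc_values, float)
        if abs(self.mean_auc - vals.mean()) > 1e-12 or abs(
            self.sd_auc - vals.std()
        ) > 1e-12:
            raise ValueError("mean/sd inconsistent with auc_values")

    @classmethod
    def from_values(
        cls,
        auc_values: Sequence[float],
        fold_assignments: dict[tuple[str, str], int],
        protocol: str,
        repeats: int,
    ) -> "CVResult":
        vals = np.asarray(auc_values, float)
        return cls(
            list(map(float, vals)),
            float(vals.mean()),
            float(vals.std()),
            fold_assignments,
            protocol,
            repeats,
        )


def auc_rank(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Mann-Whitney AUC with half-credit for ties."""
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be nonempty")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def _clamped_hypergraph_cfg(cfg: HypergraphConfig, n: int) -> HypergraphConfig:
    """Shrink k1/k2 when a training fold is smaller than the defaults."""
    k1 = min(cfg.k1, n - 1)
    k2 = min(cfg.k2, n)
    if (k1, k2) != (cfg.k1, cfg.k2):
        warnings.warn(f"hypergraph parameters clamped to k1={k1}, k2={k2} for n={n}")
        return replace(cfg, k1=k1, k2=k2)
    return cfg


def _mask(A: AssociationMatrix, pairs: Sequence[tuple[str, str]]) -> AssociationMatrix:
    masked = A.copy()
    for p in pairs:
        i, j = A.index_of(p)
        masked.values[i, j] = 0.0
    return masked


def prepare_fold(
    A_full: AssociationMatrix,
    SM: SimilarityMatrix,
    dag: DiseaseDAG,
    test_pairs: Sequence[tuple[str, str]],
    cfg: PipelineConfig,
    fold_seed: int = 0,
) -> tuple[PairFeatureTable, PairFeatureTable]:
    """Mask the test pairs and rebuild the whole feature pipeline from scratch.

    Returns (train table, query table): the train table holds the remaining
    positives plus negatives sampled from the *masked* matrix's zeros; the
    query table holds the test pairs followed by every candidate (unknown in
    A_full) pair, labelled by A_full for evaluation only.
    """
    A_masked = _mask(A_full, test_pairs) if cfg.strict else A_full.copy()
    for p in test_pairs:
        i, j = A_masked.index_of(p)
        assert A_masked.values[i, j] == 0.0 or not cfg.strict
    A_features = A_masked if cfg.strict else _mask(A_full, test_pairs)

    _, _, SD = disease_semantic_matrices(dag, A_full.disease_ids, cfg.delta_sc)
    MMS, DMS, _ = build_multi_similarities(A_masked, SM, SD, cfg.wknnp)

    train_pos = A_features.positive_pairs()
    fcfg = replace(cfg.features, rng_seed=fold_seed)
    train_neg = sample_negatives(A_features, len(train_pos), fcfg)
    train_pairs = train_pos + train_neg
    train_labels = [1] * len(train_pos) + [0] * len(train_neg)
    train = assemble_pair_features(A_features, MMS, DMS, fcfg, train_pairs, train_labels)

    test_set = set(test_pairs)
    candidates = [
        (m, d)
        for i, m in enumerate(A_full.mirna_ids)
        for j, d in enumerate(A_full.disease_ids)
        if A_full.values[i, j] == 0
    ]
    query_pairs = list(test_pairs) + candidates
    query_labels = [1] * len(test_pairs) + [0] * len(candidates)
    query = assemble_pair_features(A_features, MMS, DMS, fcfg, query_pairs, query_labels)

    if cfg.feature_blocks != FEATURE_BLOCKS:
        cols = block_columns(train.feature_names, cfg.feature_blocks)
        train = train.select_columns(cols)
        query = query.select_columns(cols)
    return train, query


def train_and_score(
    train: PairFeatureTable, query: PairFeatureTable, cfg: PipelineConfig
) -> np.ndarray:
    """Fit the two-view hypergraph model on the train table, score the query."""
    stats = chl.FeatureStats.from_training(train.X)
    Xs = stats.transform(train.X)
    hcfg = _clamped_hypergraph_cfg(cfg.hypergraph, train.n)
    hg1 = build_knn_hypergraph(Xs, hcfg)
    hg2 = build_kmeans_hypergraph(Xs, hcfg)
    model = chl.fit(Xs, train.Y, [hg1, hg2], cfg.chl, feature_stats=stats)
    return chl.score(model, query.X)


def _fold_seed(base: int, *path: int) -> int:
    return int(np.random.SeedSequence([base, *path]).generate_state(1)[0] % (2**31))


def loocv(
    A: AssociationMatrix,
    SM: SimilarityMatrix,
    dag: DiseaseDAG,
    cfg: PipelineConfig | None = None,
    score_fn: ScoreFn | None = None,
) -> CVResult:
    """Leave-one-out over known associations.

    Each positive is masked and the retrained model ranks it against all
    candidate pairs; the per-positive AUCs (test vs candidates) are averaged
    into the global AUC.
    """
    cfg = cfg or PipelineConfig()
    positives = A.positive_pairs()
    if len(positives) < 2:
        raise ValueError("LOOCV needs at least two known associations")
    score_fn = score_fn or (lambda tr, qu: train_and_score(tr, qu, cfg))
    aucs = []
    assignments: dict[tuple[str, str], int] = {}
    for k, pair in enumerate(positives):
        train, query = prepare_fold(A, SM, dag, [pair], cfg, _fold_seed(cfg.rng_seed, k))
        scores = np.asarray(score_fn(train, query), float)
        aucs.append(auc_rank(scores[:1], scores[1:]))
        assignments[pair] = k
    return CVResult.from_values(aucs, assignments, "loocv", repeats=1)


def kfold_cv(
    A: AssociationMatrix,
    SM: SimilarityMatrix,
    dag: DiseaseDAG,
    cfg: PipelineConfig | None = None,
    k: int = 5,
    repeats: int = 1,
    seed: int | None = None,
    score_fn: ScoreFn | None = None,
) -> CVResult:
    """Repeated k-fold CV over known associations, pooled AUC per repeat.

    Positives are partitioned into k folds per repeat; each fold is masked,
    the pipeline retrained, and the fold's test pairs scored against all
    candidate pairs.  Test and candidate scores are pooled across the k
    folds into one AUC per repeat; the mean and standard deviation are taken
    over repeats.
    """
    cfg = cfg or PipelineConfig()
    if k < 2:
        raise ValueError("k must be >= 2")
    seed = cfg.rng_seed if seed is None else seed
    positives = A.positive_pairs()
    if len(positives) < k:
        raise ValueError(f"fewer positives ({len(positives)}) than folds ({k})")
    score_fn = score_fn or (lambda tr, qu: train_and_score(tr, qu, cfg))
    aucs = []
    assignments: dict[tuple[str, str], int] = {}
    for r in range(repeats):
        rng = np.random.default_rng(_fold_seed(seed, r))
        order = rng.permutation(len(positives))
        folds = np.array_split(order, k)
        pos_scores: list[float] = []
        neg_scores: list[float] = []
        for f, fold_idx in enumerate(folds):
            test_pairs = [positives[i] for i in fold_idx]
            if r == 0:
                assignments.update({p: f for p in test_pairs})
            train, query = prepare_fold(
                A, SM, dag, test_pairs, cfg, _fold_seed(seed, r, f)
            )
            scores = np.asarray(score_fn(train, query), float)
            n_test = len(test_pairs)
            pos_scores.extend(scores[:n_test])
            neg_scores.extend(scores[n_test:])
        aucs.append(auc_rank(pos_scores, neg_scores))
    return CVResult.from_values(aucs, assignments, "kfold", repeats=repeats)


def feature_ablation(
    A: AssociationMatrix,
    SM: SimilarityMatrix,
    dag: DiseaseDAG,
    cfg: PipelineConfig | None = None,
    k: int = 5,
    repeats: int = 1,
) -> dict[tuple[str, ...], float]:
    """Mean k-fold AUC for each of the 7 non-empty feature-type subsets."""
    cfg = cfg or PipelineConfig()
    out: dict[tuple[str, ...], float] = {}
    subsets = [
        ("type1",), ("type2",), ("type3",),
        ("type1", "type2"), ("type1", "type3"), ("type2", "type3"),
        ("type1", "type2", "type3"),
    ]
    for blocks in subsets:
        sub_cfg = replace(cfg, feature_blocks=blocks)
        res = kfold_cv(A, SM, dag, sub_cfg, k=k, repeats=repeats)
        out[blocks] = res.mean_auc
    return out
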
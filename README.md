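# hypermda

Multi-similarity combinative hypergraph learning for miRNA–disease
association prediction.

Experimentally confirming which microRNAs are involved in which diseases is
slow and expensive, so computational ranking of candidate miRNA–disease
pairs is used to prioritise laboratory validation. `hypermda` implements a
full pipeline for this link-prediction problem, for bioinformaticians who
have (a) a binary miRNA×disease association matrix *A*, (b) a miRNA
functional-similarity matrix, and (c) a disease hierarchy (MeSH-like
parent→child edges) — or who want to study the method itself on the
package's synthetic benchmark with planted structure.

## Method

1. **Similarities.** Disease semantic similarity from each disease's
   ancestor subgraph T(d) under two contribution models (frequency-based
   D1(t) = −ln(#DAGs containing t / #diseases), and decay-based with
   per-generation factor Δ = 0.5), averaged into SD. Zeros of *A* are
   softened by weighted-K-nearest-neighbour profile completion (WKNNP),
   then the Gaussian interaction-profile kernel
   GIK(i, j) = exp(−γ‖KS(i) − KS(j)‖²), with γ the reciprocal mean squared
   profile norm, is fused with the base similarities into
   multi-similarity matrices MMS (miRNAs) and DMS (diseases): kernel value
   where the base is 0, average elsewhere.
2. **Features.** Each pair gets a 66-dimensional vector: per-entity
   statistics (association count, mean similarity, similarity histogram),
   per-entity graph descriptors on the similarity-threshold graphs
   (degree, top-k similarities, betweenness, closeness), and pair-level
   descriptors crossing the graphs and the bipartite association graph.
3. **Hypergraphs.** Two views over the training pairs: a KNN hypergraph
   (each vertex plus its k₁ nearest neighbours, Gaussian-affinity
   weights) and a K-means hypergraph (one hyperedge per cluster, equal
   weights), each summarised by the normalised hypergraph Laplacian
   Δ = I − Dv^{−1/2} H W De^{−1} Hᵀ Dv^{−1/2}.
4. **Learning.** Per view, the closed-form Laplacian-regularised ridge
   projection P_i = λ(XᵀΔ_iX + λXᵀX + μI)^{−1}XᵀY; then combination
   weights B = [β₁, β₂] on the probability simplex from the Lagrange
   stationarity formula β_i = ½ + ΣΘ/(4η) − Θ_i/(2η) (simplex-projected
   when clamped). Pairs are scored S(x) = Σ_i β_i·x·P_i.
5. **Evaluation.** Strict LOOCV and repeated k-fold CV: held-out
   associations are zeroed *before* WKNNP/kernel/feature recomputation in
   every fold, and ranking quality is the Mann–Whitney AUC of held-out
   positives against all unknown candidate pairs.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from hypermda import SynthConfig, simulate_dataset
from hypermda.evaluation import PipelineConfig, kfold_cv

A, SM, dag = simulate_dataset(
    SynthConfig(nm=60, nd=40, rank=3, density=0.08, noise=0.02, rng_seed=0)
)
print(f"{A.shape[0]} miRNAs x {A.shape[1]} diseases, "
      f"{int(A.values.sum())} known associations")
res = kfold_cv(A, SM, dag, PipelineConfig(rng_seed=0), k=5, repeats=3, seed=0)
print(f"5-fold CV AUC: {res.mean_auc:.4f} +/- {res.sd_auc:.4f} "
      f"over {res.repeats} repeats")
```

prints

```
60 miRNAs x 40 diseases, 196 known associations
5-fold CV AUC: 0.9737 +/- 0.0013 over 3 repeats
```

The benchmark plants rank-3 latent structure: miRNAs and diseases sharing
a latent factor associate, the miRNA similarity is the cosine of the miRNA
loadings, and the disease hierarchy groups diseases by dominant factor.
An AUC of 0.97 means the pipeline ranks a randomly chosen held-out true
association above a randomly chosen unknown pair 97% of the time — far
above the 0.5 chance level — i.e. it recovers the planted structure from
the masked training data alone.

The same pipeline is available from the shell:

```sh
hypermda simulate --nm 60 --nd 40 --seed 0 --out-dir data/
hypermda cv --assoc data/associations.tsv \
            --mirna-sim data/mirna_similarity.tsv \
            --dag data/disease_dag.tsv --cv-k 5 --seed 0
```

Other subcommands: `similarity`, `featurize`, `hypergraph`, `train`,
`predict`, `ablation` (see `hypermda --help`).

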
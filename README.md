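# ldaeagcn

Prediction of lncRNA–disease associations with an edge-attention graph
convolutional network over closest-node-weight pair subgraphs.

Only a small fraction of lncRNA–disease associations has been confirmed
experimentally, and assays are expensive, so computational ranking of
candidate pairs is a standard tool for prioritising wet-lab work.  This
package implements a complete link-prediction pipeline for curated
association catalogues: it integrates a hierarchical disease vocabulary, a
binary association table and the similarity structure derived from both
into per-pair graphs, and trains a graph convolutional classifier that
scores each candidate (lncRNA, disease) pair in [0, 1].

## Method

Given `nl` lncRNAs and `nd` diseases, the pipeline computes:

1. **LDCM** — the binary `nl × nd` correlation matrix, `LDCM(i, j) = 1` iff
   lncRNA `i` is known to associate with disease `j`.
2. **DDSCM** — disease semantic similarity from the vocabulary DAG.  Each
   disease `d` induces its ancestor set `T_d`; the contribution of term `t`
   decays by a factor Δ (default 0.5) per parent→child hop,
   `D_d(d) = 1`, `D_d(t) = max{Δ · D_d(t′) : t′ ∈ children(t) ∩ T_d}`,
   with semantic value `DV(d) = Σ_t D_d(t)` and similarity
   `DS(A, B) = Σ_{t ∈ T_A ∩ T_B} (D_A(t) + D_B(t)) / (DV(A) + DV(B))`.
3. **LLCM** — lncRNA functional similarity from the associated disease sets
   `DT_m`, `DT_n`:
   `SCORE(L_m, L_n) = [Σ_{d ∈ DT_m} max_{d′ ∈ DT_n} DS(d, d′) +
   Σ_{d ∈ DT_n} max_{d′ ∈ DT_m} DS(d, d′)] / (|DT_m| + |DT_n|)`.
4. **Negatives** — a random walk with restart on the heterogeneous network
   (LLCM + DDSCM + LDCM, jump probability λ = 0.5, restart r = 0.7) scores
   every pair; unknown pairs in the low-score tail are sampled as training
   negatives, one per known positive.
5. **Pair graphs (CNWGSN)** — for each candidate pair, a fixed-size graph of
   the query lncRNA plus its N−1 nearest functional neighbours and the query
   disease plus its M−1 nearest semantic neighbours (N = M = 10), with four
   typed edge tensors: the query edge (`core`), known cross associations
   (`nomal`, query edge masked to prevent label leakage), lncRNA-block
   similarities (`ll`) and disease-block similarities (`dd`).
6. **Classifier** — four graph-convolution layers, each running one
   attention block per edge category (edge logit `a·w + b`, row-softmax over
   existing edges, output `ReLU((A + I) H W)`, blocks concatenated),
   followed by three fully connected layers (dropout 0.3) and a sigmoid.
   Training is SGD (lr 0.01, momentum 0.9) on binary cross-entropy.

The evaluation harness provides stratified 10-fold and 5-fold
cross-validation with per-fold and mean rows (ACC/SEN/SPEC/PREC/MCC/AUC/
AUPR), an independent train/test/validation split, edge-category ablation,
walk-vs-uniform negative comparison, and per-disease top-k candidate
ranking.  A synthetic generator produces desk-scale inputs with planted
cluster structure so the whole pipeline is testable without downloads.

See `docs/methods.md` for assumptions, parameter choices and limitations.

## Worked example

Generate a synthetic benchmark, compute similarities, sample negatives and
cross-validate, all from the shell:

```sh
ldaeagcn simulate --seed 5 --out fix/
# wrote fixture with 232 training associations to fix
ldaeagcn similarity --assoc fix/associations.tsv --dag fix/disease_dag.tsv \
    --out-dd dd.tsv --out-ll ll.tsv
# wrote 40x40 disease and 60x60 lncRNA similarity matrices
ldaeagcn negatives --assoc fix/associations.tsv --dd dd.tsv --ll ll.tsv \
    --seed 17 --out negs.tsv
# wrote 232 negatives to negs.tsv
ldaeagcn cv --assoc fix/associations.tsv --dag fix/disease_dag.tsv \
    --folds 10 --epochs 60 --seed 2 --report cv.json
```

or from Python:

```python
import ldaeagcn as L

bench = L.make_benchmark(L.SimulationConfig(seed=1))
dataset = L.assemble_dataset(bench.table, bench.dag, seed=1)
report = L.cross_validate(dataset, L.ModelConfig(epochs=60, seed=1), k=10, seed=1)
print(round(report["mean"]["auc"], 4))   # 0.9806
print(round(report["mean"]["acc"], 4))   # 0.9610
```

The mean row averages the ten per-fold metric rows: an AUC of 0.9806 means
that across held-out folds a random known association outranks a random
sampled negative ~98% of the time on this benchmark.  A label-permuted
control run of the same pipeline scores AUC ≈ 0.48 (chance), confirming the
signal comes from the planted structure rather than the harness.

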
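# speechnet

Network analysis of spontaneous-speech markers for psychiatric research.

Quantitative speech markers — lexical diversity, syntactic complexity,
disfluency, semantic coherence — covary with each other and with
psychopathological and cognitive measures. `speechnet` treats these variables
as nodes in a **Gaussian graphical model**: an edge between two variables is
their partial correlation after conditioning on every other variable in the
system, so the resulting graph separates direct associations from those
merely mediated by third variables. The package covers the full chain from
dependency-parsed transcripts to compared group networks:

1. **Ingestion** — CoNLL-U parsed transcripts and per-sentence embedding
   vectors (`speechnet.transcripts`).
2. **Feature extraction** — 18 linguistic features across lexical, syntactic,
   fluency and coherence families (`speechnet.features`).
3. **Network estimation** — graphical lasso with EBIC model selection
   ("EBICglasso", hyperparameter γ = 0.5) on z-standardised features
   (`speechnet.ggm`). The estimated edge weight between variables *i* and
   *j* is the regularised partial correlation
   ρ̂ᵢⱼ = −θ̂ᵢⱼ / √(θ̂ᵢᵢ θ̂ⱼⱼ) from the estimated precision matrix Θ̂.
4. **Stability** — subject-level bootstrap confidence intervals for every
   edge, and pruning of edges whose interval covers zero
   (`speechnet.stability`).
5. **Centrality and structure** — betweenness, closeness, strength and
   expected influence on edge lengths 1/|w|; within- vs cross-domain edge
   classification (`speechnet.metrics`).
6. **Group comparison** — a permutation Network Comparison Test with
   maximum edge-difference (M) and global-strength-difference (S)
   statistics, Bonferroni-adjusted edgewise tests, and Frobenius network
   distance (`speechnet.comparison`); classical group statistics
   (ANOVA/η², Kruskal–Wallis, Cramér's V) in `speechnet.groupstats`.
7. **Synthetic data with planted truth** — chain/hub/random GGMs with known
   partial correlations, two-group designs with a planted edge
   perturbation, and full synthetic transcript corpora with known
   disfluency rates and coherence (`speechnet.synthetic`).
8. **Pipeline & CLI** — a one-command orchestration that estimates
   per-group networks, bootstraps, prunes, computes centralities and runs
   all group contrasts (`speechnet.pipeline`, `speechnet` CLI).

See [docs/methods.md](docs/methods.md) for the statistical model, estimator
details, defaults and their rationale, and known limitations.

## Worked example

Generate a small synthetic transcript corpus, extract features, and estimate
a study-scale network:

```sh
$ speechnet synth --preset transcripts --seed 7 --n-subjects 4 --out-dir corpus
wrote 4 transcripts to corpus

$ speechnet extract --conllu-dir corpus --embeddings corpus/embeddings.tsv --out features.csv
wrote 4 x 18 features to features.csv

$ speechnet synth --preset study-shape --seed 11 --out-dir study
wrote 372 subjects x 44 variables

$ speechnet estimate --features study/features.csv --out network.json
selected lambda 0.06988; 288 nonzero edges
```

The `study-shape` preset emulates a realistic multi-group study: 372
subjects (178 controls and three patient groups of 119, 27 and 48) measured
on 44 variables across linguistic (28), psychopathological (10) and
cognitive (6) domains, with a known planted precision matrix written to
`truth.json`.

The same stages are available from Python. Here the chain structure and its
approximate planted partial correlations (0.35) are recovered from data:

```python
>>> import numpy as np
>>> from speechnet import (planted_precision, sample_mvn_from_precision,
...                        ebicglasso_select, node_centralities)
>>> Theta, edges = planted_precision(6, "chain", 0.35)
>>> X = sample_mvn_from_precision(Theta, 1500, seed=0)
>>> net = ebicglasso_select(np.corrcoef(X, rowvar=False), n=1500, gamma=0.5)
>>> for a, b, w in net.edge_list(): print(a, b, round(w, 3))
v0 v1 0.295
v0 v2 0.008
v1 v2 0.356
v2 v3 0.306
v3 v4 0.353
v3 v5 0.027
v4 v5 0.303
>>> node_centralities(net).round(3)
      betweenness  closeness  strength  expected_influence
node
v0            0.0      0.021     0.304               0.304
v1            4.0      0.030     0.651               0.651
v2            6.0      0.036     0.670               0.670
v3            6.0      0.036     0.686               0.686
v4            4.0      0.030     0.657               0.657
v5            0.0      0.021     0.330               0.330
```

The full multi-group pipeline (per-group networks, bootstrap pruning,
centralities, all pairwise Network Comparison Tests, a Markdown summary and
a JSON manifest) runs from a config file:

```sh
speechnet run --config run.yaml
```

with `run.yaml` such as:

```yaml
features_csv: study/features.csv
out_dir: report
gamma: 0.5
bootstrap_B: 1000
nperm: 1000
seed: 42
```

## Layout

```
src/speechnet/        package source
  transcripts.py      CoNLL-U + embedding ingestion
  features.py         linguistic feature extraction
  _glasso.py          numba graphical-lasso kernels
  ggm.py              correlation, EBICglasso, NetworkModel
  stability.py        bootstrap CIs, pruning, sparsity
  metrics.py          centralities, edge classification
  comparison.py       permutation NCT, Frobenius distance
  groupstats.py       ANOVA, Kruskal–Wallis, Cramér's V
  synthetic.py        planted-truth generators
  pipeline.py, cli.py orchestration and CLI
tests/                pytest suite (unit, property, acceptance)
scripts/acceptance.py seeded verification report
docs/methods.md       statistical methods and design decisions
```
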
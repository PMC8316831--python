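# synnet

Syntactic dependency network analysis for learner-corpus studies.

`synnet` turns dependency-annotated corpora into undirected word-type
networks and runs a full analysis pipeline on them:

* **treebank I/O** — a 7-column tabular annotation dialect and standard
  CoNLL-U in; Pajek `.net` out (plain or gzip-compressed paths).
* **network construction** — word types as vertices, dependency pairs as
  merged undirected edges with multiplicities; root rows and self-pairs
  carry no edge; punctuation is dropped by default.
* **metric panel** — average degree ⟨k⟩, clustering coefficient C,
  average path length L (reachable-pairs default, all-pairs and
  largest-component variants), network density ND, and degree
  centralization NC (exact and approximate forms).
* **degree-distribution fits** — inclusive cumulative distribution
  P(K ≥ k); γ′ and R² from the log–log OLS on the cumulative; discrete
  maximum-likelihood power-law and Poisson fits compared by AIC.
* **random baselines** — seeded uniform G(N, M) ensembles matched on
  vertex/edge counts, with a threshold small-world verdict
  (C ≥ τ_C·C_rand and L ≤ τ_L·L_rand).
* **group statistics** — per-modality proficiency-trend OLS regressions
  (level codes 1–4 plus native = 5) and cross-modality pooled/Welch
  t-tests on learner levels, plus Pearson correlations.
* **synthetic treebanks** — Zipfian lexica, hub-biased random recursive
  dependency trees and a ten-corpus level plan, so the whole pipeline is
  testable without restricted corpora.

## CLI

Stages compose through files:

```sh
synnet simulate --out demo --seed 7 --tokens 5000    # 10 corpora + study.json
synnet build    --input demo/W1.tsv --out demo/W1.net --log demo/W1.log.json
synnet metrics  --network demo/W1.net --label W1 --out demo/W1.metrics.json
synnet fitdist  --network demo/W1.net --points demo/W1.cum.tsv
synnet baseline --network demo/W1.net --reps 30 --seed 0
synnet battery  --metrics demo/study_out/metrics.tsv
synnet run      --config demo/study.json             # everything at once
```

`synnet run` writes `metrics.tsv`/`metrics.json` (the parameter panel),
`fits.json`, `baselines.json`, `battery.json`, per-corpus Pajek networks
and a `manifest.json` recording the config hash and seeds; reruns with
the same config are byte-identical.

`synnet battery --use-reference-panel` runs the statistical battery on
the bundled published ten-network parameter table without any corpora.

## Python API

```python
from synnet import (
    read_dependency_table, build_network, compute_metrics_row,
    cumulative_degree_distribution, fit_power_law, fit_poisson,
    compare_models, ensemble_metrics, assess_small_world, run_battery,
)
from synnet.metrics import degree_stats

tb = read_dependency_table("corpus.tsv")
net = build_network(tb)
row = compute_metrics_row(net, tb.meta, token_count=tb.token_count)
dist = cumulative_degree_distribution(degree_stats(net))
cmp = compare_models(fit_power_law(dist), fit_poisson(dist))
```

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: worked-example
values, statistical-battery reproduction at printed precision, oracle
equivalence of all metrics against brute-force references, G(N, M)
closed-form checks, model-recovery simulations and end-to-end qualitative
trends. The full suite runs in a few minutes on one CPU.

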
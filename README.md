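# csdbench

Benchmark harness for causal structure discovery on an Alzheimer's-like
biomarker cascade.  The package

- defines a literature-derived **gold-standard causal DAG** over
  `AGE, SEX, EDU, APOE4, ABETA, PTAU, FDG, DX` (cross-sectional) and its
  two-visit longitudinal extension,
- **simulates cohorts** from a linear-Gaussian structural model on that DAG,
  calibrated in closed form so every variable reproduces the published
  marginal summary statistics (diagnosis is a thresholded latent, delivered
  both as `DX_star` and as a CN/MCI/AD code),
- runs three structure-search algorithms under three levels of background
  knowledge:
  - `fges` — serial greedy equivalence search with decomposable Gaussian
    BIC (insert/delete operators, Meek-rule pattern rebuilds),
  - `fci` — constraint-based search producing a partial ancestral graph
    (Fisher-z conditional-independence tests, possible-d-sep pruning,
    collider/discriminating-path/tail-completion orientation rules),
  - `sem` — stepwise path-model edge addition driven by exact BIC refits
    (the "use SEM to refine a hypothesized graph" control arm),
- **evaluates** discovered graphs against the gold standard with edge-level
  correct/semi-correct/incorrect labels, precision/recall, bootstrap
  occurrence rates and consensus graphs, and
- orchestrates the two studies end-to-end: the bootstrap discovery
  experiment and the SEM deletion-recovery study.

## CLI

```bash
# sample a cohort (CSV); defaults: n=1008 cross-sectional, n=266 longitudinal
csdbench simulate --design cross_sectional -n 1008 --seed 7 -o cohort.csv

# run one algorithm; graph written in Tetrad-style edge notation
csdbench discover --algorithm fges --data cohort.csv --knowledge-level 2 -o graph.txt
csdbench discover --algorithm fci  --data cohort.csv --alpha 0.05

# score a graph file against the gold standard
csdbench evaluate --graph graph.txt

# SEM deletion-recovery study (8 single + 28 pair deletions, <=5 additions)
csdbench recover --population -o recovery.json

# full bootstrap discovery experiment -> JSON report bundle
csdbench report --algorithms fges,fci,sem --knowledge-level 2 \
    --n-bootstraps 100 --seed 0 -o report.json
```

Knowledge levels: **1** no constraints; **2** nothing may point into a
demographic variable (`AGE, SEX, EDU, APOE4`); **3** adds temporal tiers so
no edge points from a later visit to an earlier one (longitudinal designs).
Custom knowledge can be supplied as YAML (`forbidden:` / `required:` /
`tiers:`), cohorts as any CSV with the expected columns, and generator
parameters as YAML via `--params`.

All randomness is seed-driven; replicate seeds derive from the master seed
via `SeedSequence([master, index])`, so reports are byte-reproducible.

## Layout

```
src/csdbench/
  graphs.py      mixed-mark graph model, Meek rules, CPDAG/PDAG machinery, text I/O
  knowledge.py   forbidden/required pairs, temporal tiers, knowledge levels
  gold.py        gold-standard DAGs (cross-sectional and longitudinal)
  cohort.py      calibrated linear-Gaussian simulator, bootstrap resampling
  stats.py       covariance model, Fisher-z test, decomposable BIC
  ges.py         greedy equivalence search + exhaustive small-graph oracle
  fci.py         PAG search: skeleton, possible-d-sep, orientation rules
  sem.py         path-model fitting, stepwise edge addition, recovery study
  evaluation.py  edge classification, precision/recall, occurrence, consensus
  experiment.py  bootstrap experiment and recovery-study orchestration
  cli.py         click entry points
```
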
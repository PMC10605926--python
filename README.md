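# fedssvm

Federated sparse (L1-regularised) soft-margin SVM toolkit for
hospitalization-risk style binary classification on tabular clinical
features, built around a consensus primal–dual splitting solver.

The package provides:

- **`fedssvm.datasets`** — seeded synthetic EHR-like cohorts (continuous +
  indicator feature blocks, sparse linear ground truth, label noise,
  tunable class balance), IID and Dirichlet label-skew partitioning across
  agents, stratified train/test splits, CSV I/O.
- **`fedssvm.network`** — connected agent graphs (complete, ring, path,
  star, Erdős–Rényi) and their Metropolis doubly stochastic weight
  matrices.
- **`fedssvm.svm`** — the sparse-SVM objective (hinge + ridge + L1, bias
  unpenalised), predictions, the elastic-net and hinge-conjugate proximal
  operators, and the stacked margin operator.
- **`fedssvm.cpds`** — the decentralised primal–dual splitting solver: a
  local hinge dual per agent plus a consensus dual driven by the Metropolis
  disagreement `I − ω`; only model vectors cross the network, and the
  averaged model converges to the centralized optimum.
- **`fedssvm.baselines`** — an exact centralized QP oracle (split-variable
  reformulation, scipy `trust-constr`) and a FedAvg-style comparator with
  deterministic proximal-subgradient local passes.
- **`fedssvm.scheduler`** — Round-Robin participant scheduling and message/
  byte accounting (one message = one `(d+1)`-float model vector).
- **`fedssvm.experiments` / `fedssvm.cli`** — accuracy-vs-rounds,
  accuracy-vs-volume and utility-vs-cost experiment grids behind a CLI.

## CLI

```bash
# write a synthetic cohort CSV
fedssvm generate cohort.csv --config config.yaml --seed 1

# train one method (cpds | fedavg | oracle) and save the model JSON
fedssvm train cpds model.json --config config.yaml

# run the configured experiment grid -> metrics CSV
fedssvm curves metrics.csv --config config.yaml --seed 1

# plots: accuracy vs rounds / volume, utility vs cost
fedssvm report metrics.csv plots/
```

A config file is YAML mirroring `fedssvm.experiments.ExperimentConfig`:

```yaml
cohort: {n_samples: 1000, n_continuous: 10, n_binary: 10, sparsity: 5,
         label_noise: 0.05, positive_fraction_target: 0.4}
m: 5
topology: star
partition_mode: label_skew
skew_alpha: 0.5
hyperparams: {psi: 0.5, rho: 0.2}
methods: [cpds, fedavg, oracle]
checkpoints: [50, 100, 150, 200]
seed: 0
```

Every run is a pure function of the config seed; `fedssvm curves` output is
reproducible byte for byte.

## Solver notes

The solver treats `min Σ_j G_j(x_j) + F_j(K_j x_j)` subject to
`x_1 = … = x_m` with `G_j` the (per-agent scaled) elastic-net penalty and
`F_j` the hinge sum over agent j's margins. Consensus is enforced through a
dual variable updated with the Metropolis disagreement `(I − ω) x̃`, which
keeps all communication to one primal vector per neighbour per round and
gives fixed points that are exactly consensual and globally optimal. Step
sizes must satisfy `τ·σ·(max_j ‖K_j‖² + β‖I − ω‖) ≤ 1`; `default_config`
picks `σ = 1/Λ, τ = 0.9/Λ` with `Λ` computed by power iteration.
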
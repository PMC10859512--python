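# symnet

Symptom-network analysis of depression and anxiety screening items.

Comorbid depression and anxiety are increasingly studied at the level of
individual symptoms rather than scale sum-scores: the 10 items of the
CESD-10 depression scale and the 7 items of the GAD-7 anxiety scale are
modelled as nodes of an undirected network whose edges are regularized
partial correlations.  Nodes with high **expected influence** (EI — the
signed sum of a node's edge weights) are candidate *central symptoms* that
drive the network; nodes with high **bridge expected influence** (BEI —
the signed sum of edges crossing into the other disorder's community) are
candidate *bridge symptoms* that transmit activation between disorders and
sustain comorbidity.

`symnet` packages this workflow for epidemiological survey data, plus a
synthetic-data generator with a known ground-truth network so the whole
pipeline is testable without access to any particular survey:

- **`symnet.synthetic`** — latent-Gaussian threshold generator for 0–3
  ordinal items with calibrated right-skewed marginals, a two-community
  partial-correlation structure, eligibility covariates and survey missing
  codes.
- **`symnet.scales`** — eligibility filtering (age ≥ 65, diagnosis flag,
  complete items), CESD-10/GAD-7 scoring and cutoffs, prevalence and
  comorbidity, Cronbach's α, item descriptives.
- **`symnet.estimation`** — Spearman correlations → PSD repair → graphical
  lasso over a log-spaced penalty path → EBIC (γ = 0.5) model selection →
  partial-correlation edge weights.
- **`symnet.centrality`** — EI, BEI, strength; raw and z-standardized.
- **`symnet.stability`** — non-parametric bootstrap CIs for edges,
  bootstrapped difference tests, case-dropping bootstrap and the
  correlation-stability (CS) coefficient.
- **`symnet.pipeline` / `symnet.cli`** — one-command reproducible runs
  with a machine-readable manifest.

The model and estimator choices (Spearman instead of polychoric for skewed
ordinal items, EBIC hyperparameter 0.5, percentile bootstrap, one-step
EI/BEI, a-priori 10 + 7 communities) are documented with their rationale in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import symnet as sn

# synthetic survey emulating the study conditions: 1685 eligible adults
table = sn.simulate_study(n=1685, seed=1)
items = sn.filter_eligible(table).table[list(sn.NODE_NAMES)]

model = sn.select_network(items, gamma=0.5)
print(model.edge_count, "of", model.n_possible_edges, "edges")
print(model.edge_list().sort_values("weight", ascending=False).head(6))

cent = sn.centrality_table(model)
print(cent.nlargest(3, "BEI")[["node", "community", "BEI"]])
```

prints

```
32 of 136 edges
node_a node_b  weight
 CESD5  CESD7   0.274
 CESD1  CESD3   0.224
 CESD8  CESD9   0.200
  GAD2   GAD3   0.154
 CESD2  CESD4   0.150
  GAD5   GAD6   0.148

 node  community   BEI
 GAD1    anxiety 0.058
CESD4 depression 0.025
CESD5 depression 0.021
```

The selected network keeps 32 of the 136 possible edges.  The six
strongest edges are the generator's within-community anchor pairs —
e.g. hopelessness–lack of happiness (CESD5–CESD7) and uncontrollable
worry–worrying too much (GAD2–GAD3) — with weights attenuated relative to
the latent truth by the ordinal discretization.  The top bridge node is
GAD1 (nervousness/anxiety), whose BEI aggregates the weak cross-community
edges that carry depression–anxiety comorbidity in the generating network.

The `examples/` directory walks through each capability (simulation,
screening, estimation, centrality, stability) as short narrative scripts;
the same stages are available from the shell:

```bash
symnet simulate --n 1685 --seed 1 --out survey.csv
symnet estimate survey.csv --out results/
symnet run-all --seed 1 --out results/   # full pipeline + manifest
```

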
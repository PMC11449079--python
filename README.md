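# phytotime

Pseudotime ordering and expression-timing analysis for **single-plant bulk
RNA-seq populations**.

When a population of genetically near-identical plants is harvested at one
chronological time, individuals are spread across a developmental window:
they pass through rapid transitions — such as the vegetative-to-reproductive
(bolting) transition in *Arabidopsis thaliana* — asynchronously. That
asynchrony is information. By ordering the individual plants along a latent
developmental axis ("pseudotime") one snapshot becomes a high-resolution
time series, resolving the sequence of transcriptional events inside what
looks like a binary switch.

Standard single-cell trajectory tools need hundreds to thousands of samples;
a bench population has tens. `phytotime` implements a consensus rank-sum
method built for that regime, together with the surrounding analysis stages:

- **Simulation** (`phytotime.simulate`) — synthetic populations with latent
  ages, monotone sigmoid gene trajectories, a bolting threshold,
  age-correlated traits and planted causal variants, so every stage has a
  recoverable ground truth.
- **Preparation** (`phytotime.prep`) — isoform→gene aggregation,
  low-expression filters (TPM 0 in ≥10 samples, or TPM <0.5 everywhere),
  CPM normalisation, correlation-based sample clustering with outlier flags.
- **Differential expression** (`phytotime.de`) — per-gene Mann–Whitney U
  between bolted and nonbolted plants on CPM, Benjamini–Hochberg correction,
  classification at adjusted p < 0.05 and |log₂FC| > 0.1.
- **Pseudotime** (`phytotime.pseudotime`) — DE genes are z-scored, clipped
  at ±3, min-max rescaled to [0, 1] and flipped so all profiles rise with
  age; genes are randomly partitioned into 100 groups; each group orders the
  samples by summed normalised expression x<sub>i,j,k</sub>; per-group
  orderings are combined by assigning each sample to its most common
  predicted position, with deterministic conflict resolution.
- **Curves & timing** (`phytotime.curves`) — cubic B-spline smoothing with a
  second-derivative penalty, minimising ‖y − Bc‖² + λ∫(f″)²; hyperparameters
  chosen by total GCV = n·RSS/(n − tr H)²; best-fitting genes retained;
  monotone genes (derivative never crossing 0 within a ±10⁻³ tolerance)
  summarised by the **AUC timing statistic** — the integral of the rescaled
  curve (of 1 − x for increasing genes), so early-changing genes score low.
  Shape-based (k-shape-style) clustering and Kruskal–Wallis/Nemenyi tests on
  annotation-term AUC distributions characterise process timing.
- **Trait prediction** (`phytotime.traits`) — elastic-net linear and
  logistic models under a tiered scheme: outer leave-one-out CV, inner
  5-fold CV over penalty strength and l1_ratio ∈ {0.1, 0.5, 0.7, 0.9, 0.95,
  0.99, 1.0}, one modal l1_ratio fixed across folds, consensus predictors by
  median coefficient.
- **Association** (`phytotime.assoc`) — VCF → dosage encoding (0|0→0,
  0|1/1|0→1, 1|1→2) with GQ/call-rate/MAF filters, variant–pseudotime
  correlation at |r| > 0.5, subgroup expression linear models, and GRN edge
  filtering (weight ≥ 10⁻¹⁰, top 5 % by weight, binding-prior intersection).

Core components follow scikit-learn estimator conventions
(`ConsensusPseudotime`, `PenalizedBSplineSmoother`, `KShapeClusterer`,
`ElasticNetLOOCV`, `LogisticLOOCV`); module-level functions wrap them.

## Worked example

```python
import numpy as np
from scipy import stats
from phytotime import prep, de as de_mod
from phytotime.simulate import SimulationConfig, simulate_population
from phytotime.pseudotime import normalize_for_pseudotime, ConsensusPseudotime
from phytotime.curves import fit_gene_curves, timing_table

pop = simulate_population(SimulationConfig(seed=7))   # 68 plants, 2000 genes
cpm = prep.cpm_from_counts(pop.expression)
de = de_mod.de_table(cpm, pop.traits["bolted"])
print("up:", (de.de_class == "up").sum(), "down:", (de.de_class == "down").sum())

norm, _ = normalize_for_pseudotime(pop.expression, de)
cp = ConsensusPseudotime(n_groups=100, random_state=0).fit(norm.T)
cp.orient(pop.traits["bolted"])
rho = stats.spearmanr(cp.consensus_rank_,
                      pop.truth.ages.loc[cp.consensus_rank_.index]).statistic
print("spearman(pseudotime, true age) = %.3f" % rho)

norm_u, _ = normalize_for_pseudotime(pop.expression, de, flip_down=False)
order = cp.consensus_rank_.sort_values().index
fits, gcv = fit_gene_curves(norm_u.loc[:, order], np.linspace(0, 1, 68),
                            n_basis=12, lam=1.0)
timing = timing_table(fits)
print("monotone genes:", int(timing.monotone.sum()), "of", len(timing))
```

Output:

```
up: 696 down: 1275
spearman(pseudotime, true age) = 0.994
monotone genes: 1930 of 1971
```

696 + 1275 of 2000 genes shift with bolting (the simulator plants 65 %
decreasing / 25 % increasing / 10 % flat); the inferred ordering recovers
the latent ages at ρ = 0.994 despite multiplicative noise and dropout; and
nearly all fitted curves are monotone, each then summarised by its AUC
(small = early-changing). The same pipeline runs from the shell:

```bash
phytotime run --out demo_run --seed 7          # synthetic end-to-end run
phytotime simulate --out fixtures --seed 3     # just write a fixture
phytotime de --expr cpm.tsv --traits traits.tsv --out de.tsv
```

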
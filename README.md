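# seasonet

Seasonal dynamics of soil microbial communities under experimental
warming, analyzed through co-occurrence networks. `seasonet` is a Python
library and CLI for microbial ecologists who have a rarefied OTU table
from a designed time series (treatment × block × month) and want the
full downstream chain, reproducibly and with every statistic
implemented, tested and seedable:

* **β-diversity** — PCoA, PERMANOVA (`dissimilarity ~ treatment × month
  + block`, sequential pseudo-F), multivariate homogeneity of group
  variances (β-dispersion around group centroids), paired
  warming–control divergence with quadratic regression over months, and
  Mantel tests against environmental distances.
* **Co-occurrence networks** — ≥ 75% prevalence filter, log10
  relative-abundance transform, Pearson similarity |r|, hard threshold
  S_t (seasonal 0.890 / global 0.680 by convention), with signed edges
  retained.
* **Topology** — avgK = 2L/n, clustering, connectance, geodesic
  distance, power-law fit of the degree distribution, Newman–Girvan
  modularity M = Σ_c (l_c/L − (d_c/2L)²) by greedy agglomeration with
  deterministic refinement, degree-preserving rewired null ensembles
  and relative modularity (M − M_null)/M_null.
* **Node roles and module eigengenes** — Guimerà–Amaral Zi/Pi with the
  Zi > 2.5 / Pi > 0.62 hub and connector cutoffs; first-singular-vector
  eigengenes per module (≥ 5 members), their hierarchical clustering and
  Pearson correlations with environmental variables.
* **Robustness** — abundance-weighted mean interaction strength
  wMIS_i = Σ_j b_j s_ij / Σ_j b_j, extinction cascades after random 50%
  removal or targeted removal of five module hubs, 100 repetitions,
  Welch t comparison between treatments.
* **Stochasticity** — normalized stochasticity ratio (NST) per group
  from fixed-richness, occurrence-weighted null communities, with exact
  or sampled permutation comparison between groups.
* **Synthetic benchmark** — a generator that emulates the study design
  (96 samples at depth 17,700; +4.3 °C and ×0.793 moisture under
  warming; 5 planted modules × 20 OTUs with association strength 0.95)
  and keeps the ground truth for recovery tests.

See `docs/methods.md` for models, parameter defaults and numerical
choices.

## Worked example

```python
import seasonet as sn

table, meta, env, truth = sn.simulate_study(7)   # 600 OTUs x 96 samples

dist = sn.community_distance(table, "bray_curtis")
for r in sn.permanova(dist, meta, n_perm=999, seed=7):
    print(r.statistic_name, r.df, round(r.r_squared, 3),
          round(r.p_value, 3) if r.df != 69 else "")

warm = list(meta.index[meta.treatment == "warming"])
filt = sn.prevalence_filter(table, warm)          # >= 36 of 48 samples
net = sn.threshold_network(sn.similarity_matrix(filt), 0.680, table=filt)
mods = sn.greedy_modules(net)
abund = filt.counts.div(filt.counts.sum(0), axis=1).mean(1).loc[list(net.graph.nodes)]
rob = sn.robustness_random(net, abund, fraction=0.5, n_reps=100, seed=7)
nst = sn.nst(table, meta, grouping="treatment", n_rand=100, seed=7)
```

printed output:

```
600 OTUs x 96 samples, depth 17700
pseudo-F[treatment]          df=1   R2=0.019 F=1.99 p=0.004
pseudo-F[month]              df=11  R2=0.162 F=1.50 p=0.001
pseudo-F[treatment:month]    df=11  R2=0.109 F=1.01 p=0.442
pseudo-F[block]              df=3   R2=0.035 F=1.19 p=0.141
residual                     df=69  R2=0.675
warming global network: n=102 L=918 pos=80.0% M=0.800
robustness (50% random removal): 0.443 +/- 0.014
NST control: 75.3%   NST warming: 75.6%
```

Reading it: month explains the largest community-structure variance
(seasonal succession) and the warming term is small but significant; the
warming global network at S_t = 0.68 keeps 102 of the prevalence-filtered
OTUs with 918 links, 80% from positive correlations, and is strongly
modular (M = 0.80 > 0.4); removing half the taxa at random leaves 44% of
nodes after the extinction cascade; and both treatments sit near NST ≈
75%, i.e. assembly in this synthetic community is mostly stochastic.

## One-config pipeline

```bash
seasonet run --config examples/config.yaml --out run1/
```

executes simulate (or load your own `otu.tsv`/`meta.tsv`/`env.tsv`) →
β-diversity → 2 global + 8 seasonal networks → topology, roles,
eigengenes → robustness → NST, writing TSV/GraphML/JSON outputs, a
`summary.json`, and a manifest with all derived seeds. Identical configs
give byte-identical summaries. Individual steps are also exposed:
`seasonet simulate|beta|network|topology|robustness|nst`.

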
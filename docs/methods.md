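# Methods

`seasonet` re-implements, as a tested library, the analysis chain commonly
applied to warming-experiment soil microbiome time series: β-diversity
permutation statistics, hard-threshold Pearson co-occurrence networks with
module and node-role analysis, node-removal robustness simulation, and
null-model quantification of community-assembly stochasticity. This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic benchmark does and does not demonstrate.

## Data model and rarefaction

The root object is an integer OTU × sample count table with optional
taxonomy strings and per-sample metadata (treatment ∈ {warming, control},
block 1–4, month 1–12; season is a function of month: 3–5 spring, 6–8
summer, 9–11 fall, 12/1/2 winter). Rarefaction to a fixed depth (default
17,700 reads) samples **without replacement** within each sample
(multivariate hypergeometric), so rarefied counts never exceed the input
and every retained column sums exactly to the depth. Samples below depth
are dropped with a warning rather than aborting the run, so parameter
sweeps survive edge draws. All-zero OTU rows are retained; filtering is an
explicit downstream step.

Community dissimilarities are Bray–Curtis on counts, and Sørensen (Dice)
or Jaccard on presence/absence, all delegated to `scipy.spatial.distance`.

## β-diversity statistics

All permutation machinery is implemented in-package; p-values use the
conservative +1 convention p = (1 + #{perm ≥ obs}) / (1 + n_perm) and can
never be 0.

* **PCoA** is classical scaling of the Gower-centred squared-distance
  matrix. Negative eigenvalues (non-Euclidean dissimilarities) are
  reported, not corrected; their axes are retained separately because the
  dispersion construction needs them.
* **PERMANOVA** partitions the Gower-centred matrix by sequential (type-I)
  sums of squares over an ordered term list (default
  `treatment, month, treatment:month, block`), with pseudo-F per term and
  permutation of sample identities. For the full 96-sample design the
  degrees of freedom are 1 (treatment), 11 (month), 11 (interaction),
  3 (block) and 69 residual. Free permutation is the default; a
  `permute_within` argument restricts permutations to blocks for the
  repeated-measures reading of the design. The pseudo-F agrees exactly
  with an independent implementation (scikit-bio) in the test suite.
* **β-dispersion** embeds samples by PCoA and measures each sample's
  distance to its group centroid, handling negative-eigenvalue axes by
  subtracting their squared contribution and flooring at zero before the
  square root (the standard betadisper construction). F is a one-way ANOVA
  on those distances; p by permutation of group labels with centroids
  recomputed per permutation. Centroids (not spatial medians) are used;
  the dispersion metric defaults to Sørensen in the pipeline,
  configurable to Bray–Curtis.
* **Paired divergence** extracts the warming–control dissimilarity per
  (block, month) and fits OLS of dissimilarity on month and month²,
  reporting coefficients, R² and the overall-F p-value. A constant
  response returns R² = 0 rather than a 0/0 artefact.
* **Mantel** correlates off-diagonal distance vectors with p by
  row/column permutation of one matrix; when n! ≤ n_perm the permutation
  space is enumerated and p is exact.

Calibration: over 500 null simulations each (n = 24), PERMANOVA,
β-dispersion, Mantel and the eigengene–environment correlation hold
type-I error within ±2 percentage points of α = 0.05 (asserted in the
test suite).

## Co-occurrence networks

Construction follows the hard-threshold recipe: OTUs present in ≥ 75% of
the in-scope samples are retained (36 of 48 for global scopes, 9 of 12
for seasonal scopes); abundances are log10 relative abundances with zeros
replaced per OTU by 0.01 × that OTU's smallest nonzero proportion
(`none` and `clr` transforms are available — the original pipeline's
blank handling is not public, so the choice is exposed, with
`log10_pseudocount` the documented default); pairwise Pearson r is
computed across samples and edges keep |r| ≥ S_t. Similarity is |r| so
strong negative associations survive thresholding; the sign is an edge
attribute and positive/negative link fractions are reported. S_t is a
config input (0.890 seasonal, 0.680 global in the pipeline defaults); no
automatic threshold scan is performed. Isolated nodes are pruned;
raising S_t can only remove edges (a property test).

## Topology, modularity and null ensembles

Summary indices: avgK = 2L/n, connectance = 2L/(n(n−1)), mean local
clustering (degree < 2 contributes 0), and mean geodesic distance over
connected pairs only, with the unreachable-pair count reported (high
thresholds fragment the graph, so an all-pairs average is undefined).
The degree distribution is fitted by least squares on log frequency vs
log degree, returning the exponent and R².

Modularity is Newman–Girvan M = Σ_c (l_c/L − (d_c/2L)²) on the
unweighted simple graph. Optimization is CNM greedy agglomeration —
merge the connected community pair with the largest gain, continue
through negative gains, keep the best partition along the path, ties
broken by lowest node-id pair — followed by a deterministic single-node
local-move refinement sweep (each node, in sorted order, moves to the
neighboring community with the largest positive gain until no move
improves). The refinement is a standard companion to plain CNM and
measurably closes its gap to the exhaustive-partition maximum on small
graphs while never exceeding it (verified by enumeration on ≤ 8-node
fixtures; on sparse ring-like graphs the heuristic can remain below the
maximum). M > 0.4 declares modular structure.

Null ensembles are degree-preserving double-edge-swap rewirings (10 × L
attempted swaps per replicate; the degree sequence is asserted identical
every replicate), the stricter comparison relative to Erdős–Rényi.
Relative modularity is RM = (M − M_null)/M_null and is undefined for a
non-positive null mean.

## Node roles and eigengenes

Zi is the Guimerà–Amaral within-module degree z-score with the standard
deviation taken over same-module nodes (modules of size 1 or zero
variance give Zi = 0); Pi = 1 − Σ_s (k_is/k_i)². Categories use the
conventional cutoffs: module hubs Zi > 2.5, connectors Pi > 0.62,
network hubs both, peripherals otherwise.

A module eigengene (for modules with ≥ 5 members) is the first right
singular vector of the members' per-OTU standardized relative-abundance
profiles, scaled to zero mean and unit variance and oriented to correlate
positively with the mean member profile; variance explained is the first
squared singular value over the total. Eigengenes are clustered by
average linkage on 1 − Pearson correlation, and correlated with
environmental variables by Pearson r with two-sided t p-values —
starred raw, with a Benjamini–Hochberg column emitted alongside for
honesty.

## Robustness simulation

Node abundance is the mean relative abundance over the network's
construction samples. The abundance-weighted mean interaction strength of
node i is wMIS_i = Σ_j b_j s_ij / Σ_j b_j over remaining neighbors j,
with s_ij the signed edge correlation. After the initial removal — a
random fraction (default 0.5, 100 repetitions) or the top module hubs by
Zi (default 5; ties by Pi then id, with repetitions sampling among
equal-standing hubs at the cut) — the extinction rule (wMIS ≤ 0 or no
neighbors) is iterated to a fixed point; single-pass evaluation is
available for sensitivity. Robustness is survivors / original n.
All-positive networks never cascade, so robustness is exactly
1 − ⌊fraction·n⌋/n there; an independent step-by-step oracle reproduces
the surviving set exactly on random signed fixtures. Warming–control
comparisons use Welch's two-sided t-test on per-repetition values.

## Stochasticity (NST)

For each group, observed pairwise dissimilarities D_ij (Jaccard default,
Bray–Curtis optional) are compared to the mean E_ij over null communities
that fix each sample's richness and draw taxa with probability
proportional to their occurrence frequency in the group (equiprobable
available). Null draws use exponential-key weighted sampling without
replacement, equivalent to sequential draws with renormalization; for the
Bray–Curtis option each sample's reads are redistributed multinomially
over its null taxa proportional to regional relative abundance. Per-pair
stochasticity is D/E below the null, (1−D)/(1−E) above it, 1 at equality;
pairs with E ∈ {0, 1} are flagged and excluded; group NST is the mean
over pairs (reported as a percentage).

Two limits anchor the scale: communities drawn from the null itself score
NST ≈ 0.95, and strong selection toward distinct attractors within a
group (within-cluster near-identical samples, disjoint cores) scores
≈ 0.05. Note that a group in which *all* samples are near-identical is
not a low-NST case under a group-derived null: richness then nearly
exhausts the pool, the null reproduces the observed communities and E
tracks D — the informative deterministic signal is convergence to
*structure within* the group, not global uniformity.

Group comparisons permute sample labels over the union of two groups
using per-pair stochasticity values computed once under the pooled null,
recomputing each group's NST from within-group pairs; the full split
space is enumerated exactly when small. Fully recomputing the null
model inside every permutation would multiply the dominant cost by the
permutation count for no inferential gain.

## Synthetic generator

The generator emulates the study design: 2 treatments × 4 blocks × 12
months (96 samples). Soil temperature is a seasonal sinusoid (mean 12 °C,
half-range 13 °C, July peak) plus a +4.3 °C warming offset and noise
(sd 1 °C); moisture is a spring-peaked curve (mean 0.30, half-range 0.08)
scaled by 0.793 under warming (a 20.7% decrease); pH, SOC, TN, NO3, NH4
and the CO2 fluxes (R_h, R_a, R_t, R_eco, GPP, NEE) respond linearly to
temperature and moisture anomalies plus noise.

Counts follow a log-normal latent-factor model: each of 5 planted modules
has a per-sample standard-normal factor, and its 20 members load on it so
pairwise within-module latent correlation equals `assoc_strength`
(default 0.95) with zero between-module correlation; 10% of members load
negatively, planting negative associations. The remaining 500 OTUs are
independent log-normal noise with a heavy tail (sd 2 on the natural-log
scale) so the prevalence filter has realistic bite, plus random seasonal
amplitudes and warming selection coefficients (30% of noise OTUs,
sd 0.3); planted modules carry a per-module warming shift (sd 0.2) and no
seasonal term by default, keeping module ground truth clean. Latent
log-abundances are exponentiated, closed to proportions, and sampled
multinomially at depth 17,700 — the compositional, fixed-depth character
of rarefied data. Ground truth (membership, signed association matrix,
drivers, effect sizes, the latent matrix) is retained.

What the benchmark does *not* emulate: phylogenetic signal, spatial
autocorrelation between blocks, sequence-level error, overdispersion
beyond the multinomial, or taxon-specific warming responses calibrated to
any real community. Passing recovery tests therefore demonstrates that
the inference chain recovers the structure this model plants at realistic
depth and sample size — not that real soil networks are recovered with
the same fidelity.

## Pipeline and problem sizes

`run_pipeline` executes simulate (or load) → rarefy → β-diversity → 2
global + 8 seasonal networks → topology/modules/roles/eigengenes →
robustness → NST from one config, with a single seed fanned out to
per-stage seeds by a counter scheme recorded in the manifest. Reruns with
an identical config are byte-identical and reuse a completed run
directory (config SHA-256 in the manifest). Every scope must select ≥ 4
samples; violations fail validation before any compute.

The reported acceptance run uses 999 PERMANOVA permutations, 20 null
rewirings per network, 100 robustness repetitions and 200 NST
randomizations per group; the API defaults are 100 rewirings and 1000
randomizations.

## Known limitations

* Greedy modularity is a heuristic; the refinement narrows but does not
  close the gap to the exhaustive optimum on sparse cyclic graphs.
* The geodesic-distance average ignores unreachable pairs (count
  reported) and is therefore not comparable across networks with very
  different fragmentation.
* NST group values depend on the null configuration (metric, weighting,
  richness constraint); only the qualitative contrasts are
  interpretable across configurations.
* The eigengene uses standardized profiles; raw-abundance eigengenes
  would weight abundant members more and are not currently exposed.
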
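# Methods

`grnbench` benchmarks unsupervised gene-regulatory-network (GRN)
inference the way the field's reference comparisons do: a large
noise-free *datasource* (expression matrix plus true network) is
subsampled into many smaller, noise-contaminated *datasets*; every
inference method turns each dataset into a G×G edge-confidence matrix;
and each matrix is scored against the gold standard over only its most
confident predictions. This note documents the models behind each
stage, the defaults and why they were chosen, and what the synthetic
data can and cannot tell you about real expression compendia.

## Synthetic datasources

Real benchmark compendia come from kinetic simulators; `grnbench`
replaces them with two transparent generative models so that every
result is reproducible from a seed without external downloads or ODE
integration.

**Topology.** `generate_powerlaw_topology(G, E, seed)` samples one
out-degree per gene from a discrete power law P(d=k) ∝ k^-a (default
exponent a = 2.5, k = 1…G−1), wires each gene to that many distinct
successors in a random topological order, then trims or augments edges
uniformly at random to exactly E. The result is a directed acyclic
graph with a heavy-tailed out-degree distribution (hubs — master
regulators) whose steady states are computable in closed form by one
pass in topological order. Real GRNs contain feedback loops; forcing
acyclicity is the price of closed-form steady states and is a stated
non-goal.

**Knockout datasources** (one experiment per single-gene knockout)
use a linear structural-equation model: gene j's abundance is
x_j = b_j + Σ_i w_ij x_i, evaluated in topological order, floored at a
small positive value, with the knocked-out gene clamped to 0. Defaults:

| parameter | default | rationale |
|---|---|---|
| gain magnitude \|w\| | U(0.15, 0.25) | sub-unity gains make a perturbation decay geometrically with path length, the linear analogue of the attenuation that saturating kinetics produce; a k-hop influence is ~0.2^k of the knockout deviation, so direct targets separate cleanly from indirect descendants |
| activation probability | 0.75 | transcriptional networks are activation-biased; with symmetric random signs, parallel paths frequently cancel a direct effect and make individual edges undetectable in principle |
| basal level b | U(1.3, 1.8) | narrow positive range keeps knockout deviations on a comparable scale across genes (wide basal ranges reorder effect sizes rather than model anything biological) |
| knockout level | 0 | abundance scale; makes the knocked-out gene the strict minimum of its experiment, so minimum-based knockout detection is exact |
| expression floor | 0.05 | keeps abundances positive under repression |

**Multifactorial datasources** (every experiment perturbs all genes
slightly — the common observational-compendium regime) use saturating
regulation: each experiment multiplies every gene's basal rate by an
independent lognormal factor exp(sZ − s²/2) (unit mean, default spread
s = 0.4, i.e. ~40% coefficient of variation), and a regulated gene's
steady state is m_j · (b_j + Σ_i v_ij h_ij(x_i)) with Hill terms
h = x^n/(K^n + x^n) for activation and its complement for repression
(n = 2; strengths v ~ U(0.5, 1.0); equal odds of activation and
repression). The half-saturation constant K of each edge is pinned to
the regulator's unperturbed steady-state level (two fixed-point passes),
which keeps every edge in the responsive part of its curve — without
this, many edges sit in a saturated regime and carry no statistical
signal at any sample size.

**What the generators do not emulate:** feedback loops, time series,
measurement-specific error structure (intensity-dependent microarray
noise, count noise), hidden confounders, and the particular kinetic
parameter distributions of published simulators. Passing benchmarks
here demonstrate correct method implementations and the expected
*relative* behaviour of methods across data regimes; absolute AUPR
values on real compendia will differ.

## Subsampling and noise

`subsample` draws experiments without replacement within a dataset
(datasets may overlap with each other). Noise is added in two parts:

* **local noise** — additive, zero-mean, per-gene std
  σ_g · U(0.8κ, 1.2κ)/100, where σ_g is the gene's std over the rows of
  the dataset (computed after subsampling). Every gene keeps roughly the
  same signal-to-noise ratio; the ±20% band gives replicate datasets
  slightly different SNRs, emulating between-batch variability.
* **global noise** — additive, zero-mean, one dataset-wide std
  mean(σ_g) · U(0.8κ_g, 1.2κ_g)/100 shared by all genes. "Mean
  variance of all the genes" is read as the mean of per-gene *standard
  deviations*, matching the σ̄_g symbol.

Either component can be normal or lognormal. Lognormal noise is
generated as c·exp(Z) (shape parameter 1 by default) scaled to the
target std and shifted by its mean, so the added noise has zero mean —
noise is contamination, not a systematic shift. The benchmark default
is 20% normal local noise plus 10% lognormal global noise.

The subsampling RNG stream is independent of the noise stream, keyed
only by (master seed, datasource, dataset index, size), so the noise
sweep applies different noise levels to *identical* experiment draws.

## Inference methods

All methods satisfy one contract: expression matrix in, finite G×G
score matrix out, zero diagonal, higher = more confident, rows =
putative regulators.

**Mutual information** (shared by relnet/CLR/ARACNE/C3NET/MRNET/
MRNETB): plug-in estimate on equal-frequency bins, B = ⌈√N⌉ by default.
Binning uses midranks, so tied values always share a bin and the
estimate is invariant under strictly monotone per-gene transforms.
The plug-in estimator is biased upward by roughly (B−1)²/(2N ln2) bits
under independence; this bias is nearly uniform across pairs and the
row-normalization of CLR (and the ranking-only use everywhere else)
makes the methods insensitive to it. Term sums are accumulated in
sorted order so that M_ij and M_ji are bit-identical — greedy
selections downstream must not see 1-ulp asymmetries, and exact MI ties
are common on discretized data, so all greedy argmax steps break ties
by gene id rather than column position.

* **relnet** — the MI matrix itself (thresholding is the evaluator's job).
* **clr** — each row's MI values are summarized by mean μ_i and std
  σ_i (G−1 denominator, diagonal zero included in the row); the score is
  √(c_i² + c_j²) with c_i = max(0, (M_ij − μ_i)/σ_i), and 0 for a
  constant row.
* **aracne** — data-processing-inequality pruning: M_ij is zeroed when
  some third gene k has min(M_ik, M_jk) − ε > M_ij (ε = 0 by default);
  all removals are decided simultaneously on the original matrix.
* **c3net** — pairs below a permutation-null significance threshold
  (100 draws, α = 0.05; each draw shuffles one column of a canonically
  chosen gene pair) are zeroed, then each gene keeps only its single
  strongest partner; after max-symmetrization at most G connections can
  survive.
* **mrnet** — per target, forward minimum-redundancy maximum-relevance
  selection: candidate score u_j = M_jt − mean over already-selected s
  of M_js, stop when no candidate is positive; confidence = u at
  selection time, symmetrized by max.
* **mrnetb** — per target, backward elimination (drop the gene whose
  removal most improves the set objective Σ relevance − mean pairwise
  redundancy) followed by sequential replacement (best of swap/add/drop
  while strictly improving; each accepted move raises the objective, so
  it terminates). Backward and forward greedy can land in different
  local optima; neither dominates the other in general.
* **mutrank** — per gene, partners ranked by decreasing |Pearson r|
  (average ranks on ties); combined score s_ij = r_ij·r_ji/2, emitted
  negated so that higher = better. The defining text calls this a
  geometric mean but prints the product over 2; the printed formula is
  implemented. Since ranks are positive, the two orderings agree
  monotonically, so ranking-based evaluation is unaffected.
* **zscore** — assumes knockout-style interventions: the knocked-out
  gene of experiment k is detected as the row minimum (first index on
  ties); its score against gene j is |x_jk − μ_j|/σ_j (population std;
  0 for constant genes). Genes detected in several experiments average
  their rows; never-detected genes emit zero rows. Directed.
* **pcit** — first-order partial correlations in every gene triplet.
  For triplet (i,j,k) the local tolerance ε is the mean of the three
  |partial|/|raw| correlation ratios (ratios with a zero denominator
  count as 1); pair (i,j) is non-significant in that triplet when
  |r_ij| ≤ ε|r_ik| and |r_ij| ≤ ε|r_jk|. An edge flagged in *any*
  triplet is zeroed — the same any-triplet semantics as the
  data-processing inequality it generalizes; survivors keep |r_ij|.
  This tolerance construction is this package's dialect.
* **genenet** — shrinkage-regularized full-order partial correlation:
  the correlation matrix is shrunk toward the identity with the
  analytic intensity λ = Σ var̂(r_ij)/Σ r_ij² (clipped to
  [10⁻⁶, 1], guaranteeing invertibility), and the confidence is
  |−Ω_ij/√(Ω_ii Ω_jj)| from the precision matrix Ω. The original
  heuristic's causal-orientation step is deliberately not implemented;
  this is an undirected ranking.
* **genie3** — one random-forest regression per target gene on all
  other genes (scikit-learn, 500 trees by default, √(G−1) features per
  split); score(i,j) = variance-reduction importance of i in j's
  forest. Candidate regressors are presented in gene-id-sorted order
  and each forest is seeded from (seed, target id), so results are
  reproducible and column-order independent. Directed.
* **random** — i.i.d. uniform scores from a hash of
  (seed, regulator, target): the floor reference whose expected
  precision at any cut is the gold edge density.

## Evaluation protocol

Self-pairs are never candidates. In directed mode the candidate
universe is all G²−G ordered pairs; in undirected mode (the default)
it is the (G²−G)/2 unordered pairs, a pair's score is the max over the
two directions and a pair is true if either direction is a gold edge.
Candidates are sorted by decreasing score, ties broken by a fixed
lexicographic edge order (recorded; an all-constant score matrix is
flagged as degenerate). Confusion counts are accumulated at each of
the first t = round(x·universe) ranks (x = 20% by default, round half
up).

Three scalar metrics summarize the truncated curves:

* **AUPR_top** — trapezoidal area under precision vs recall over the
  evaluated ranks, normalized by the recall actually reached at rank t,
  so a perfect ranking scores exactly 1 within the evaluated span.
* **AUROC_top** — trapezoidal area under TPR vs FPR, normalized by the
  FPR span covered (defined as 1 when no false positive occurs within
  the span).
* **mean precision** — arithmetic mean of precision over ranks 1…t.

The normalization of the truncated areas is a documented dialect: the
defining protocol reports "AUPR in the top x%" without fixing the
integration domain, so absolute values are comparable *within* this
package but only indicatively against other implementations. A random
ranking scores ≈ gold density on AUPR_top and ≈ 0.5 on AUROC_top.

## Benchmark orchestration and statistics

`run_benchmark` subsamples `datasets_per_source` datasets (default 10,
default 150 experiments), contaminates each with the configured noise,
runs every method on every dataset and records AUPR_top per
(method, dataset). A method that raises on a dataset is recorded as
missing and logged, never fatal. All RNG streams are derived from the
master seed through stable CRC-based hashes of (stage, datasource,
index) labels, so runs are bit-identical end to end.

Winner flags per datasource: the top-mean method is compared to every
other with a two-sided Wilcoxon rank-sum test — exact when both sides
have ≤ 10 replicates (full enumeration over C(n1+n2, n1) splits, with
midranks for ties and symmetric-tail counting), normal approximation
with tie correction otherwise — Bonferroni-corrected over the
(methods − 1) comparisons; every method not significantly different
from the top one shares the flag. Method ranks (1 = best, average on
ties) are computed within each datasource from mean AUPR_top and
aggregated across datasources as rank distributions, because AUPR
ranges differ too much between datasources to average directly.

The noise sweep re-runs the benchmark at κ ∈ {0, 25, 50, 75, 100} with
local normal noise only, reusing identical subsampled draws at every
level; the sample-size sweep re-runs at n ∈ {20, 50, 200, 800} with
20% local noise, re-subsampling per size and marking sizes beyond a
datasource's pool infeasible. Both re-subsample fresh datasets per
trial with documented seeds.

## Problem sizes used in the checked studies

The automated studies run at deliberately reduced scale so the full
suite completes on one CPU in minutes: knockout specialization at
G = 100, E = 135 over 10 seeds; sensitivity studies on a G = 150,
E = 210 multifactorial datasource with 10 trials per condition, with
the tree-ensemble method at 16 trees per forest in the sample-size
study (forest size affects importance variance, not the direction of
the sample-size trend). The acceptance script reports 5-dataset means
at G = 100 with 50-tree forests for the same reason. All scales are
configuration values, not code constants.

## Known limitations

* Steady-state data only; no time-series methods or evaluation.
* Acyclic topologies; methods that exploit feedback are not
  representable.
* The MI estimator's bin count trades bias for resolution; method
  rankings are stable under it, absolute MI values are not calibrated.
  At N ≈ 150 the √N-bin plug-in floor is comparable to the MI of a
  weakly coupled pair, so MI-based methods lose ground to
  correlation-based ones on this package's near-monotone multifactorial
  data — a joint property of estimator and generator, not of the method
  implementations, and one reason relative method standings here can
  differ from benchmarks built on kinetic ODE simulators.
* The exact rank-sum test enumerates up to C(20,10) ≈ 1.8×10⁵ splits;
  above 10 replicates per side it switches to the asymptotic form.
* GeneNet-style scoring omits causal orientation, so its directed
  performance cannot be assessed here.
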
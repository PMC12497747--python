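# Methods

`monoconn` screens epoch-wise summaries of task-fMRI functional connectivity
for monotone change across the repetitions of a block-design learning task.
This note records the models, the defaults and the numerical choices, and
what the synthetic validation does and does not establish.

## The analysis pipeline

**Epoch model.** An acquisition is a regions × volumes matrix sampled at a
fixed TR. The task cycles `n_iterations` times (default 8) through an
ordered list of conditions (default Encoding, Post-Encoding Rest, Retrieval,
Post-Retrieval Rest), each condition occupying `volumes_per_epoch`
consecutive volumes (default 9, i.e. 27 s at TR = 3 s). At the defaults a
participant contributes 8 × 4 × 9 = 288 volumes. Windows are extracted as
contiguous slices; a hemodynamic-lag shift of 0–2 volumes is supported and
defaults to 0 (epochs are long relative to the hemodynamic delay, and no
shift is part of the canonical analysis). Segmentation is a partition: at
lag 0 the 32 windows reassemble the input exactly.

**Connectivity.** For each (condition, iteration) window the edge weight
between regions i and j is the Fisher-Z transform `z = atanh(r)` of their
zero-lag Pearson correlation across the window's volumes. Graphs are kept
*full*: all n(n−1)/2 weighted edges are retained (30,135 at n = 246), with
no thresholding or binarization, preserving the complete distribution of
connectivity strengths. Correlations are clipped to |r| ≤ 1 − 1e−7 before
atanh so numerically perfect correlations (possible on synthetic or
duplicated signals; never observed on real data) stay finite. No detrending
is applied within the 9-volume window.

**Graph metrics.** Stronger connections are treated as shorter paths:
edge weights are inverted to distances before Dijkstra-based shortest-path
computation. Because a full Fisher-Z graph contains negative edges and
Dijkstra requires non-negative distances, the inversion policy is explicit
and is the single most consequential free choice in the pipeline:

- `exclude_nonpositive` (default): d = 1/z for z > 0, +∞ otherwise.
  Preserves the stronger-is-shorter ordering without reinterpreting
  anticorrelation as coupling strength.
- `absolute`: d = 1/|z|; treats correlation magnitude as coupling.
- `clip_epsilon`: z floored at 1e−6 and inverted; all edges stay finite.

Weighted betweenness centrality of node i is the fraction of all-pairs
shortest paths passing through i, summed over ordered endpoint pairs and
normalized by (n−1)(n−2), so BC ∈ [0, 1] (a star center scores exactly 1).
Endpoint pairs with no finite path contribute nothing. Nodes are then
ranked 1..n by descending BC (BC_RO; average rank on ties), making the
trajectory of interest a node's *relative* integrative importance rather
than its raw centrality, which is sensitive to overall connectivity level.
Average shortest path length (ASPL) is the mean Dijkstra distance over
ordered node pairs; pairs with no finite path are excluded from the mean
and their count is reported. Multiplying every positive weight by c > 1
divides ASPL by exactly c and leaves BC and BC_RO unchanged — the formal
link between "stronger connectivity" and "more efficient network".

The implementation delegates Brandes betweenness and Dijkstra to networkx /
scipy; the test suite holds both to independent brute-force oracles
(exhaustive simple-path enumeration and Floyd–Warshall) on graphs with
n ≤ 8 at 1e−9, with shortest-path ties detected at 1e−12 relative
tolerance. Exact tie counting and tolerance-based tie counting agree on
generic continuous weights, which is the tested regime.

**Monotonicity.** A length-T trajectory D₁..D_T is weakly monotone when
every adjacent step is non-decreasing (or every step non-increasing) and
the endpoints differ. The liberal variant used throughout permits
`max_violations` adjacent steps strictly against the trend (default 1).
Two documented choices: a violation is one adjacent reversal regardless of
magnitude, and the relaxed rule still requires the endpoints to be strictly
ordered in the claimed direction (a net-trend condition; without it a
sequence like 5,1,1,1,1,1,1,6 would be classified by violation count in an
arbitrary direction). Adjacent ties violate neither direction.

**Trend test.** Group-level screening uses Spearman's ρ between iteration
number 1..8 and the group-averaged BC_RO values, with an *exact*
permutation p-value over all 8! = 40,320 orderings (two-sided: the fraction
of orderings with |ρ| at least the observed, within 1e−12 relative
tolerance). The large-sample approximation is not trusted at n = 8; the
exact critical magnitude at α = 0.05 is |ρ| ≥ 31/42 ≈ 0.738. Ranks are
averaged across participants first and then tested (not re-ranked).
Significance is uncorrected p < 0.05 per node × condition × group by
default, matching the screening convention; Benjamini–Hochberg is available
(`fdr=True`) but off by default.

**Group statistics.** ASPL is tested with a three-way mixed ANOVA — Group
between subjects; Condition and Time within — using the classical
univariate split-plot decomposition with no sphericity correction: each
within stratum is formed by projecting out subject means and every within
effect is tested against its own effect-by-subject(group) error stratum.
With 88 participants in two groups, 4 conditions and 8 iterations the Time
effect carries df (7, 602) and the Group effect df (1, 86). Group sizes may
differ; within-subject cells must be complete (no imputation — unbalanced
designs are rejected). The decomposition was validated against R's
`aov` with `Error(participant/(condition*iteration))` on an unequal-groups
dataset; the seven F statistics agree to printed precision (frozen in the
test suite). Behavioral monotone proportions are compared with Fisher's
exact test (two-sided, hypergeometric). Edge-weight distributions are
summarized per group as mean, SD, deciles and an ECDF on a shared grid.

## The synthetic cohort generator

The generator is the pipeline's test bed: it plants known monotone
structure and group contrasts so that recovery can be measured against an
explicit manifest.

**Signal model.** Each epoch has one shared latent factor f_t ~ N(0, 1),
i.i.d. across volumes within the epoch; region r's signal is
`baseline + c_r·f_t + noise_sd·ε` with independent Gaussian noise. The
population correlation between regions i and j is therefore
`c_i c_j / sqrt((c_i² + σ²)(c_j² + σ²))`, which the calibration test
verifies empirically at 10⁴ volumes (±0.02). A one-factor model was chosen
over a full random covariance because it is the simplest structure in which
a node's centrality can be steered by a single number: raising a node's
loading strengthens all its edges at once. Hub nodes' loadings grow by
`drift_per_iteration` per task iteration (by default in all four
conditions; a per-condition mask is available), so their betweenness — and
hence their rank — drifts monotonically. The patient-like group's loadings
are reduced by `group_coupling_offset`, producing both the lower pooled
edge weights (a leftward Fisher-Z distribution shift) and the higher ASPL
that characterize the less efficient network. Volumes are white within
epochs by default; an AR(1) option (`ar1_phi`) exists because real fMRI is
temporally autocorrelated, but it is off by default for analytic
tractability of the calibration closed form. All loadings must lie in
[0, 1); configurations violating this (e.g. base + 8·drift ≥ 1) are
rejected with the offending parameter named.

Defaults: 246 regions, `base_coupling` 0.4, `group_coupling_offset` 0.1,
`noise_sd` 0.6, `baseline` 1000 — giving control-group epoch correlations
around 0.3 and patient around 0.2, a realistic Fisher-Z range.

**Behavior model.** Retrieval is modeled as all-or-none item acquisition:
each of 9 items is learnable with probability `behavior_asymptote` (0.92
control / 0.75 patient by default), a learnable item is acquired on any
iteration with probability 1 − e^(−rate) (rate 0.9), and once acquired it
stays correct (`lapse_prob`, default 0, re-introduces occasional recall
failures). The expected proportion correct is exactly the negatively
accelerated curve p_t = a·(1 − e^(−rate·t)), and realized trajectories are
weakly monotone — the defining empirical signature of associative-learning
performance, which per-iteration independent Bernoulli draws cannot
reproduce (item-level persistence is what makes individual learning curves
monotone, not just their expectation). A configurable fraction of
participants per group (0.1 control / 0.4 patient) are non-monotone
performers whose success schedule is permuted across iterations with items
redrawn independently; at these defaults roughly 90% of controls and 60%
of patients are classified monotone by the one-violation rule.

**What the generator does not emulate.** No hemodynamic response shapes,
head motion, physiological noise spectra, voxel-level structure, spatial
correlation between parcels beyond the single factor, or heavy-tailed
connectivity distributions. Passing the recovery tests therefore shows the
*statistical machinery* recovers planted monotone structure at realistic
noise levels — not that real task-fMRI contains such structure.

## Validation study sizes

Desk-scale problem sizes used by the test suite and the acceptance script
(chosen so the full validation completes in minutes on one CPU):

- **Oracle suites**: 100 random mixed-sign graphs with 4–8 nodes; all 3⁸
  sequences for the classifier; 10⁵ Monte-Carlo permutation draws.
- **Planted-drift recovery**: 30 regions, hubs {0, 1, 2}, base coupling
  0.3, drift 0.08/iteration (hub loading 0.38 → 0.94), noise SD 0.45,
  40 participants per group, no group offset — the recovery experiment
  isolates the planted-drift question from the group contrast. Hub
  recovery (significant trend toward rank 1) exceeds 90% while non-hub
  false positives stay near α.
- **Null calibration**: five no-drift cohorts (24 regions, 10 per group);
  the pooled significant fraction stays within binomial 99% bounds of
  α = 0.05. Rank trajectories of different nodes are negatively dependent
  (ranks sum to a constant per epoch), which only concentrates the
  fraction.
- **Directional group contrasts**: 24 regions, 6 per group, coupling
  offset 0.1. At least ~24 regions are needed at this scale: in very small
  graphs a single near-disconnected node (one tiny positive z) contributes
  a 1/z distance that can dominate the mean ASPL of an epoch.
- **ANOVA df check**: simulated ASPL tables at the published cohort shape,
  39 + 49 participants.

## Known limitations

- The distance-policy choice for non-positive Fisher-Z edges is not
  settled science; results on data with many negative correlations can be
  policy-sensitive, which is why all three policies are exposed.
- ASPL's mean over finite pairs is sensitive to near-disconnected nodes in
  small graphs (see above); the finite-pair fraction is reported alongside.
- The exact permutation test enumerates up to 10! orderings; longer
  trajectories would need a different strategy.
- The mixed ANOVA uses the classical weighted-means decomposition; with
  unequal group sizes other sum-of-squares conventions (Type III) would
  differ slightly. Degrees of freedom are unaffected.
- Behavioral classification counts only *increasing* trajectories as
  monotone performance, by design of the learning paradigm.
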
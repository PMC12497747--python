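# monoconn

Monotonicity screening of graph-theoretic summaries of epoch-wise task-fMRI
functional connectivity.

During associative learning, behavioral proficiency typically improves
*monotonically*: performance on each task repetition is no worse than on the
previous one. Whether connectome-level summaries of fMRI data co-acquired
during learning show the same temporal signature is an open question.
`monoconn` provides a tested, reusable pipeline for asking it: it turns a
parcellated BOLD time series into per-epoch weighted connectivity graphs,
tracks each node's centrality rank and the network's efficiency across task
iterations, and screens those trajectories — together with the behavioral
learning curves — for weak monotonicity, at the participant and the group
level. A synthetic cohort generator with *planted, ground-truth-known*
monotone structure makes the whole chain verifiable end to end.

## The pipeline

For a block-design task with 8 iterations of 4 conditions (Encoding,
Post-Encoding Rest, Retrieval, Post-Retrieval Rest; 9 volumes per 27-s epoch
at TR = 3 s):

1. **Epochs** — segment the regions × volumes matrix into 32
   (condition, iteration) windows; optional percent-signal-change
   trajectories per region.
2. **Connectivity** — per window, the *full* undirected weighted graph with
   edge weights z_ij = atanh(r_ij), the Fisher-Z transformed zero-lag
   Pearson correlation (30,135 unique edges for a 246-region parcellation;
   no thresholding).
3. **Graph metrics** — with edge distances d = 1/z (stronger = shorter;
   non-positive edges excluded by default, with `absolute` and
   `clip_epsilon` alternatives):
   - weighted betweenness centrality
     `BC_i = 1/((n−1)(n−2)) · Σ_{h≠j≠i} sp_hj(i)/sp_hj`, and its
     per-epoch rank order BC_RO ∈ {1..n} (1 = most central);
   - average shortest path length
     `ASPL = 1/(n(n−1)) · Σ_{i≠j} d(v_i, v_j)` via Dijkstra.
4. **Monotonicity** — a trajectory D₁..D₈ is weakly monotone when
   D₁≤D₂≤…≤D₈ or D₁≥D₂≥…≥D₈ with D₁≠D₈; the liberal rule used throughout
   tolerates one adjacent violation. Group-averaged BC_RO trajectories are
   tested with Spearman's ρ against iteration number using the **exact**
   8!-permutation two-sided p-value (critical |ρ| = 31/42 ≈ 0.738 at
   α = 0.05).
5. **Group statistics** — three-way mixed ANOVA on ASPL (Group between;
   Condition, Time within; classical split-plot sums of squares), Fisher's
   exact test on behavioral monotone proportions, pooled edge-weight
   distribution summaries per group.

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example

Simulate a small cohort with two drifting hub nodes (their latent-factor
loading grows each iteration, so their centrality rank should fall toward
1) and a patient-like group with reduced coupling, then analyze it:

```sh
cat > demo.yaml <<EOF
synthetic:
  n_regions: 16
  n_participants_per_group: 4
  hub_nodes: [0, 1]
  drift_per_iteration: 0.07
  base_coupling: 0.3
  noise_sd: 0.5
  seed: 42
EOF
monoconn simulate --config demo.yaml --out demo_cohort
monoconn run --config demo.yaml --cohort demo_cohort --out demo_out
monoconn report demo_out
```

which prints (abridged):

```
== Group-level monotone-trend screen (node counts) ==
            Encoding | control    0 increasing,   1 decreasing of 16 nodes (93.8% non-monotone)
           Retrieval | control    0 increasing,   2 decreasing of 16 nodes (87.5% non-monotone)
...
== Behavioral monotonicity ==
control  3/4 participants monotone increasing (75%)
patient  2/4 participants monotone increasing (50%)
Fisher exact (monotone proportion, two-sided): p = 1.0000

== ASPL mixed ANOVA (Group x Condition x Time) ==
Group                        F(1, 6) = 101.782, p = 5.507e-05
Time                         F(7, 42) = 1.201, p = 0.3236
...
```

Reading this: non-monotonicity of centrality rank is the norm for
non-drifting nodes, while planted hub node 0 surfaces as a significant
*decreasing* rank trend (rank moving toward 1 = rising hubness) in several
condition × group screens (`demo_out/group_trends.tsv`; e.g. Encoding,
control: ρ = −0.786, exact p = 0.028). The reduced-coupling patient group
is cleanly separated by network efficiency (Group effect on ASPL,
F(1, 6) = 101.8) while no Time effect is claimed (F(7, 42) = 1.2), and at
4 participants per group the behavioral proportions (3/4 vs 2/4) are far
from Fisher-exact significance — small-sample behavior working as it
should.

The same machinery is available as a library:

```python
from monoconn import SynthConfig, generate_cohort
from monoconn.pipeline import analyze_cohort

cohort = generate_cohort(SynthConfig(n_regions=24, n_participants_per_group=6, seed=7))
res = analyze_cohort(cohort)
print(res.aspl.groupby("group")["aspl"].mean())   # patient > control
print(res.anova.table)                            # Group F on df (1, 10)
```

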
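# rankloop

Dominance-rank inference and rank-structured-aggression statistics for
directed animal aggression networks.

## The problem

In many group-living animals (the motivating system is a captive group of
~20 monk parakeets observed over 24 days), dominance rank is not worn on
the body: it emerges from, and feeds back into, who attacks whom. Given
only a timestamped log of dyadic **aggressive wins** — an actor displaces a
target from its perch — `rankloop` answers three questions a behavioral
ecologist asks of such data:

1. **What is the hierarchy?** Continuous power scores and ordinal ranks
   from the directed win-count network.
2. **Is aggression structured by rank?** Observed aggression patterns are
   compared against a *hierarchy-constrained null model* — random
   aggression networks with the same power structure but no further
   strategy.
3. **What rank information do individuals have access to, and do they use
   it?** Signal statistics on network motifs (aggression chains) and on
   simpler cues (body size, spatial proximity).

## The statistics

Let `d_ij` be the number of wins of individual *i* over *j* in a window.

- **EC power scores.** The win matrix is regularized and row-normalized,
  `t_ij = (d_ij + eps) / sum_{k != i} (d_ik + eps)`, and the power-score
  vector `v` is the stationary distribution of the Markov chain with
  transition matrix `t` (`v^T t = v^T`): an individual has low power when
  it receives much aggression from individuals who themselves have low
  power. High `v` = low power; rank 1 = most dominant. (The naive
  row-sum fixed point `v = t v` is degenerate for a row-stochastic
  matrix; the stationary-distribution form is the non-degenerate reading
  of the same recursion.) Weighted Simple Consensus (incoming events x
  distinct aggressors) and David's Score are provided as breadth/depth
  cross-checks.
- **Null model.** An ensemble of win matrices that preserve every
  individual's total outgoing aggression *exactly* and the EC scores *on
  average*, but are otherwise unstructured: a zero-diagonal row-stochastic
  kernel is fitted so its stationary vector equals `v`, and each row is an
  independent multinomial draw.
- **Average rank aggression** `R(Delta) = (1 / (N_Delta T_obs)) sum_i
  d_{i, i+Delta}`: per-individual, per-minute aggression at the target
  exactly `Delta` rank steps away (`Delta > 0` = down the hierarchy,
  `N_Delta = N - |Delta|`). The **above-null ratio** summarizes
  rank-focused aggression as observed/null events at `Delta in [1, 5]`,
  with a one-sided empirical p-value.
- **Aggression chains.** For directed paths `i -> j -> k -> ...` of `n`
  edges with all individuals distinct and weight = product of win counts:
  `W(n)` is the weighted mean rank difference between originator and
  terminal (how much rank information a chain carries), and `T(n)` is the
  weighted mean relative excess of the originator's aggression toward the
  chain's terminal over its baseline aggression (whether chains predict
  behavior; `T < 0` = avoidance).

A synthetic event-stream generator with latent ranks and a configurable
rank-difference attack kernel (uniform early phase, focused-plus-avoidant
structured phase) makes every stage testable end to end with no field
data.

## Worked example

```python
import rankloop as rl

# a synthetic study: 20 birds, 24 days, unstructured first quarter, then
# rank-focused aggression
log, truth = rl.simulate_events(rl.GeneratorConfig(rng_seed=42))

cfg = rl.AnalysisConfig(null_replicates=100, max_chain_length=4, rng_seed=7)
res = rl.DominanceModel(log, cfg).fit()
print(res.summary())
```

prints

```
Dominance hierarchy analysis
============================================================
individuals: 20   events (post-filter): 1235   epsilon: 0.01   seed: 7
network density (directed): 0.76
EC vs WSC agreement: signed r^2 = 0.49 (Spearman rho = 0.77)

 window  events   ratio        p   W(2)      T(2)
-------------------------------------------------
    all    1235    1.86    0.010     4.33      0.10
     Q1     326    0.98    0.634     0.53     -0.00
     Q2     299    3.62    0.010     6.23      0.43
     Q3     297    3.55    0.010     6.58      0.39
     Q4     313    4.99    0.010     6.86      0.37
```

Reading it: after the 60-s win-cooldown filter, 1235 wins remain. In the
first 6-day quarter, aggression toward targets one-to-five ranks below is
indistinguishable from the hierarchy-constrained null (ratio 0.98,
p = 0.63) — the group has a power structure, but individuals do not yet
aim their aggression by rank. From quarter two on, nearby-below targets
receive 3.6-5x the null aggression (p = 0.01), two-step chains span ~6.5
ranks, and `T(2) ~ 0.4` says chains predict extra aggression toward their
terminal individual. `res.scores_frame()`, `res.profile_frame()` and
`res.chains_frame()` expose the tidy tables behind the summary; `res.save(dir)`
writes them as CSV plus a JSON run manifest.

The same analysis runs from the shell:

```bash
rankloop simulate --out sim/ --seed 42 --scans 200
rankloop run --config run.yaml      # events_csv/scans_csv + analysis block
rankloop demo                       # two-group structured-vs-unstructured demo
```

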
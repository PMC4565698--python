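# Methods

This note documents the models and procedures `rankloop` implements, the
defaults it ships with and why, what the synthetic generator does and
does not emulate, and the numerical choices that matter. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model and protocol filters

The unit observation is an aggressive win: `(time, actor, target)`, with
`actor != target`, on a fixed roster. Three protocol stages precede all
statistics:

- **Win cooldown** (default 60 s). Field observers log barrages of
  sub-attacks; a win A→B is only counted if at least the cooldown has
  elapsed since the previously *retained* A→B win. The clock resets from
  the retained event, so a continuous barrage yields one win per cooldown
  period — resetting from the raw last event would let a sustained
  barrage collapse to a single win forever, which contradicts the "one
  full win per target per minute" reading. The rule is applied per
  ordered pair: simultaneous attacks on different targets are independent
  wins.
- **Exclusions.** Individuals whose incoming aggression is judged
  reactive rather than strategic (e.g. a bird pestering others into
  displacing it) can be censored; every event touching them is dropped,
  the roster shrinks, and observation time is unchanged.
- **Windowing.** The study period divides into equal half-open windows
  `[start, end)` in event time (default four 6-day quarters); an event on
  a boundary belongs to the later window. Per-window `T_obs` is
  proportional to window length. Non-multiple durations error unless
  forced (short final window).

`R(Delta)` is internally events per individual per *minute*; figures
rescale to per-1000-minutes at presentation time only.

## Power scores

`t_ij = (d_ij + eps) / sum_{k != i}(d_ik + eps)`, zero diagonal. The EC
power-score vector is the stationary distribution of the chain with
transition matrix `t`. Two deliberate readings:

- The row-sum recursion `v = t v` has only the uniform solution for a
  row-stochastic `t`; the verbal semantics ("low power = much incoming
  aggression from the low-powered") require centrality to flow along
  *incoming* edges, i.e. `v^T t = v^T`. We implement the latter and flag
  it here prominently.
- The regularizer is added off-diagonal only (no self-aggression term),
  so rows sum to one over actual potential targets.

Default `eps = 0.01`: small against typical per-individual totals of
tens of events (it shifts each row by well under 1%), yet strictly
positive so the chain is irreducible and the stationary vector unique.
Reported results always carry the epsilon used. The stationary vector is
computed by dense eigen-decomposition of `t^T` for `N <= 64` (one
power-iteration refinement step damps solver noise) and by power
iteration (tol 1e-12, max 1e5 iterations) above. Reducible inputs (only
possible with `eps = 0`) raise an error advising a positive epsilon.

Rank 1 = most dominant = smallest EC score. Ties break by stable roster
order and the policy is recorded. WSC (incoming events x distinct
aggressors; higher = lower rank) and David's Score
(`DS = w + w2 - l - l2` on dyadic win proportions; higher = more
dominant) carry explicit polarity flags so derived ranks always mean the
same thing. Cross-method agreement reports Pearson and Spearman
correlations plus a signed r-squared `sign(r) * r^2` (the convention that
lets anticorrelated signals report negative values).

Bootstrap uncertainty resamples the event list with replacement (same
event count), re-scores end to end, and reports per-individual 1-sigma
score ranges, mean/modal bootstrap ranks and modal-rank frequencies. In
strong hierarchies the bottom ranks are pinned almost exactly across
resamples while the top ranks wobble: EC concentrates information where
aggression lands, and the most dominant individuals receive the least.

## The hierarchy-constrained null model

The null asks what aggression would look like with the same power
structure but no further strategy. Constraints: per-individual outgoing
totals exactly; EC scores on average. Construction: fit a zero-diagonal
row-stochastic kernel whose stationary vector equals the observed `v`
(initialize rows proportional to `v`, iteratively rescale columns by
`v_j / w_j`); draw each row as an independent multinomial. Because rows
are conditionally independent categorical draws, no correlation beyond
the two constraints is injected. The kernel, achieved residual and seed
are stored with every ensemble.

Numerics: the column-rescaling iteration converges in a handful of steps
for rosters of ~8 and larger but decays only like 1/iteration for very
small `N`; after 500 rescaling steps the fit switches to a Newton-type
solve over log column multipliers. Two-individual rosters have a forced
kernel whose stationary vector is (1/2, 1/2); any other target errors
with the achieved residual. Kernel fitting is deterministic given `v`;
sampling is reproducible given a seed.

Null statistics are computed against the *observed* rank order: the null
preserves the power scores by construction, and re-ranking each sample
would mostly permute near-ties (a config flag enables per-sample
re-ranking for sensitivity analysis). Empirical p-values are one-sided
with the `(count + 1)/(B + 1)` correction; samples on which a statistic
is undefined are dropped and counted.

**A structural property worth knowing.** The kernel must reproduce the
*estimated* score vector. In data that are truly rank-blind, the
estimate's sampling noise becomes, in the null's eyes, genuine shared
target preference: every null row tilts toward the same
high-estimated-score targets, while the observed matrix's noise is
unshared. Chain statistics are sensitive to shared preference, so
observed `W(n)` and `T(n)` of an unstructured group sit systematically
low (about 2 sigma) against this null, at any sample size — the
per-Delta profile `R(Delta)` is unaffected (~95% pointwise 2-sigma
coverage). This liberality is a property of hierarchy-constrained nulls
generally, not of this implementation; the validation suite measures and
reports per-family coverage so it is visible rather than hidden.

## Chain statistics

Chains are directed paths over nonzero edges with pairwise-distinct
individuals; length counts edges; weight is the product of win counts.
`W(n)` averages `rank(terminal) - rank(originator)` over chains, weighted;
`W(1)` is the dyadic weighted mean rank difference. `T(n)` averages
`(d[i, terminal] - b) / b` where the baseline `b` is the originator's
mean aggression toward individuals outside the chain. For `n = 2` the
baseline excludes the single intermediate; for longer chains the default
generalization excludes *all* interior members (`b = (S_i -
sum_interior d_i.) / (N - n)`), with the literal exclude-only-the-first
variant also implemented and reported when used. Chains whose baseline
is zero are excluded and counted. `T >= -1` by construction; both `W`
and `T` are invariant under scaling the whole matrix by a positive
integer.

Enumeration is a single depth-first pass over nonzero edges that
accumulates `W` and both `T` variants for *all* lengths `1..max_n` at
once, updating the interior-baseline sum incrementally; numba compiles
the scan when available (pure-Python fallback otherwise), and the study
size (N = 21, n = 6, ~6e8 path visits) completes in minutes on one core.
A cost guard errors beyond ~2e9 projected visits unless raised
explicitly. A naive all-tuples oracle over explicit vertex permutations
is kept in the package as an independent cross-check and is exercised,
against the DFS, across random matrices in the tests (agreement to
1e-12).

## Simpler signals of rank

Morphometrics (wing chord, culmen depth/width, mass) are tested per
trait by correlation with rank (Pearson and Spearman signed r-squared,
two-sided p). Spatial structure uses nearest-neighbor scan samples: the
dyadic table of (|rank difference|, times *i* was *j*'s nearest
neighbor) over ordered pairs — counts sum to the number of scans — and
its correlation; rank neighbors associating spatially shows up as a
negative signed r-squared. Undirected pooling of dyads is available by
flag.

## The synthetic generator

The generator emulates the *structure* of the motivating study: N = 20
individuals (19-21 supported), ~1200 expected wins (Poisson) over 24
days, an unstructured first quarter (`phase_change_day = 6`), and a
structured phase in which target choice depends on rank difference.
Latent ranks are generative truth only; the analysis never sees them
outside tests.

Structured kernel, for an actor and a target `Delta` ranks below (+) or
above (-):

| region              | weight                                           | default |
|---------------------|--------------------------------------------------|---------|
| focus, `1..5`       | `focus_strength * focus_decay^abs(Delta-peak)`   | strength 3, peak 3, decay 0.6 |
| far below, `> 5`    | `1 / avoidance_strength`                         | 4 |
| above, `< 0`        | `up_weight * up_decay^(abs(Delta)-1) + up_global`| 0.3, 0.7, 0.0 |

Actor choice is rank-graded (`rate ~ 0.9^(rank-1)`), the despotic
pattern in which dominants do most of the attacking.

Three design points were forced by round-trip analysis on *expected*
(noise-free) matrices rather than tuned on samples:

- **Local counter-aggression.** If up-hierarchy aggression spreads
  uniformly, the chain is translation-invariant in the bulk and its
  stationary distribution — hence EC — is flat mid-hierarchy, and no
  amount of data recovers the latent order. Geometrically local
  counter-attacks make the chain a drift walk with a monotone, graded
  stationary distribution; latent-rank recovery is then ~0.95-0.99
  Spearman at the default surface.
- **A humped focus.** With focus weight peaked at `Delta = 1`, typical
  chain steps are so short that 3-step chains still terminate inside the
  actor's focus zone, and long chains predict *extra* aggression —
  the opposite of the avoidance signature. A hump peaked ~3 ranks down
  puts 2-chain terminals inside, and 3-chain terminals beyond, the zone.
- **Rank-graded activity.** With uniform actor rates most 3-chains start
  mid-hierarchy and clamp against the bottom of the order, again ending
  inside the focus zone.

`GeneratorConfig.strong_structure()` names the strong-avoidance regime
(no warm-up, `avoidance_strength = 8`, `focus_peak = 3.5`, `up_weight =
0.2`, `up_decay = 0.5`, `up_global = 0.1`): hard suppression of far-below
targets plus a small rank-blind floor of upward challenges. The floor
keeps the EC score mass from collapsing onto the bottom ranks, which is
what keeps the null's `W` level flat and moderate so the observed
`W(n)`'s growth with `n` is visible against it.

What the generator does **not** emulate: the cognitive feedback loop
itself (agents updating beliefs about rank — the kernel is fixed within
a phase), seasonal drift in activity, coalitions, site fidelity, and
observation effort that varies across days. Passing tests on this
generator show the *measurement pipeline* recovers planted structure of
the study's shape and size; they do not validate behavioral conclusions
about real birds.

Scan samples and morphometrics are generated with tunable coupling to
rank (proximity coupling in [0, 1]; trait-rank correlation in [-1, 1])
at plausible monk-parakeet trait scales.

## Validation runs and problem sizes

`rankloop.validation` packages the study-scale checks used by both the
test suite and `scripts/acceptance.py`; sizes were chosen so the whole
suite runs in a few minutes on one core:

- **Oracle agreement**: 50 random matrices, `N <= 7`, `n <= 5`, DFS vs
  naive enumeration, both T baselines (tolerance 1e-12).
- **Null validity**: synthetic 10-bird hierarchy, 200 samples;
  ensemble-mean EC within 0.01 (max norm) of the target and row totals
  exact — the null model's own two constraints.
- **Structured recovery**: default structured generator (focus 3, N=20,
  ~1200 events, no warm-up), 200 nulls; above-null ratio at
  `Delta in [1,5]`, empirical p, latent-rank recovery.
- **Unstructured coverage**: 50 rank-blind streams, 100 nulls each,
  chains to `n = 3`; pooled fraction of pointwise statistics inside
  their own null 2-sigma bands, with per-family breakdown (see the
  structural-liberality note above for why the W/T families run low).
- **Signature recovery**: three replicate strong-avoidance groups at
  4800 events each, 40 nulls, chains to `n = 5`, statistics averaged
  across groups. The higher event density is deliberate: the
  `W(3)`-versus-null contrast is a few tenths of a rank, and at ~1200
  events the score-estimation noise that the null absorbs as target
  preference (above) masks it; the noise-free expected matrices show the
  crossing cleanly, and at 4800 events per group it is recovered
  robustly. The preference-inversion signature (`T(2) > 0`,
  `T(n >= 3) < 0`) is robust at ordinary stream sizes.
- **Worked examples**: the deterministic protocol checks (a 6-attack
  burst in 10 s retains exactly 1 win; a 24-day log splits into 4
  quarters; dropping one of 19 birds leaves a maximum rank difference
  of 17).

## Known limitations

- The null model's W/T liberality under truly unstructured data (above)
  means chain-statistic p-values against this null should be read as
  evidence of structure *given* the estimated scores, not as calibrated
  tests of the no-structure hypothesis.
- EC rank uncertainty is largest at the top of strong hierarchies;
  bootstrap rank summaries should accompany any claim about specific
  top positions.
- `T(n)` for `n > 2` depends on the baseline generalization; both
  implemented variants are reported with results, and they agree at
  `n = 2` by construction.
- The generator's kernel is stationary within a phase; it cannot produce
  gradual structural emergence inside a quarter.
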
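# Methods

## The algorithm

`blockssa` simulates the chemical master equation (CME) of a well-stirred
reaction system exactly, one reaction event at a time.  Given species
counts `[s_i]` and mass-action channels `r_l` with stochastic rate
constants `k_l`, the propensities are

* Type 1 (unimolecular): `a_l = k_l [s_i]`
* Type 2 (bimolecular, distinct): `a_l = k_l [s_i][s_j]`
* Type 3 (dimerization): `a_l = k_l [s_i]([s_i] - 1) / 2`

One step draws two uniforms `z_1, z_2` in `(0, 1]`: the next reaction is
the first index whose cumulative propensity reaches `z_1 · a_R`
(`a_R = Σ a_l`), and the waiting time is `Δt = ln(1/z_2) / a_R`.  Every
engine in the package consumes exactly these two draws per step, in this
order, so different engines given the same seed walk through the same
event sequence — cross-implementation checks become exact sequence
comparisons instead of distributional ones.

### Blocked selection

The propensity vector is partitioned into `p` blocks of `b` entries (`b` a
multiple of the 128-wide chunk), and the *cumulative* block sums
`B_0 ≤ … ≤ B_{p-1} = a_R` are maintained incrementally.  Selection is a
three-level elimination: first the block whose cumulative sum reaches the
target, then the 128-wide chunk inside it, then the entry inside the
chunk.  The hardware primitives of the original design (warp ballot /
find-first-set, lane-strided reductions) are realized by their algorithmic
contract — "first index at which a predicate over a segment holds".

A deliberate numerical choice makes the three-level search *bit-for-bit*
equal to a sequential linear scan whenever the block sums are fresh: the
within-block running sum is seeded with the cumulative sum of all
preceding blocks and every predicate compares against the original target
in that continued frame.  Subtracting block bases to form residual targets
would re-round near chunk boundaries and occasionally shift the selected
index by one; seeding avoids the subtraction entirely.

### Incremental updates

Firing reaction `f` changes at most four species (net deltas in
{−2, −1, +1, +2}, stored both as a packed 29-bit-index/3-bit-delta table
and as an unpacked view the kernels use).  Only the dependents of `f` —
reactions consuming a changed species, looked up in a block-sorted
dependency graph with per-block end offsets — have their propensities
recomputed.  The propensity changes are summed per block (`δ_i`),
prefix-summed, and added to the cumulative block sums, so the update costs
O(#dependents + p) instead of O(M).  Two update paths exist (a per-block
loop for sparse coupling, a scatter-add for dense coupling, chosen by mean
dependents per block against `dense_update_threshold = 32`); both add the
same numbers in the same order and are bitwise identical.

### Drift control

Incremental block sums accumulate rounding error.  Defaults: an
unconditional from-scratch rebuild every `refresh_interval = 10^4`
firings, plus a drift check every 1024 firings against `rel_tol = 1e-9`
on `a_R`.  Measured drift after 10^4 unrefreshed firings on the random
benchmark network is ~10^-14 relative — the 1e-8 conservation bound is
enforced with orders of magnitude to spare.  If a stale block sum ever
makes the within-block search fail, the engine refreshes and reselects.

Because the three engines obtain `a_R` by different summation orders
(fresh sequential scan vs incremental scalar vs incremental block sums),
their waiting times agree to ~10^-13 relative, not bitwise; reaction
indices agree exactly.

## Recording on the time grid

Realizations are recorded on a uniform grid (`record_dt = 0.01` time
units by default).  Two grid estimators are provided:

* `interpolation="linear"` — blend the two event states bracketing the
  grid time, the estimator used for cross-method residual comparisons.
* `interpolation="hold"` — the exact piecewise-constant state in force at
  the grid time.

The linear blend is *not* an unbiased estimator of the state: for a pure
death process it sits low by about half a stoichiometric jump (≈0.5
molecules) at every grid point, because the true path is flat between
events while the blend slopes toward the next one.  This offset is
identical for any exact engine, so it cancels in engine-vs-engine
residuals; comparisons against closed-form means must use `"hold"`.  The
analytic-limit test (death process `A → ∅`, `k = 1`, 1000 molecules, 2000
realizations) checks the ensemble mean against `1000·e^{-t}` within 3
Monte-Carlo standard errors at every grid point, using `"hold"`.

## Benchmark model families

All families default to the benchmark study conditions: every rate
constant 1, every initial count 1.

* **Cyclic chain** (`cyclic_chain(N)`): `s_i → s_{i+1 mod N}`, `M = N`,
  exactly 2 dependents per reaction — the weak-coupling extreme.
* **Colloidal aggregation** (`colloidal_aggregation(N)`): all
  aggregations `s_i + s_j → s_{i+j}` (`i ≤ j`, `i+j ≤ N`) plus their
  fragmentations.  Enumeration shows the *maximum* dependent count is
  `3N − 7`, attained by `s_1 + s_2 → s_3` (the consumers of `s_1`, `s_2`
  and `s_3` number `(N−1) + (N−2) + (N−4)` after removing duplicates) —
  the strong-coupling extreme.
* **Random consistent networks** (`random_network(N, M)`): the
  intermediate regime, with per-reaction dependent counts confined to a
  window (default 8–16).

### Random-network construction

Consistency is defined as closed species flow: every species any reaction
consumes is also produced.  The generator additionally guarantees the
dynamics cannot die out.  Construction (bimolecular mode, the default):

1. A reaction changes at most 4 species, so per-reaction dependent counts
   of ~`3g − 1` require a consumer degree of `g` per species; for the
   8–16 window, `g = 4`.  With `M` reactions supplying ~`2M` reactant
   slots, degree 4 forces an *active* subset of
   `n_active = (2M − n_dim)/(g+1)` species (≈100 of 256); the remaining
   species take part in no reaction and stay frozen at their initial
   count.
2. Every active species gets exactly one unimolecular branching channel
   `s_a → s_b + s_c`.  A lone molecule can therefore always branch:
   `a_R ≥ total molecule count ≥ 1` for all time, so a zero-propensity
   absorbing state is unreachable by construction.
3. The remaining degree budget is filled with bimolecular coalescences
   `s_a + s_b → s_c` (one per two active species, which balances
   branching growth against quadratic loss at a few molecules per active
   species), conversions `s_a + s_b → s_c + s_d`, and ~5% dimerizations
   `2s_a → s_c + s_d`.
4. Product slots cover every active species at least once (closed flow),
   then fill uniformly; a local repair pass reassigns products of any
   reaction whose dependent count leaves the window.

The result is reproducible from its seed and settles into a
quasi-stationary state around 4–6 molecules per active species.  A
chain-like mode (unimolecular random cycle, exactly 2 dependents) covers
low dependency windows.

What the generator does *not* emulate: real biochemical stoichiometries
(conserved moieties, enzymes), heavy-tailed rate constants (all `k = 1`
here, so no channel dominates), or species counts large enough for the
deterministic limit.  Passing the accuracy protocol on these networks
shows the two engines sample the same CME on strongly coupled low-count
systems; it says nothing about stiff or multiscale kinetics.

## Ensemble protocol and problem sizes

The accuracy verification compares the blocked engine against the
reference Optimized Direct Method on a random consistent network with 256
species × 256 reactions: 2,000 independent realizations per engine (this
package's desk-scale rendition of the original 1024×1024 / 10,000-run
protocol), `t_final = 2.0` (long enough to cover the relaxation of the
unit-count initial condition toward quasi-stationarity), grid spacing
0.01, linear-blend recording of all species.  The statistic is the
maximum percentage residual `100·|mean_blocked − mean_odm|/mean_odm` over
every species and grid point with reference mean ≥ 0.5 molecules.

Realization `i` draws from the counter-derived stream
`SeedSequence(base_seed, spawn_key=(i,))`, so ensemble sums are exact
regardless of execution order or batching, and summaries over disjoint
index ranges merge by the weighted-mean identity.  The two engines use
*independent* base seeds — the residual therefore contains the full
two-sample Monte-Carlo error; `EnsembleSummary.sem` reports the
per-point standard error so the residual magnitude can be judged against
the noise floor.

The pre-simulation reordering of the reference ODM counts propensity
recomputations per reaction and count updates per species over 10^4
ODM steps of a single fixed-seed realization, then stably sorts both
arrays by descending access count (ties keep their original order).  The
ordering shortens linear scans on skewed models; it is off by default in
cross-engine comparisons because reordering the scan changes which
physical reaction a given `z_1` selects.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `block_size` | smallest multiple of 128 with ≤ 25 blocks | propensities per block |
| `chunk_size` | 128 | second-level search granularity |
| `lane_width` | 32 | reduction lane geometry (a no-op serially) |
| `refresh_interval` | 10^4 firings | unconditional block-sum rebuild |
| `rel_tol` | 1e-9 | drift bound on `a_R` (checked every 1024 firings) |
| `dense_update_threshold` | 32 | mean dependents/block switching update paths |
| `record_dt` | 0.01 time units | recording grid spacing |
| residual floor | 0.5 molecules | minimum reference mean for a residual |

The block-count trade-off is observable in counted work rather than
wall-clock: per firing, selection touches ~`b = M/p` elements inside the
chosen block while the update touches `#dependents + p`; sweeping `p`
with a fixed firing sequence shows selection work strictly falling and
update work strictly rising (the `benchmark` subcommand).

## Degenerate inputs and tie-breaks

Selection uses `≥` throughout, so a target landing exactly on a prefix
sum resolves to the lower index, and zero-propensity runs are never
selected (their prefix sums are exactly flat).  `z = 0` draws are
excluded by mapping numpy's `[0,1)` uniforms to `(0,1]`.  A network with
`a_R = 0` before `t_final` holds its final state on the remaining grid.
Firing a reaction that would drive a count negative, or producing a
negative propensity, raises an internal-consistency error — these signal
implementation bugs, not user errors, and counts are checked on every
firing.  Catalytic species (net zero change) are rejected at model
construction: the packed stoichiometry has no encoding for a zero delta.

## Known limitations

* One realization runs serially; the package parallelizes over
  realizations conceptually (counter-derived streams) but executes them
  in-process.  Wall-clock speed-ups of the source design are out of
  scope; work counters stand in for them.
* Mass-action kinetics only, at most 2 reactants and 2 products.
* The dependency graph is reaction-reaction and denormalized; memory
  grows with coupling (the colloidal family is quadratic in `N`).
* The max-residual statistic of the ensemble protocol is noise-bounded:
  with two *independently seeded* ensembles of `l` realizations each, a
  point with reference mean `μ` and per-trajectory spread `σ` carries
  residual noise of `100·sqrt(2/l)·σ/μ` percent, and the maximum over
  ~5·10^4 (species × grid) points sits 3–4 of those standard errors out.
  The per-point standard errors in `EnsembleSummary.sem` quantify this
  floor for any given run; a max residual within it carries no evidence
  of disagreement between engines (shared-seed runs, which remove the
  noise entirely, agree event for event).
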
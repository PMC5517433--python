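# Methods

## Problem setting

`patchboot` quantifies estimation uncertainty for functions of a network
degree distribution — the probabilities `f(k)` of observing a vertex of
degree `k`, and the mean degree `μ(G)` — when only a single realization of
the network is observable, possibly only partially. The observed graph
`G_n` (undirected, simple, no self-loops) is treated as one realization of a
hypothetical population network `G` whose degree distribution
`F = {f(k), k ≥ 0}` is the inferential target. The working assumptions are
the standard ones for this setting: involution invariance (the network looks
probabilistically the same from any randomly chosen vertex — the network
analogue of stationarity that licenses resampling of local neighbourhoods),
and realization convergence (`N_k/n → f(k)` as `n` grows). Nothing is
assumed about the parametric form of `F`.

Because only one realization exists, classical i.i.d. bootstrap does not
apply. The package adapts the blocking argument of time-series and spatial
bootstrap: local neighbourhoods (patches) play the role of blocks, and
resampling happens within patches. Patches may overlap, as with overlapping
time-series blocks.

## Sampling: labeled snowball with multiple inclusions (LSMI)

A patch is grown around each of `m` uniformly sampled seed vertices for `d`
waves. Within a patch no edge is traced twice: wave `j+1` explores the
previously untraced edges incident to the vertices recorded at wave `j`. A
new vertex reached through `r` distinct untraced edges within a wave is
recorded `r` times (multiple inclusions); a vertex already recorded at an
earlier wave of the same patch is never re-recorded, although the edge
reaching it is still marked as traced. Patches from different seeds are
grown independently, so one seed may appear as a non-seed inside another
seed's patch, and the same vertex may be recorded in several patches. Every
recorded vertex stores its full degree in the input graph; this presumes the
graph is observable up to `2d − 1` waves around any seed, which holds
trivially in simulations and must be guaranteed by the data supplier for
partially observed networks.

The multiplicity rule ("one record per distinct untraced edge into the new
wave, none for already-recorded vertices") is a reading of a procedure that
is described verbally in the literature; it is isolated in one function
(`lsmi._grow_patch`) and checked exhaustively against an independent
brute-force edge-ledger enumerator on all connected graphs with at most six
vertices, every seed, every depth up to three.

Seed order is retained, and patches store waves separately, so one maximal
LSMI with `m_l` seeds and `d` waves yields every nested sub-combination
`(m_i ≤ m_l, w ≤ d)` as a pure view — the efficiency device that makes
cross-validation cheap (exactly one LSMI per selection, audited by a test).

## Resampling and estimators

Each bootstrap replicate redraws, with replacement, `m` seed degrees
(uniformly) and `N` non-seed degree records, where `m` and `N` are the
observed counts of the patch-set view — the replicate's information volume
is fixed. A non-seed is reached along an edge, so its inclusion probability
is proportional to its degree; non-seed records are therefore resampled with
probability proportional to `1/degree`, a Horvitz–Thompson-type correction.
(`weights="uniform"` disables the correction; the ablation test shows the
uncorrected pool overestimates the mean degree, as size-biased sampling
must.)

From the resampled multisets `{v_s*}` (seeds) and `{v_ns*}` (non-seeds):

    f*(k) = ( |{v_s*(k)}| + (1 − p0*)·|{v_ns*(k)}| ) / ( |{v_s*}| + |{v_ns*}| ),  k ≥ 1
    f*(0) = p0*   (proportion of zeros among resampled seeds)
    μ*    = Σ_k k·f*(k)
          = ( Σ seed degrees* + (1 − p0*)·Σ non-seed degrees* ) / ( |{v_s*}| + |{v_ns*}| )

Two algebraic identities pin the estimator down and are asserted to 1e-12 on
10^4 random multisets: `Σ_{k≥1} f*(k) = 1 − p0*` (the numerators telescope)
and `Σ_k k·f*(k) = μ*`. The second identity is what forces the μ* form
above: it is the only reading consistent with f*(k).

Confidence intervals are Efron percentile intervals: with `B` replicates and
level `1 − α`, the endpoints are the 1-based order statistics at ranks
`ceil(B·α/2)` and `ceil(B·(1−α/2))`. This rank rule is deliberately
bit-exact (documented, tested on fixed fixtures) because interval endpoints
feed the coverage benchmarks. `B < 2/α` triggers a warning, not an error.

## Choosing the patch size (cross-validation)

Patch size — the seed-wave combination `(m, w)` — is the method's tuning
parameter, with the classical block-bootstrap trade-off: seeds-only patches
give unbiased but wide intervals; deeper waves shrink the bootstrap spread
and add bias. The selection procedure:

1. grow one maximal LSMI (`m_l` seeds, `d` waves);
2. for each of the `J = l·d` combinations, bootstrap the nested view and
   form the percentile interval `BCI_j`;
3. draw `proxy_reps` independent uniform vertex samples of size
   `proxy_size`; each yields a cheap seeds-only point estimate of the
   statistic (sample mean of degrees, or sample proportion at `k`);
4. score each combination by its proxy coverage `c_j` = fraction of proxy
   estimates inside `BCI_j`, and choose `argmin_j |c_j − (1 − α)|`, breaking
   ties by smaller width, then fewer waves, then fewer seeds (sharper,
   cheaper, less biased).

Two design choices here were genuinely open and deserve explanation:

* **Selector statistic.** With the selection re-run per target statistic,
  the chosen interval is, by construction, one that covers ~95% of unbiased
  proxy estimates of that same statistic — an interval that almost surely
  contains the population value, which drives conditional coverage far above
  nominal (we measured ≈99.5% for `f(2)` on ztp(2) graphs). The package
  instead tunes the patch size **once per network on the mean degree** and
  reads every target's interval from the chosen combination — the
  one-combination-per-network usage seen in applied work with this method,
  where a single optimal patch serves all reported `f(k)`. This policy
  reproduces the published benchmark closely (see README) and is the default
  (`selector="mean"`); per-target selection remains available
  (`selector=None`).
* **Proxy configuration.** Proxy estimates are seeds-only (their
  unbiasedness is what makes them usable anchors) and are drawn fresh from
  the graph, not from the LSMI; one proxy set is shared by all combinations
  (variance-reducing). Defaults are 13 repetitions of 100 vertices, the
  configuration used in the collaboration-network application of the method;
  they are cheap (degrees only) and explicit parameters everywhere.

The whole policy sits behind the `selector` argument so alternative rules
can be swapped without touching sampling or bootstrap code.

## Synthetic networks

The generator realises a prescribed degree law as a simple graph in two
stages: the pairing (configuration) model matches degree stubs uniformly at
random, and degree-preserving double-edge swaps remove the resulting loops
and parallel edges (a defective edge is paired with a uniformly chosen
partner edge; a swap is accepted only if both replacement edges are new and
loop-free, so defects never increase). The output has exactly the sampled
degree sequence; graphicality is checked first (Erdős–Gallai, via networkx).
The swap budget is `100·|E|` attempts; exhaustion raises an error reporting
the remaining defects rather than returning a near-simple graph. Disconnected
outputs are accepted — the sparse benchmark regimes routinely produce
fragments, and patches handle them naturally.

Degree sequences are drawn i.i.d. from the model through an inverse-CDF
table truncated where the remaining tail mass falls below 1e-10. An odd
degree total is repaired by redrawing one uniformly chosen entry until the
total is even, which preserves the marginal law exactly (unlike adding a
stub to one vertex).

Two parametric laws drive the benchmarks, both supported on `k ≥ 1` (the
networks of interest have isolates removed, so `f(0) = 0`):

* zero-truncated Poisson, rate λ: `f(k) = e^{-λ} λ^k / (k!·(1 − e^{-λ}))`;
  benchmark rate λ = 2 (mean 2.3130).
* polylogarithmic, exponent λ and scale θ:
  `f(k) = k^{-λ} z^k / Li_λ(z)` with `z = e^{-1/θ}` — a power-law body with
  geometric cutoff. Benchmark parameters (0.1, 2) (heavy tail, mean 2.4225,
  the 2.42 reference value) and (2, 3) (lightest tail, mean 1.3731, the
  ultra-sparse regime). The scale convention `z = e^{-1/θ}` is validated by
  reproducing the 2.42 reference mean.

The polylogarithm `Li_s(z)` is evaluated by direct series with Kahan
compensated summation and a geometric tail bound below 1e-12; no
acceleration is needed for the benchmark arguments (`z ≤ e^{-1/3}`), and the
implementation is cross-checked against mpmath in the tests.

What the generator deliberately does not emulate: degree–degree correlations,
clustering/transitivity, community structure, and exact-uniform sampling of
simple graphs with the given sequence (the swap chain is standard practice
but is not a uniform sampler). Passing coverage tests on these graphs
therefore demonstrates calibration under near-tree-like, uncorrelated
sparse structure — the regime the benchmark study defines — not under
arbitrary real-network dependence.

## Competitor intervals

Both baselines draw `M` vertices by simple random sampling without
replacement (benchmark `M = 50`) and estimate `f̂(k)` as a sample proportion:

* NCI: `f̂ ± z_{α/2}·σ̂`, `σ̂² = ((n − M)/n)·f̂(1 − f̂)/(M − 1)` — note it
  consumes the true graph order `n`, an information advantage over the
  patchwork method; endpoints are not truncated to [0, 1], matching the
  formula as printed.
* QCI: Efron percentile interval of `B` with-replacement resamples of the
  `M` degrees. Its resampling distribution is exactly `Binomial(M, f̂)/M`,
  which the tests exploit as a closed-form oracle.

Both collapse on rare degrees: with `f(k) ≈ 0.008` and `M = 50`, the sample
usually contains no degree-`k` vertex and the interval degenerates to the
point {0}.

## Monte-Carlo harness and numerical choices

`run_experiment` repeats (generate graph → build intervals → record
hit/width) `mc_reps` times and reports coverage percent, its binomial
standard error, and mean width per (method, target). Truth is the
population model value (`f(k)` or mean from the law), not the realized
per-graph frequency — the estimand is a functional of the hypothetical
population network; a `truth="realization"` flag exists for sensitivity
checks. Repetition `r` uses the generator seeded with `[rng_seed, r]`, so
every repetition is individually replayable; a repetition that raises is
logged and skipped, and the run aborts if more than 5% fail.

Default benchmark conditions mirror the published study: graph orders
{2000, 3000, 5000, 10000}, seed grid {20, 30, 40, 50} with waves 1–5,
`B = 500` bootstrap replicates, `α = 0.05`, `M = 50` for the SRS baselines.
The published study uses 1000 Monte-Carlo repetitions per cell; the
acceptance script and tests run 200–400 repetitions (binomial SE on coverage
≈ 1.5–2 points), which keeps the full reproduction in the minutes range on
one CPU. These are the package's desk-scale defaults; every knob is an
explicit `ExperimentConfig` field.

Degenerate inputs are handled explicitly: a wave->0 view with zero non-seed
records warns and falls back to seeds-only resampling; an all-zero seed
multiset yields `f*(0) = 1`; `B = 1` produces a degenerate point interval;
empty bootstrap samples, non-graphical sequences, malformed edge-list lines
(reported with line numbers) and self-loops raise errors.

## Known limitations

* The LSMI multiplicity convention and the cross-validation selector are
  reconstructions of procedures whose original descriptions are informal;
  both are isolated behind single functions/arguments and validated against
  the published benchmark numbers rather than against a formal definition.
* Non-seed `1/k` reweighting corrects size bias exactly under
  configuration-model-like neighbour sampling; on graphs with strong
  degree assortativity the correction is only approximate.
* Directed and weighted networks, respondent-driven sampling designs, and
  simultaneous confidence bands over `k` are out of scope; intervals are
  percentile-type (no BCa or studentisation).
* For partially observed inputs the caller must ensure all edges within
  `2d − 1` waves of any seed are present in the edge list; the package
  cannot verify this.
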
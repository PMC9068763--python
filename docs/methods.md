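# Methods

## Model and assumptions

All routines assume a weakly stationary, zero-mean VAR(p) process
`Y_t = Σ_ℓ A_ℓ Y_{t−ℓ} + ε_t` with Gaussian white innovations of constant
covariance `Σ_ε`, observed on an even time grid, possibly in several
independent trials.  Means are removed per channel and per trial before
any fit (`demean`); regression rows never mix samples from two trials.
Unevenly sampled, missing-data, integrated/nonstationary and
exogenous-input settings are out of scope.

Residual covariances use the maximum-likelihood denominator `n` (the
stacked row count), not `n − d`: the search statistics are
determinant-ratio likelihood ratios, and the ML form keeps them exactly
monotone over nested supports.  Rank-deficient designs are a hard error
(`RankDeficiencyError`) rather than a pseudo-inverse fallback, so the
greedy search can never silently accept a collinear augmentation; the rank
check is a relative floor (1e-7) on the scaled Cholesky diagonal.

## The greedy search

Each target block starts from the trivial model `r_t = ε_t` and alternates
an entry scan (largest `det(Σ)/det(Σ⁺)` over all absent (source, lag)
blocks) with an exit scan (smallest `det(Σ⁻)/det(Σ)` over present blocks).
Ties are broken lexicographically by (lag, source index), which makes the
whole search deterministic.  A support level terminates when a full
entry+exit pass changes nothing; `p_entry` then grows by
`increment_factor` until it reaches `p_max`.  Within one level, revisiting
an earlier support (an entry/exit cycle) or exceeding `max_sweeps = 200`
changes also ends the level; the final answer never depends on where a
cycle was cut because the best recorded model is selected afterwards.

**Test statistics.**  For scalar target and regressor (`a = b = 1`) the
determinant ratio maps exactly onto `F = (ratio − 1)(n − m − 1)` with an
F(1, n − m − 1) null (m = columns of the smaller model).  For blocks a
Wilks-type large-sample χ² on `n·ln(ratio)` with `a·b` degrees of freedom
is used.

**Scan-size correction.**  The entry statistic is the *maximum* over the
scanned candidates, so its single-test p-value is not uniform under the
null; with q candidates per scan its null distribution is approximately
that of the minimum of q uniform p-values.  The entry gate therefore tests
the Šidák-corrected value `1 − (1 − p)^q` against `p_entry`
(`FitConfig.scan_correction`, on by default).  Without this correction the
search cannot terminate sensibly once candidates outnumber observations:
the expected maximal null F (≈ 2·ln q) then always beats any fixed
per-candidate threshold and entries continue until the exit tests saturate.
With it, the false-entry rate per equation is roughly constant in both k
and N.  The default family-wise schedule is `p_min = 1e-6`,
`p_max = 0.3`, factor 1.3; `p_max = 0.3` admits a fraction of a false
entry per equation before model selection, which reproduces the observed
spurious-coefficient rates of the benchmark below (a stricter `p_max`,
e.g. 0.01, is the right setting when exact support recovery matters more
than power, as in the end-to-end recovery test).  The exit level is
`p_exit = 2·p_entry` and is tested per member.

**Extended SBC.**  Every support change is recorded with
`n·ln det(Σ̂) + d·ln n + 2γ·d·ln q`, an EBIC-style penalty over the
candidate pool of `q = a·k·|T|` scalar slots, `γ = 0.5` by default.  The
returned model is the trace minimum, refit by OLS, so the endpoint of the
escalation schedule is largely immaterial.

**Fast scans.**  All scans run on precomputed Gram matrices: per support
state the engine keeps the Cholesky factor of `G_ss`, the coefficients and
the residual cross-product, and evaluates every single-block augmentation
through Schur complements in O(m·q) total (vectorised for atomic blocks);
deletions use the inverse-block identity
`Σ⁻ = Σ + β_d'(G⁻¹_dd)⁻¹β_d`.  Scan results depend only on the support and
are memoised, so the escalation levels where nothing changes are free.  A
plain refit path (`use_fast=False` in `entry_scan`/`exit_scan`) exists
solely as a cross-check; the two paths agree to rounding error and the
test-suite enforces 1e-8.

## Random models and simulation

`random_sparse_stable_var` draws the order uniformly from `order_range`,
places exactly `round(density·k²·p)` coefficients at uniformly random
(lag, row, col) slots, and samples magnitudes uniformly from [0.1, 1] with
random signs (the magnitude law is a package choice; any i.i.d. law with a
bounded-away-from-zero scale behaves similarly).  If the companion
spectral radius reaches 0.95 the lag-ℓ matrices are scaled by
`(0.95/r)^ℓ`, which moves every companion eigenvalue by exactly `0.95/r`
and preserves the sparsity pattern, so one pass lands on the cap.
Simulation uses Gaussian innovations (identity covariance by default, any
SPD matrix accepted) and discards `10·p` burn-in samples per trial.

The generator emulates the structural features that matter for support
recovery — sparsity level, lag range, stability margin, coefficient scale —
but not features of real recordings such as measurement noise on top of
the process, volume conduction / instantaneous mixing, nonstationarity, or
heavy-tailed innovations.  Passing recovery tests on these models
demonstrates correctness of the estimator under its own assumptions, not
robustness to those violations.

## Conditional Granger causality

The default time-domain value (`method="refit"`) is the equation-local
likelihood ratio: `Σ_full` comes from refitting the target equations on
their selected supports, `Σ_reduced` from the same refit with every lag of
the source removed and all other regressors retained.  A source absent
from the target's support yields F = 0 with no computation — with a sparse
model the full k×k CGC matrix therefore costs one refit per *selected*
(target, source) pair only.  χ² p-values use `n·F` with
df = (source lags removed) × (target block size).

`method="innovation"` is fully model-based: the conditioning subsystem's
marginal process is approximated by a dense Yule–Walker fit of order
`max(4p, 24)` to the model autocovariances (computed by the companion
doubling iteration), and F compares its innovation covariance with the
model's `Σ_ε` block.  The refit value upper-bounds the innovation value:
a restricted refit cannot exploit source-mediated information carried by
the full reduced past, and the two can differ noticeably when mediation is
strong.  The innovation value is the quantity whose Geweke spectral
decomposition exists.

**Spectral CGC.**  `spectral_cgc` uses the partitioned Geweke
construction: with `A_R(f)` the characteristic matrix of the Yule–Walker
reduced subsystem (embedded with an identity at the source), `H` and
`Σ_ε` from the full model, and `P` the block transformation that
decorrelates the target's innovations from the rest,

```
f_{j→i}(f) = ln [ Σ_R,ii / |Q_ii(f)|² Σ_ii ],   Q = A_R H P⁻¹.
```

The grid mean over a uniform one-sided grid on [0, fs/2) equals the
time-domain innovation value up to grid resolution, Yule–Walker truncation
and a Szegő-type minimum-phase residual; with 512 grid points and spectral
radius ≤ 0.9 the relative gap stays well under 1% on the systems in the
test-suite (5% is asserted).  Truncation can push individual frequencies
mildly negative; values are clipped at zero.  At k = 2 the construction is
algebraically the classical bivariate Geweke measure with the numerator
spectrum factored through the reduced AR model, and the test-suite checks
that identity to 1e-6.

## Network measures

Distances are `1/weight`; characteristic path length averages over ordered
reachable pairs (NaN if none) and global efficiency averages `1/distance`
over all ordered pairs with unreachable pairs contributing zero.
Clustering and transitivity follow the cube-root triangle convention for
weighted digraphs, with weights normalised by the graph maximum.
Assortativity is the Pearson correlation over directed edges of the chosen
(in/out) endpoint strengths, each edge counted once.  Closeness uses the
reachable-fraction-scaled (Wasserman–Faust) form; the "total" variant runs
on the symmetrised weight matrix.  Eigenvector centralities are Perron
vectors of `W` (out) and `Wᵀ` (in) by power iteration (tolerance 1e-10,
cap 1e4).  Subgraph centrality is `diag(expm(A))` of the binary directed
pattern.  Participation uses a community partition argument and is zero
under the default single community.  Flow paths of node v count ordered
neighbour pairs (i, j) with i→v→j; the flow coefficient divides by
nb(nb−1) over the union neighbourhood.  Coreness is the k-core level of
the union undirected pattern (complete digraph ⇒ k−1).  Where several
directed/weighted variants circulate, the one implemented is stated here
and cross-checked against networkx or brute-force enumeration in the
tests.

## Recovery benchmark

Error measures: unpredicted% = 100·|true∖fit|/|true| (false negatives);
spurious per 100 = 100·|fit∖true|/|true|; order error = mean over
equations of |max fitted lag − max true lag|; coefficient correlation =
Pearson correlation of true vs fitted values over the union support
(absent = 0); normalized RMSE = ‖fit−true‖₂/‖true‖₂ over the correctly
recovered set; normalized bias = mean(fit−true) scaled by the rms of the
true nonzeros; relative spurious weight = ‖spurious‖₂/‖true nonzeros‖₂.

The benchmark draws density uniformly per model from size-specific ranges
(1.2–2.4% at k = 35, 0.4–0.9% at k = 100, 0.13–0.25% at k = 300,
0.08–0.18% at k = 500), orders uniform on 5–8, and passes the search a lag
cutoff two above the true order.  The packaged problem sizes — 5
replicates over N ∈ {150, 250, 350, 450} at k = 35, 3 replicates over
{150, 300, 450} at k = 100, and a single k = 300, N = 250 run as the
desk-scale analogue of a very-high-dimensional fit — keep the whole
acceptance script at a few minutes on one core while leaving every
qualitative conclusion (spurious rate roughly constant in N, false
negatives falling with N, coefficient correlation above 0.95 when
variables far outnumber time points) visible.

## Known limitations

* Support recovery, not inference on coefficients: no confidence
  intervals are produced, and post-selection p-values are not corrected.
* The refit-based CGC is a fast approximation whose value exceeds the
  innovation-based one under strong mediation; spectral decompositions
  refer to the latter.
* The χ² null for GC p-values is asymptotic; at short data lengths it is
  visibly anti-conservative below n ≈ 200.
* Equation-wise independent fitting ignores cross-equation error
  correlation during selection (it is reported in `Σ_ε` afterwards).
* Genuinely dense systems violate the sparsity premise; the search is not
  designed for them.
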
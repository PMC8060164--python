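# Methods

This note records the models implemented in `ndteflow`, the numerical and
design choices that were genuinely open, and what the synthetic test
conditions do and do not establish.

## Flow estimation

**Embedding.** For an ordered pair (source *X*, target *Y*) both series are
z-scored and embedded with a past window of `T` samples and a one-step
horizon.  The default `T = 10` is the first-minimum-of-the-autocorrelation
heuristic evaluated on narrowband haemodynamic-like signals;
`estimate_window` re-derives it from data (minima are found per region per
subject and averaged — averaging the ACFs first and then locating the
minimum is a defensible alternative that typically agrees within one lag).
Past-block columns are ordered most-recent-first; any consistent order gives
identical determinant-based entropies, the order is fixed only so tests are
reproducible.

**Gaussian entropies.** Every term is `(d/2)ln(2πe) + (1/2)ln det Σ` with Σ
a sample covariance (`1/(rows−1)`), evaluated by `slogdet`.  No shrinkage is
applied by default; if a log-determinant fails, a single ridge of
`1e-8·trace/d` is tried with a warning, then the offending block is named in
a `SingularCovarianceError`.  All five entropies needed by the decomposition
are read off one `(2T+1)`-dimensional covariance, which makes the chain rule
`I(Y⁺;X,Y) = I(Y⁺;Y) + I(Y⁺;X|Y)` an exact algebraic identity of the
implementation — it is nevertheless asserted to 1e-10 on every call.

**Normalization caveat.** `F_XY = I(Y⁺;X|Y)/I(Y⁺;X,Y)` is a ratio whose
denominator is the target's total one-step predictability.  For a
memoryless target (white noise) the denominator's population value is zero
and the ratio is finite-sample noise that can sit anywhere in [0, 1].  The
measure is therefore meaningful only for targets with temporal structure;
all null calibrations in the tests use AR(1) or narrowband signals for this
reason, and `ndte_pair` raises `UndefinedFlowError` when the denominator is
not positive.  The flow matrix is oriented rows = targets, columns =
sources, so `G_in` is a row sum.

## Significance

Per subject and ordered pair, 100 circular-shift surrogates are drawn: both
series are rotated by independent offsets uniform on `[0.05n, 0.95n]`, and
the flow is recomputed.  The p-value is the upper-tail area of a
Gaussian-kernel density over the surrogate flows (Silverman bandwidth,
univariate: `sd·(3m/4)^(-1/5)`), evaluated in closed form as
`mean_s Φ̄((F_obs − F_s)/h)` and floored at 1e-6 (the floor and shift
fractions are configurable).  An empirical rank would be the obvious
alternative to the KDE tail; both are calibrated, the KDE just interpolates
between the discrete ranks.  Group pooling is Stouffer's
`S = Σ Φ⁻¹(p_i)`, left tail (`Φ(S/√m)`); p-values are clamped to
`[1e-15, 1−1e-15]` before the quantile transform.  BH-FDR runs jointly over
all `N(N−1)` ordered pairs at `q = 0.05` by default.  The group mean flow is
masked (non-significant entries zeroed) by default; the raw mean is always
retained alongside, and the FF-hierarchy GLM accepts either.  All surrogate
draws derive from one master seed through `SeedSequence` spawning per
subject and pair, so runs are bit-reproducible and parallelizable.

## Club detection

The club score of a subset is within-subset flow + Σ`G_in` − Σ`G_out`
(equivalently: within-flow − flow sent outside + flow received from
outside; both forms are implemented and asserted equal).  Detection seeds at
the top-`G_in` region, proposes members in descending `G_in`, and at each
size compares the candidate club against all single-member-replacement
clubs (exhaustively when there are ≤ 500, otherwise 1,000 Monte-Carlo
draws), stopping when the replacement p-value reaches `alpha`.

**Tie handling (mid-p).**  Exact score ties between the candidate and a
replacement club are counted as one half.  This is forced by two degenerate
limits: counting ties fully against the candidate, a club of exactly
interchangeable members can never be admitted (every member swap ties);
counting them in the candidate's favour, any club grows without bound
through interchangeable outsiders.  Mid-p is also exactly what a smoothed
(kernel) surrogate-score distribution yields.  A consequence worth knowing:
for a perfectly homogeneous planted club of size *c* in an *N*-region
matrix, the admission p-value at proposal size *l* has a discrete floor of
`(c−l)/(2(N−l))`, so exact recovery of a zero-jitter club needs `alpha`
above that floor (e.g. club 3 in 12 regions ⇒ floor 0.05 at the first
admission, tested at `alpha = 0.1`) — real, heterogeneous matrices have no
exact ties and are unaffected.  A second known property: because candidates
are selected by the same statistic the score rewards, the stopping rule
inherits a selection bias and can admit the best of many near-identical
outsiders on jittered backgrounds; the detector is therefore most reliable
where club contrast is strong, which is the regime it is designed for.

The GW is the set of regions present in at least `min_count` of the
condition FRICs (default: all).  The `approx_gw_top_gin` shortcut
(intersecting top-`G_in` sets) is provided for large parcellations.  The
anatomical rich club uses the standard weighted coefficient; the null
preserves the degree sequence exactly (double-edge swaps on the binary
topology, 10 per edge, weights reshuffled over edges; degree preservation
is asserted per draw).  Membership is reported at the largest `k` with
`Φ_norm > 1`, a documented convention since the qualitative rule ("for a
range of increasing k") does not pin a single set.

## FF hierarchy

The feedforward fraction of each unordered pair is regressed on `H_i − H_j`
through a logit link (binomial GLM, IRLS via statsmodels).  Pairs are
weighted by their total bidirectional flow — strong pairs carry more
evidence; an unweighted option exists.  Zero-total pairs are dropped with a
warning.  The model is identified up to an additive constant, so one
reference region (default: the last) is pinned at 0.

## Whole-brain model

Each region is a Stuart–Landau oscillator; `x_n` emulates the regional
signal.  For `a_n < 0` the node is a noisy focus, for `a_n > 0` a limit
cycle of radius `√a_n` at `ω_n/2π` Hz.  Coupling is diffusive,
`G Σ_p C_np (x_p(t−τ) − x_n)`, with the same form in `y` (the printed
source for the `y` equation has an inconsistent index in the coupling
difference; the symmetric reading is implemented).  Integration is
Euler–Maruyama (numba-jitted) with `dt = 0.072 s` (tr/10) and a ring-buffer
delay line (τ rounded to a multiple of dt); initial conditions are uniform
in `[−0.1, 0.1]²` and 100 s of burn-in are discarded.  Two discretization
facts matter for tests: Euler inflates the cycle radius by ≈ `dt·ω²/2`
(0.7% at `a = 0.25`, `f = 0.05 Hz`), and the spectral peak of a *strongly*
damped focus (|a| ≳ ω) genuinely sits below `ω/2π` because the ±ω
Lorentzians overlap — spectral-peak checks use the weakly damped point
`a = −0.02`.

**Validation protocol.**  Binary ground-truth graphs are simulated with
`a = −0.2`, `G = 0.13`, `β = 0.02`, 1,200 output points at tr = 0.72 s, 10
repetitions treated as subjects (T = 10, 100 surrogates).  The binary
adjacency enters the coupling as-is (an edge contributes coupling `G`); the
max-0.2 normalization is the convention for tractography-derived structural
matrices, under which a binary validation graph would produce no detectable
interaction at this scale.  The recovery benchmark uses the 5-node fan-in
graph because it is the topology whose pairwise ground truth is exact: the
source nodes are mutually independent, so any detected flow between them is
a true false positive.  In graphs with common drivers or two-step paths
(fan-out, chains), pairwise conditional transfer entropy is *genuinely*
nonzero on absent edges — measured here at a 0.2–0.3 apparent
false-positive rate on a 5-node fan-out — which is a property of the
measure, not an estimator error; group pooling makes these real indirect
flows significant.

## Generative coupling (GABIC) and lesioning

The fit maximizes the Pearson correlation between off-diagonal entries of
the target flow matrix and the flow matrix of a fresh simulation.
Parameter blocks are optimized sequentially (noise β_n, delay τ,
bifurcations a_n, then the directed coupling weights on the structural
support) with inertia-weight PSO (defaults: swarm 30, inertia 0.729,
cognitive = social = 1.49, 100 iterations per stage, bounds β ∈
[0.001, 0.1], τ ∈ [0, 5] s, a ∈ [−0.3, 0.3], coupling ∈ [0, 0.3]; one pass
through the stages, cycling optional).  Every objective evaluation inside a
fit uses one fixed simulation seed — common random numbers make the
objective deterministic, so the incumbent never regresses and swarm
comparisons are not drowned by simulation noise; the reported final
correlation is recomputed with an independent seed.  Surrogate testing is
skipped inside the optimization loop for speed (raw flows); the lesion
experiment runs the significance pipeline at a reduced 20 surrogates.

Self-recovery benchmarks run at 6 nodes with 3,000-point evaluations (the
test–retest ceiling of the raw objective is ≈ 0.84 at 1,200 points and
≈ 0.92 at 3,000, so the longer runs keep the ceiling clear of the 0.8
recovery threshold) and optimize the coupling stage, where the perturbation
lives.  Lesioning zeroes all coupling into and out of the lesioned regions,
keeping matrix dimensions comparable; the experiment draws size-matched
lesion sets from club members, from random non-members, and from
non-members in the top half of incoming flow, and compares the
fit-correlation and club-retention distributions with Wilcoxon rank-sum
tests (median differences with bootstrap 95% intervals).

## Synthetic data: what it does and does not show

The generators produce exactly the structures the methods are designed to
detect — linear channels with known analytic transfer entropy, independent
AR(1) nulls with unit variance, binary directed graphs, planted clubs and
hierarchies, planted-hub oscillator networks — all bit-reproducible from a
seed.  They deliberately lack the features that make empirical imaging data
hard: spatial autocorrelation, shared physiological confounds, subject
heterogeneity, measurement noise with structure, and indirect anatomical
pathways.  Passing tests therefore establish estimator correctness and
calibration under the stated models, not performance on empirical
recordings; in particular the indirect-flow property discussed under the
validation protocol means recovered edges on real data are directed
*information* flows, not anatomical connections.

## Problem sizes

Test and acceptance runs use 5–12 regions, 1,200–3,000 time points, 10–20
repetitions, 100 surrogates (20 inside lesion loops), 300–1,000 null pairs,
and PSO swarms of 12 × 20 iterations — sizes at which every quantity is
measurable with comfortable margins on a single CPU.
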
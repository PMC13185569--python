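# Methods

## The model

`glvcom` models a defined community of gut bacteria with a generalized
Lotka-Volterra (gLV) system in which each species grows logistically and the
other species modulate both its maximum growth rate and its carrying
capacity linearly:

    dX_i/dt = X_i g_i max(10^-3, 1 + Σ_{j≠i} a_ij X_j)
                    (1 − X_i / clamp(1 + Σ_{j≠i} b_ij X_j))

with `clamp(v) = min(max(10^-20, v), 2)`. Densities `X_i` are normalized by
each species' own fresh-medium carrying capacity `N_i`, so every monoculture
equilibrates at `X_i = 1`. This is the only unit convention under which
`b_ij = N_ij/N_i − 1` reproduces the conditioned-media capacity ratio when
the donor sits at its own capacity; absolute abundances are recovered as
`X_i N_i` and relative abundances by normalizing those.

The clamps have distinct ecological readings. The growth floor (`10^-3`)
keeps the per-capita growth factor positive: inhibition slows growth but a
spent medium does not reverse it. The capacity floor (`10^-20`) turns strong
inhibition (`1 + Σ b_ij X_j ≤ 0`) into collapse toward zero rather than a
sign error, and the capacity cap (`2`) bounds mutualistic runaway at twice
the monoculture capacity. Self-interaction terms are excluded (`a_ii = b_ii
= 0`): self-limitation is carried entirely by the logistic capacity term, and
species are never assayed in their own conditioned medium anyway.

Higher-order interactions, time-varying environments and demographic noise
are deliberately out of scope; pairwise environmentally mediated terms
carry the predictive content here.

## Interaction inference from conditioned-media assays

For acceptor `i` grown in medium conditioned by donor `j`, the assay yields
a maximum specific growth rate `g_ij` and final density `N_ij`; fresh-medium
monocultures yield `g_i`, `N_i`. The model coefficients are the ratios minus
one, `a_ij = g_ij/g_i − 1` and `b_ij = N_ij/N_i − 1`; the log-ratios
`ε = ln(N_ij/N_i)` (natural log; base only rescales heatmaps and never
enters the model) are carried for reporting. Ratio SDs are propagated by the
delta method assuming independent errors, which holds because each condition
is measured in separate wells.

A condition counts as *grown* when the (median-smoothed) final OD reaches at
least twice the inoculum (OD 0.05), with the call taken by majority vote
over replicates (ties fail). Failed conditions are carried as missing — never
imputed as neutral, which would fabricate biology. Two retention policies
restore a fully measurable matrix: dropping every acceptor with any missing
cell, or removing a minimum-size species set covering all missing cells
(ties broken by involvement count, then name). A species whose *monoculture*
fails is a hard error: nothing about it can be estimated.

## Growth-curve fitting

The maximum specific growth rate is the maximum over rolling windows
(default 5 points) of the slope of `ln(OD)` against time. A curve inoculated
at OD 0.05 with capacity near 1 starts at 5% of capacity, which depresses
the early log-slope by `(1 − X/K)` — about 6% at the maximum-slope window —
so on curves that have plateaued (final window slope < 10% of the maximum)
each window slope is divided by `1 − mean(OD)/K̂`, where `K̂` is the maximum
of the median-of-3 smoothed trace; windows with mean OD above `0.8 K̂` are
excluded from the corrected search because the correction degenerates on the
plateau. Non-saturating (still-exponential) traces are left uncorrected, so
a pure exponential is fit exactly. ODs below the detection floor (`0.001`)
are floored before the log transform, and windows that are mostly floored
are skipped. The final density estimate is `K̂` itself, robust to a noisy
final read or end-of-run decline. Lag-time estimation and alternative growth
models (Gompertz, Baranyi) are out of scope.

## Equilibria, stability and enumeration

Wherever no clamp is active, interior equilibria satisfy the linear system
`(I − B)X = 1` — fixed points depend only on the density interactions, not
on growth rates or `A`. Because the linear solution satisfies
`X_i = 1 + Σ b_ij X_j` exactly, a clamp is active precisely when some `X_i`
leaves `(10^-20, 2)`; in that case the equilibrium is recomputed by long
integration (500 h) from a uniform inoculum and marked `simulated`. Singular
systems are classified not-stable (a measure-zero degeneracy). Feasibility
requires all densities strictly positive (tolerance `10^-9`).

Stability is a double check: all eigenvalues of the numerical Jacobian at
the equilibrium must have real part `< −10^-9`, *and* integration from the
equilibrium perturbed by ±1% per species must return within 1% by 48 h. The
perturbation check guards against clamp-boundary equilibria where the
smooth-branch Jacobian is misleading. Community enumeration evaluates every
non-empty subset (`2^n − 1`; guarded above 20 species).

Note that a locally stable interior equilibrium need not be reachable from
a uniform inoculum: under bistable exclusion the dynamics settle on a
boundary attractor instead. Tests therefore verify the fixed-point property
by integrating *from* the equilibrium.

## Co-culture prediction and error propagation

Experimental co-cultures are mixed at equal CFU counts to a combined OD of
0.05, so predictions integrate from `x_i(0) = (0.05/k)/N_i` over the 24 h
experiment horizon and convert the final state to absolute-density
fractions. Prediction uncertainty is propagated by Monte Carlo: 100
parameter sets drawn entrywise-independently from normal distributions with
the measured SDs (growth rates and capacities redrawn while non-positive),
each integrated, and the per-species fraction mean and SD reported.
Prediction quality against measured fractions is summarized by RMSE and the
squared Pearson correlation (via `scipy.stats.linregress`), with one point
per species per community.

## Invasion protocol

The simulated protocol mirrors the experiment: residents sit at their model
equilibrium (the pellet is resuspended in fresh medium at unchanged cell
numbers, so no re-dilution), the invader enters at OD 0.05 — normalized
`0.05/N_inv` — and the system runs 48 h. A species persists iff its final
normalized density reaches the persistence threshold; by default one common
threshold equal to the invader inoculum (the per-species alternative is an
argument). Outcomes: augmentation (invader persists, no resident lost),
displacement (persists, ≥1 lost), resistance (fails, none lost), disruption
(fails, ≥1 lost). A separate experimental rule calls invasion when the
invader's relative abundance (absolute-density basis, as qPCR measures)
reaches 5% at 24 h.

A closed-form proxy — the invader's clamped capacity at the resident
equilibrium, `clamp(1 + Σ_j b_inv,j X̄_j)`, compared against the threshold —
agrees with full simulation on ≈98–99% of random trials and generates the
regime boundaries in the density-versus-interaction invasion map.

Known artifact of the common threshold: a resident whose equilibrium density
is already below the invader inoculum counts as "lost" even if the invader
never touches it, so a handful of disruption calls can appear where
resistance would be read off the trajectory.

## Synthetic-invader ensembles and predictor scoring

Synthetic invaders decorrelate traits by construction: growth rate and
capacity are resampled with replacement from the observed per-species
values, and every interaction entry from the pooled off-diagonal entries of
the corresponding matrix (empirical resampling, asserting no distributional
family). Each invader crosses every stable community; each trial records
Shannon diversity (nats, on absolute-density equilibrium fractions),
richness, total normalized density, and the three mean couplings
(resident→resident, resident→invader, invader→resident).

Property predictiveness is scored as the stratified 5-fold cross-validated
balanced accuracy of a univariate threshold classifier for success
(augmentation or displacement) versus failure, with mutual information as a
secondary score; ties break by property name. Regime frontiers report, per
bin of total resident density, the minimal resident→invader coupling at
which each success type occurred, with isotonic-regression monotone cleanups
alongside the raw values; empty bins stay missing.

## The synthetic-data generator

The generator emulates the study design: `n` fresh-medium monocultures plus
`n(n−1)` conditioned conditions, up to 9 replicates each, logistic curves
over 24 h sampled every 15 min from an OD-0.05 inoculum. Conditioned curves
use rate `g_i(1 + a_ij)` and capacity `N_i(1 + b_ij)`. OD noise is
multiplicative lognormal (OD is positive with roughly proportional scatter;
additive Gaussian can produce negative ODs) with CV 0.05 by default — a
convention, since replicate noise magnitude is a free choice. No-growth
pairs arise from a separate Bernoulli mechanism (or an explicit pair list),
consistent across replicates, rather than from extreme `b` values.

Default world conditions, chosen once: growth rates `U(0.5, 1.1) /h`
(doubling times ≈ 40–80 min, typical of gut anaerobes in rich medium),
capacities `U(0.6, 1.4)` OD. Density interactions come from a two-component
sign mixture — negatives `N(−0.4, 0.3)` truncated below zero and clipped at
−0.9 (total suppression is the no-growth mechanism's job), positives
half-normal — with a 20% positive fraction, so inhibition dominates but
facilitation occurs. Growth-rate interactions use half the mean and SD,
twice the positive fraction, clipped at −0.3: spent-media effects on growth
rate are milder and more often positive than on final density. Passing
`positive_fraction=None` draws plain normals instead, for sweeping the
interaction mean through positive values. "Measured" co-culture fractions
integrate the true dynamics and apply lognormal noise (CV 0.10, 3
replicates) to absolute abundances before renormalizing.

What the generator does *not* emulate: metabolite-level mechanism (no
cross-feeding chemistry), pH effects, plate-layout artifacts, lag phases,
and any correlation structure between a species' traits. Passing tests
therefore demonstrate that the pipeline recovers the truth of this model
family under realistic noise — not that real communities obey the model.

## Numerical choices

- Integration: `scipy.integrate.solve_ivp` (LSODA), `rtol 10^-8`,
  `atol 10^-10`; the capacity floor makes collapse extremely stiff.
- During integration the logistic bracket `(1 − X/K)` is bounded below at
  `−10^4`: with `K = 10^-20` the exact bracket reaches `−10^18` and forces
  hundreds of thousands of solver steps to resolve a collapse that is
  instantaneous on the hour scale either way. The bound preserves every
  fixed point, its sign structure and local stability; only the sub-second
  collapse transient is slowed to a still-negligible timescale (measured:
  identical 48 h endpoints, ~900× fewer steps).
- Non-negativity: the RHS is evaluated at `max(x, 0)`, sub-zero solver
  excursions are clipped in the output, and species below `10^-12` at the
  horizon are set to exact zero.
- Equilibration horizon for simulated fallbacks: 500 h.
- Parameter-recovery comparisons use 5% relative tolerance with a 0.01
  absolute resolution, since relative error is ill-posed for near-neutral
  interactions (and exactly zero diagonals).

## Problem sizes

The default test suite and the acceptance script run a 10-species,
9-replicate assay for inference checks; 5-species pools (50 seeds) for
equilibrium-oracle equivalence; a 7-species pool with ≈1,200
invader-community trials for invasion and trend checks; and an acceptance
study with minimal-cover retention, all pairwise plus 11 three/four-species
validation co-cultures, two contrasting invader surveys and a 20-invader
proxy-agreement ensemble. These sizes were chosen to exercise every code
path at full fidelity while keeping a complete run in minutes.

## Known limitations

- Under the capacity cap, invasion success saturates rather than declines
  as the shared interaction mean moves positive: stable all-mutualist
  communities exist (members pinned near the cap) and admit invaders drawn
  from the same distribution. A decline of success for strongly positive
  mean interactions is therefore not a property of this model family; the
  corresponding trend test documents the negative-side rise only as holding.
- The drop-acceptors retention policy can be severe when strong suppression
  is scattered across acceptors; minimal-cover retention keeps more species
  and matches how the study handled isolated no-growth conditions.
- Equilibria found by the simulated fallback inherit integration tolerance;
  slowly converging boundary states near 500 h may be classified
  conservatively (the stability double-check then rejects them).
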
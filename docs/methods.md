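# Methods

## Problem and pipeline

The package analyzes the topology of resting-state functional brain
networks in a two-group (case/control) design. Each subject contributes a
T × N table of parcellated ROI signals; the pipeline estimates an N × N
Pearson/Fisher-z connectivity matrix per subject, binarizes it across a
cost (density) sweep, computes segregation/integration metrics normalized
by degree-matched random networks, and compares groups with permutation
statistics. Defaults mirror a typical study design: 32 controls vs 30
cases, N = 246 regions, T = 170 volumes at TR = 2 s.

## Signal preparation

*Nuisance regression.* Per region, ordinary least-squares residuals after
projecting out K confound regressors plus an intercept (the classic
14-parameter set: six motion traces, their first temporal derivatives, and
two tissue signals). The design is checked for full column rank; collinear
columns are named in the error. Residual columns are exactly mean-zero.

*Band-pass filtering.* Zero-phase (forward–backward) application of a
2nd-order Butterworth band-pass, 0.01–0.08 Hz. The binding contract is the
measured frequency response, not the filter family: at TR = 2 s the
amplitude gain is ≈ 0.96 at 0.05 Hz (within the required [0.9, 1.1]
pass-band window) and < 0.01 one octave above the upper edge (required
≤ 0.1). Zero-phase filtering was chosen so that downstream correlation
estimates are not phase-distorted. Regression precedes filtering.

## Network construction

Edges are ranked by |z| (absolute Fisher-z correlation — strong negative
correlations can become edges; this is deliberate and documented). At cost
c the top E = round(c·N(N−1)/2) edges are kept (round half up; at
N = 246, c = 0.10 this is 3014 edges). Rank thresholding (edge count, not
a fixed z cut) equates densities across subjects, removing mean-correlation
differences between groups as a confound. Ties at the cut are broken by
lexicographic (i, j) order, deterministically, and logged. Because each
cost keeps a prefix of one fixed edge ordering, edge sets are nested across
the sweep. The diagonal is always excluded; any non-finite off-diagonal z
is a hard error. The default grid is the 31 costs 0.10, 0.11, …, 0.40
(endpoints included: metric curves are computed *at* both ends of the
stated range).

## Graph metrics

All metrics operate on validated undirected simple graphs (symmetric,
hollow, 0/1). Shortest paths are unweighted breadth-first distances
(`scipy.sparse.csgraph`); local efficiency runs per-node BFS in a compiled
(numba) kernel for speed, and both are checked against brute-force
Floyd–Warshall / exhaustive-triangle / neighbor-subgraph oracles and
against networkx in the tests.

Degenerate-input conventions:

- Nodes with degree < 2 contribute clustering 0, and C_p remains an N-term
  mean (keeping the 1/N prefactor of the definition exact).
- Fragmented graphs: L_p averages finite ordered pairs only and carries a
  disconnected-pair count; efficiencies use the 1/∞ = 0 convention. A graph
  with no connected pair is an error.
- mean_i E_nodal(i) = E_global holds identically and is asserted to 1e−12.

## Null models and small-worldness

Matched random networks are generated by Maslov–Sneppen double-edge swaps:
swap_factor × E attempted swaps (default swap_factor 10, a standard mixing
heuristic), rejecting self-loops and duplicate edges, preserving every
degree exactly. Saturated graphs (no valid swap) are returned unchanged
with a log message. The ensemble default is 100 members; ensemble member i
derives its RNG from SeedSequence([master_seed, i]), so parallel or
reordered execution cannot change results. λ in fragmented ensemble members
uses the same finite-pairs L_p convention as real networks (consistency
over convention-mixing). σ and the alternative symbol δ are one quantity
(γ/λ); the small-world flag defaults to γ > 1 and σ > 1, with 1.1
available as a stricter report threshold.

## Group statistics

- **AUC**: trapezoidal integral of each metric curve over the full grid;
  missing costs are an error, never interpolated.
- **Permutation test**: pooled-variance two-sample t; group labels
  reshuffled with group sizes preserved; two-sided
  p = (1 + #{|t_perm| ≥ |t_obs|})/(n_perm + 1) (add-one: valid under
  exchangeability, never exactly 0). Default 5000 permutations, α = 0.05
  for global and nodal tests.
- **Edge-wise tests** operate on pre-threshold Fisher-z values (t tests on
  binarized entries would be ill-posed). Primary edge threshold p < 0.005
  (parametric t); family-wise control by Bonferroni or NBS. The NBS
  component statistic is edge count (extent); sum-of-|t| intensity is
  available via config. Component-level p compares the observed statistic
  with the permutation distribution of the maximal null component.
- **Brain–behavior**: metric and behavior are residualized on covariates
  (age, education) plus intercept; the residual Pearson r is tested with
  t = r√(df/(1−r²)), df = n − K − 2.

## Synthetic cohort generator

Each subject's signal component is multivariate Gaussian with a
block-structured correlation matrix: regions are partitioned into
near-equal contiguous modules (remainder to the last module); within-module
correlation 0.35, between-module 0.05 by default. Iid Gaussian noise
(default sd 0.5, a realistic mid-range signal-to-noise choice) is added and
columns are z-scored, so realized correlations attenuate to
cov/(1 + noise_sd²) — a closed form the tests check. The factor model has
no temporal autocorrelation by default (an AR(1) knob exists but defaults
off): band-pass filtering makes residual autocorrelation irrelevant to
Pearson r in expectation, though it does reduce the effective number of
independent samples, which is why single-cohort behavioral correlations at
n = 12 are noisy (see the worked example).

Case-group (B) structure: within-module correlation is scaled by
(1 − clustering_deficit) and further by (1 − duration_effect × duration)
per subject, floored at the between-module level so modular ordering never
inverts. Implementing the duration link through covariance attenuation
(not post-hoc labeling) means the planted negative metric–duration
correlation is recoverable by the *real* pipeline. Covariates: ages
~ N(21, 1.1) and education ~ N(14.1, 0.55) in both groups (matched by
construction); case smoking duration is lognormal with median 4.5 y and
log-sd 0.45 (sd ≈ 2.4 y). Block equicorrelation matrices with
1 > within > between ≥ 0 are PSD by construction; eigenvalues in
[−1e−10, 0) would be clipped with a logged warning, anything lower is an
error.

What the generator does **not** emulate: scanner/motion artifacts, spatial
structure, hemodynamic autocorrelation, heavy-tailed noise, or realistic
anatomical module layout. Passing tests therefore demonstrate correctness
and calibration of the *analysis*, and recoverability of planted effects —
not claims about real smokers' brains.

## Problem sizes and numerical choices

Test and acceptance workloads use scaled-down study conditions chosen as
the package's own testbed sizes: the small-world screen runs 20 subjects ×
90 ROIs × 31 costs with 20-member null ensembles; effect-recovery runs use
12 + 12 subjects over 20 seeds with a planted deficit of 0.15 and
duration_effect 0.03/y; calibration loops use 500 (type-I) and 200 (NBS
FWER) null repetitions with 999/99 permutations. Floating-point equality
checks use 1e−12 for graph quantities and 1e−8..1e−10 for regression
residuals. All randomness flows from explicit seeds through
`numpy.random.SeedSequence` counter schemes; identical configs give
bit-identical outputs.

## Known limitations

- Binary networks only; no weighted variants, betweenness, modularity or
  rich-club metrics.
- The bundled 246-region atlas table is synthetic (structurally valid
  labels/coordinates for visualization export, no anatomical meaning).
- Permutation engines are exhaustive over random relabelings, not over the
  full permutation group; p-values carry Monte-Carlo error of order
  1/√n_perm.
- The NBS implementation calibrates the maximal component statistic only
  (no per-component step-down refinement).
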
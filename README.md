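# fcgraph

Graph-theory analysis of resting-state functional brain networks, built for
case/control studies of the kind used in addiction imaging: two groups of
subjects, each contributing a parcellated ROI time-series table, compared on
the topology of their cost-thresholded functional connectivity networks.

The package covers the whole chain:

1. **Signal preparation** — nuisance (confound) regression and zero-phase
   0.01–0.08 Hz band-pass filtering of ROI signals.
2. **Network construction** — all-pairs Pearson correlation, Fisher
   z-transform, and binarization at fixed *cost* (edge density) over the
   sweep 0.10 ≤ cost ≤ 0.40 in steps of 0.01, so every subject's graph has
   the same edge count at each threshold.
3. **Graph metrics** — clustering coefficient C_p, characteristic path
   length L_p, global/local efficiency E_global, E_local, and nodal
   efficiency E_nodal:

   C_p = (1/N) Σ_i E_i / (D_i(D_i−1)/2),
   L_p = (1/(N(N−1))) Σ_{i≠j} L_ij,
   E_global = (1/(N(N−1))) Σ_{i≠j} 1/L_ij,
   E_local = (1/N) Σ_i E_global(G_i),
   E_nodal(i) = (1/(N−1)) Σ_{j≠i} 1/L_ij.

4. **Null normalization** — Maslov–Sneppen degree-preserving rewiring gives
   matched random networks; γ = C_p/⟨C_p^rand⟩, λ = L_p/⟨L_p^rand⟩,
   σ = γ/λ. A network with γ > 1 and λ ≈ 1 (σ > 1) is small-world.
5. **Group statistics** — trapezoidal AUC over the cost sweep collapses each
   metric curve to one scalar per subject; two-sample permutation tests
   (pooled-variance t, label reshuffling, add-one p), per-region tests on
   E_nodal, edge-wise inference on Fisher-z values with Bonferroni or the
   network-based statistic (NBS), and covariate-adjusted partial
   correlations between network metrics and behavior.
6. **Synthetic cohorts** — because such imaging datasets are rarely public,
   a generator simulates two-group cohorts with a modular, small-world-
   generating correlation structure, a plantable deficit in within-module
   correlation for the case group, and a planted metric–duration
   association, so the full pipeline is testable end to end.

## Worked example

The numbered scripts under `analysis/` run a complete study on synthetic
data (bulk intermediates under `scratch/`, tables under `results/`):

```bash
python analysis/01_simulate_cohort.py   # 12 + 12 subjects, 90 ROIs
python analysis/02_preprocess.py        # confound regression + band-pass
python analysis/03_small_world_screen.py
python analysis/04_group_statistics.py
python analysis/05_export_visualization.py
```

Script 03 prints (seed 2024):

```
min sigma over subjects and costs: 1.1691
min gamma over subjects and costs: 1.1691
lambda range: 1.000 - 2.290
```

— every subject's network is small-world (σ > 1.1, γ > 1) at every cost in
the sweep. Script 04, on a cohort with a planted 15 % within-module
correlation deficit in the case group, prints:

```
global AUC group tests (case vs control):
        Cp: t= +3.681 p=0.0040 decreased *
        Lp: t= +2.758 p=0.0170 decreased *
   Eglobal: t= -2.750 p=0.0140 increased *
    Elocal: t= +4.146 p=0.0010 decreased *
...
  Cp AUC vs smoking duration: partial r=-0.066, p=0.8552
```

The planted clustering deficit is recovered as significantly lower C_p and
E_local AUC in the case group (positive t = control > case, direction
"decreased"). The duration association is sign-correct but weak at n = 12
after filtering; its systematic sign recovery is checked across 20 seeds in
the test suite.

A CLI wraps the same library (`fcgraph simulate|run|metrics|stats|export`);
see `fcgraph --help`.

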
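# plinet

Phase-lag-index functional brain networks from multichannel resting-state
EEG: connectivity estimation, sparsity-swept weighted graph topology, and
three-group statistics — with a synthetic phase-coupled cohort generator
for end-to-end validation against known ground truth.

## The problem

Resting-state EEG studies of psychosis compare functional connectivity
between healthy controls (HC), individuals at ultra-high risk for
psychosis (UHR) and first-episode schizophrenia patients (FES). Alpha-band
(8–13 Hz) phase coupling is a sensitive marker, but naive phase-synchrony
measures are inflated by volume conduction: one cortical source reaches
many scalp electrodes with essentially zero lag and masquerades as
connectivity. The **phase lag index** discards exactly that component.
For two channels with instantaneous phases φ_a(t), φ_b(t) (Hilbert
transform of the band-limited signal),

    PLI = | ⟨ sign( Δφ(t) ) ⟩ |,    Δφ wrapped to (−π, π],

computed within each 3-s epoch and averaged over the M = 50 epochs of a
3-min recording. PLI is 0 for zero-lag (and no) synchronisation —
sign(0) = 0 — and 1 when one channel consistently leads the other; only a
consistently *lagged* phase relation registers.

Per subject this yields an N×N adjacency (N = 128 electrodes). The matrix
is proportionally thresholded at sparsities 0.05–0.50 (step 0.05),
*keeping edge weights*, and weighted graph metrics are computed at every
sparsity: clustering coefficient Cp, characteristic path length Lp
(edge distance 1/w), global and local efficiency Eg/Eloc, strength
(weighted degree), assortativity, hierarchy and synchronizability, plus
small-world σ = (Cp/⟨Cp_rand⟩)/(Lp/⟨Lp_rand⟩) against 100
degree-preserving (Maslov–Sneppen) rewired surrogates. Each metric's
curve is summarised by its area under the sparsity curve (AUC), removing
the arbitrary choice of threshold. Group inference uses one-way ANOVA
with Bonferroni post-hoc t-tests, chi-squared tests for categorical
demographics, electrode-wise ANOVA maps (p < 0.001) grouped into
spatially connected ROIs, and Pearson correlations between degree AUC
and clinical scales (MCCB, GAF) with Bonferroni correction.

Because no patient data accompany the analysis, the package includes a
first-class **synthetic cohort generator**: channels are noisy Kuramoto
oscillators with group-dependent coupling gain (HC < FES < UHR), a fixed
non-zero coupling lag (so the coupling is visible to PLI), 1/f
background noise, an optional zero-lag common source (the
volume-conduction confound PLI must ignore), and clinical covariates
generated with negative dependence on coupling.

## Worked example

```python
import numpy as np
from plinet import (SyntheticCohortSpec, simulate_subject, segment,
                    isolate_band, instantaneous_phase, pli_matrix,
                    mean_global_pli, sparsity_sweep)

spec = SyntheticCohortSpec(group_sizes={"HC": 2, "UHR": 2, "FES": 2},
                           n_channels=16, duration=33.0, seed=3)
rec = simulate_subject(spec, subject_coupling=3.0, seed=3)
alpha = isolate_band(segment(rec, 3.0, 10), 8.0, 13.0, trim=0.075)
matrix = pli_matrix(instantaneous_phase(alpha))
print(round(mean_global_pli(matrix), 3))
profile = sparsity_sweep(matrix, n_random=20, seed=3)
print(round(profile.auc["Eg"], 4), round(float(np.mean(profile.degree_auc)), 4))
```

prints

```
0.411
0.1286 1.0006
```

— the subject's global PLI (mean of the upper-triangle adjacency), the
global-efficiency AUC over the sparsity grid, and the mean per-electrode
degree (strength) AUC. With coupling gain 3 the global PLI sits well
above the independent-channel floor (≈ 0.36 at these epoch sizes; finite
3-s epochs give PLI a positive null floor), and it is these quantities
whose group ordering the statistics stage compares. The scripts in
`examples/` walk through each capability: cohort simulation, PLI
estimation, the metric sweep, the statistical toolkit, and the full
pipeline (also available as the `plinet` command-line tool with
`simulate` / `validate` / `run` / `connectivity` / `network` / `stats`
subcommands).

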
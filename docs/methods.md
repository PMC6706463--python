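# Methods

This note documents the models, estimators, numerical choices and known
limitations of `plinet`. It is the place where design decisions that
were genuinely open are argued; the README gives the user-facing
overview.

## PLI estimation

**Estimator.** For two channels the phase lag index is the magnitude of
the time-averaged sign of the wrapped instantaneous-phase difference.
The phase comes from the analytic (Hilbert) signal of each band-limited
epoch. The average is taken **within each epoch** (over its 2850
samples), the magnitude of each per-epoch average is formed, and the
per-epoch magnitudes are averaged over the M epochs. Averaging the
*magnitudes* rather than the signed means matters: a lag whose sign is
stable within epochs but flips between epochs still yields a high PLI,
which is the behaviour of the standard estimator in the EEG literature.

**Conventions.** The phase difference is wrapped to (−π, π] before the
sign; sign(0) = 0 (three-valued sign), so identical signals — and any
strictly zero-lag common component — give PLI 0, not 1. The global PLI
of a subject is the mean of the strictly-upper-triangle entries of the
adjacency; including the N zero diagonal cells would only rescale every
subject by (N−1)/(N+1)-type factors and cannot change group
comparisons. Channels that are constant in any epoch have undefined
phase; they propagate as *missing* (NaN) rows/columns with an explicit
report, never as 0, because 0 is a meaningful PLI value.

**Finite-sample null floor.** PLI is positively biased at finite epoch
length: under independence the sign of the phase difference decorrelates
on the timescale τ on which the signals themselves decorrelate, so a
T-second epoch contains only ≈ T/τ independent sign observations and
E[PLI] ≈ √(2τ/(πT)) rather than 0. For an 8–13 Hz band (τ ≈ 0.2 s) and
2.85-s epochs this floor is ≈ 0.17 for fully independent band-limited
noise, and higher for signals with longer phase-coherence times. Only
the *estimator-level* null — independent phases drawn i.i.d. per sample
— approaches 0 (≈ 1/√(samples·M)). All group comparisons in this
package are therefore comparisons *above a common floor*; tests assert
orderings and floor-relative elevations, never that a realistic
signal-level null is numerically zero. The volume-conduction property
is likewise asserted as an invariance: adding a zero-lag common source
at gains up to 0.8 leaves the PLI distribution at its unmixed null,
while genuinely lagged coupling raises it.

## Synthetic cohort model

Channels are oscillators near the alpha centre frequency whose phases
follow a noisy, lag-carrying, degree-normalised Kuramoto system:

    dφ_i = [ ω_i + (K/k_i) Σ_j A_ij sin(φ_j − φ_i + δ_ij) ] dt + η dW_i

* **ω_i** — natural frequency, N(2π·10 Hz, (2π·jitter)²) with jitter
  0.1 Hz by default.
* **A** — coupling topology: all pairs within a montage region coupled,
  plus a sparse (2%) fraction of cross-region pairs; deterministic per
  cohort.
* **δ_ij = −δ_ji** — fixed non-zero pairwise lag (default π/4). The
  antisymmetric convention makes the pair's phase difference lock *at*
  δ_ij for any δ ∈ (0, π); with the symmetric (Sakaguchi) convention a
  lag of π/2 would cancel the attractive component entirely and no
  locking could occur at any gain. Zero lag is deliberately excluded:
  it is reserved for the volume-conduction confound, which is injected
  as a separate common source added with zero lag to every channel.
* **K/k_i** — the subject's coupling gain normalised by each node's
  partner count, so the per-pair attraction produced by a given K does
  not depend on the channel count or topology density; group gains
  (defaults HC 0.5, FES 2.0, UHR 3.0) are directly comparable between
  the 32-channel test profile and the 128-channel default.
* **η** — intrinsic phase diffusion, default 1.7 rad/√s, equivalent to
  a Lorentzian linewidth of ≈ 0.9 Hz. This is what makes the rhythm a
  *rhythm* rather than a pure tone; without it two uncoupled channels
  with nearly equal frequencies hold one phase-difference sign for
  entire epochs and the null PLI saturates near 0.7. The default was
  calibrated once against the estimator's null floor and the coupling
  response (gains 0.5/2/3 straddle the synchronisation transition) and
  is not revisited per experiment.

The output signal is an amplitude-modulated cosine of the oscillator
phase (slow sinusoidal envelope, depth 0.2, 0.05–0.2 Hz) plus 1/f-power
background noise made by spectral shaping of white noise, scaled to
`noise_sd` (default 0.5) of the oscillation RMS, plus `mixing_gain`
times a shared zero-lag source (an independent alpha-band oscillation
with its own 1/f component; default gain 0). Clinical covariates are
linear-Gaussian in the subject's gain K — MCCB-like: 46 − 3K ± 3;
GAF-like: 90 − 10K ± 5 — giving the negative coupling–functioning
relation the ROI correlation stage is meant to recover. Only the sign
and approximate magnitude of recovered correlations are ever asserted.

**Numerics.** Euler–Maruyama integration at 4 ms steps (phase advance
≈ 0.25 rad/step), linearly interpolated onto the 1 kHz sample grid;
verified against 1 ms integration (group-level PLI differences within
between-subject variability). Seeds derive hierarchically from the
cohort seed via `SeedSequence` spawn keys (topology, cohort draws, one
stream per subject), so any subject is reproducible in isolation and
identical spec + seed reproduces cohorts bit for bit.

**What the generator does not emulate.** Ocular/muscle artifacts,
non-stationary spectral drift, forward-model (lead-field) volume
conduction with distance-dependent mixing, heterogeneous per-channel
noise, and any true spatial autocorrelation of source activity. Passing
tests therefore demonstrate that the *analysis chain* recovers planted
phase-coupling structure through realistic narrowband noise — not that
it is robust to everything real EEG contains.

## Preprocessing

Zero-phase (forward–backward) order-4 Butterworth filters throughout;
zero-phase filtering is required because any one-pass filter delay would
bias the phase differences PLI is built on. The forward–backward pass
gives ≈ 48 dB attenuation one octave outside the band and a maximally
flat passband. Epochs are cut consecutively from the start of the
recording (3 s, 50 per subject by default), band-isolated per epoch, and
trimmed 75 ms per end. One caveat is documented rather than hidden: a
filter with ≥ 40 dB stopband across the 8→4 Hz lower transition
necessarily rings longer than 75 ms, so the trim reduces but does not
eliminate the epoch-edge transient (per-epoch output correlates > 0.99
with continuously filtered signal at the default trim; the residual is
common to all subjects and groups). An optional amplitude-threshold
epoch rejector stands in for the manual/ICA artifact screening used on
real recordings; synthetic inputs are artifact-free.

## Graph metrics

Thresholding retains the round(s·N(N−1)/2) largest-weight edges **with
their PLI weights**; ties at the cutoff break by ascending (i, j) index
so results are bit-reproducible. Weighted (not binary) graphs are a
deliberate choice: under binary proportional thresholding every
subject's mean degree at sparsity s is fixed by the edge count alone,
so a binary degree AUC could never differ between subjects — weighted
degree (strength) carries the subject differences the degree analysis
needs.

Path-based metrics use edge distance 1/w (shortest paths via Dijkstra).
Lp averages over *connected* ordered pairs; Eg averages 1/d over all
ordered pairs with disconnected pairs contributing 0 (both conventions
are stated here because the literature varies). Cp is the mean Onnela
weighted clustering (geometric mean of triangle weights, normalised by
the maximum weight). Eloc is the mean over nodes of the efficiency of
the neighbour-induced subgraph (nodes with < 2 neighbours contribute
0). Assortativity is the Pearson correlation of strengths across edge
endpoints (both orientations). Hierarchy is the exponent β of
C(k) ∝ k^(−β), least squares on log–log over nodes with k > 1 and
C > 0; with fewer than two usable nodes it is missing. Synchronizability
is λ₂/λ_max of the weighted graph Laplacian.

Small-world σ uses ensembles of degree-preserving double-edge-swap
(Maslov–Sneppen) surrogates: ≥ 10·|E| attempted swaps per member,
weights carried with the rewired edges, binary degree sequence preserved
exactly; 100 members by default (reducible for speed — ensemble-mean
standard errors at 20 members are already below the between-subject
spread). A graph admitting no valid swap (e.g. a triangle) yields an
ensemble of identical copies plus a warning, and σ = 1. σ is missing
when the ensemble clustering mean is 0 (graphs too sparse for
triangles); AUCs integrate over the finite grid points only and report
missing when fewer than two remain.

AUC is the trapezoid over the sparsity grid (exact for linear curves;
the grid is the method's own discretisation, so no finer quadrature is
meaningful).

## Statistics

Classical one-way ANOVA (between/within decomposition), two-sided
throughout. `anova_from_summary` reconstructs SS_between and SS_within
from per-group means, SDs and ns — the verification surface for
published tables; with inputs rounded to two decimals, recovered F
values agree with published ones to well under 1%. Chi-squared is the
Pearson statistic without Yates correction (the printed sex-ratio
statistic matches the uncorrected computation). Post-hoc tests are
equal-variance two-sample t-tests with Bonferroni adjustment over the
number of pairs (Welch available by flag). Electrode-wise ANOVA maps
are left uncorrected because ROI selection happens on raw p < 0.001 by
design; ROIs are the spatially connected components (montage adjacency)
of the significant set, named by majority region label. A fixed
reference ROI set (superior parietal 12/13/19/20/24; right temporal
96/97/98/101/102; occipital 68/69/73/74/82/88/89) ships with the
package so the ROI stage runs without re-deriving a montage adjacency.
Degree–scale correlations pool all subjects across groups and are
Bonferroni-adjusted over the (ROI × scale) test count; per-group
correlations are available by flag but carry no reference values.

## Test and acceptance problem sizes

The replicated end-to-end recovery experiments use 15 subjects per
group at 32 channels, 10 epochs of 3 s (33 s of simulated signal per
subject), with the sweep restricted to the degree map — the orderings
and correlations under test involve only mean PLI and strength AUC,
neither of which uses the random-network ensemble. The full metric set
including σ (20-member ensembles) is exercised on smaller cohorts. At
these sizes the planted effects are recovered in 20/20 seeded
replicates; the acceptance suite requires ≥ 90%.

## Known limitations

* The null floor means absolute PLI values are epoch-length- and
  bandwidth-dependent; only contrasts are interpretable.
* Hierarchy and assortativity are noisy on graphs below ~20 nodes; σ is
  undefined at sparsities without triangles (handled as missing).
* The EDF writer quantises to 16 bits over each channel's range; the
  float-exact npy+json container is the fidelity path, EDF the
  interoperability path.
* The montage is a schematic sunflower layout with position-derived
  regions, not a digitised electrode file; ROI definitions on real data
  should come from the recording system's montage.
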
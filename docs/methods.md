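# Methods

This note documents the models, conventions and design choices behind
`planconn`, in the order the pipeline runs them.

## Tower of London task model

The task is the classic 3-bead variant: posts of capacities (3, 2, 1),
beads R/G/B, one bead moved at a time and only from the top of a stack.
The admissible configurations number 36 (six occupancy patterns × 3!
bead orderings); the package enumerates them exhaustively and caches
all-pairs BFS distances, so `min_moves` is exact and O(1) per query.
Problem difficulty is the BFS distance (1–5 in the task); the state
graph's diameter is 8, so harder pairs exist but are not used. Problem
sets sample uniformly without replacement among the (start, goal) pairs
at each requested distance. Scoring is accuracy (%) over presented
trials and mean reaction time over correct trials only, either across
all levels or restricted to levels 4–5 (the post-hoc variant that avoids
ceiling effects on easy trials). RT pooling is across all correct trials
rather than per-level-then-averaged; both conventions are defensible and
the pooled one is the package default because it weighs levels by their
correct-trial counts.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes.
Defaults describe a 62-subject cohort, 192 volumes at TR = 1.8 s, and a
225-node parcellation (DMN 40, FPN 30, DAN 25, VAN 20, 110 unassigned)
of which 31 nodes contain fewer than 4 signal voxels in some subject, so
harmonization leaves 194 common nodes. A 60-node variant
(`CohortConfig.emulation_60`) keeps the four networks at sizes
14/12/10/10 plus 14 unassigned nodes for fast end-to-end runs.

**Signals.** Each named network k has a shared signal
`S_k = sqrt(b)·G + sqrt(1−b)·N_k`, where `G` and `N_k` are independent
Gaussian series band-passed to 0.06–0.12 Hz (4th-order Butterworth,
forward–backward) and `b = coupling_between` (default 0.3) sets
cross-network leakage. A node in network k is
`c·S_k + sqrt(1−c²)·ε` with private white noise ε and the subject's
coupling `c ~ Beta(2, 2)`; unassigned nodes are pure noise; columns are
standardized. Band-limited noise rather than sinusoids spreads coherence
realistically across the band. The Beta coupling distribution is a
modelling choice (nothing constrains inter-subject topology
variability); its wide spread makes the measured-efficiency readout of
coupling nearly noiseless when averaged over node pairs.

**Motion.** Six-parameter random walks whose step sizes split the
displacement budget evenly between rotations and translations; the trace
is rescaled (three fixed-point iterations) so its realized mean relative
RMS equals the drawn severity. Severities follow a lognormal matched to
mean 0.07 mm, SD 0.03 mm, clipped to 0.025–0.17 mm. Planted violators
get severity 0.30 mm (mean rule) or 25 injected 0.3 mm single-volume
jumps (spike rule, mean kept below 0.2 mm).

**Behavior.** Reaction time is linear in age (0.09 s/yr) and in the
standardized coupling (default standardized effect 0.22), with residual
SD 1.65 s; accuracy carries a weak negative age slope (−0.131 %-pt/yr,
residual SD 7). Trial-level responses are generated per difficulty level
with easy levels near ceiling and the deficit concentrated at levels
4–5; correct counts are rounded deterministically and correct-trial RTs
rescaled so the pooled mean equals the subject's target exactly, so the
planted RT effects survive trial simulation unattenuated. Residuals are
truncated at ±1.8 SD and targets winsorized at ±1.6 sample SD: the
generator guarantees that no non-planted subject crosses the |z| ≥ 2
behavioral exclusion bound, which is what makes planted-violator ground
truth exact. The cost is slightly thin behavioral tails; tests of the
exclusion logic do not depend on tail shape.

**What the generator does not emulate:** hemodynamic response shapes,
physiological (cardiac/respiratory) noise, spatial autocorrelation
within networks beyond the single shared component, non-stationary
coupling, or realistic motion–signal interaction (motion affects the QC
covariate but not the simulated signals). Passing tests therefore show
the pipeline recovers effects under its own generating assumptions, not
that those assumptions hold in scanner data.

## Wavelet coherence

FC is magnitude-squared wavelet coherence, band-averaged over
0.06–0.12 Hz and the entire scan. The transform is a complex Morlet CWT
(centre frequency ω₀ = 6 rad) on 12 log-spaced frequencies spanning
0.04–0.18 Hz, so the analysis band is interior to the grid; all
frequencies sit below Nyquist for TR = 1.8 s. Smoothing is mandatory —
unsmoothed magnitude coherence is identically 1 — and follows the
standard scale-dependent recipe: a Gaussian in time with σ equal to the
scale (applied spectrally on mirror-padded series, batched over all
pairs and scales) and a boxcar across ≈ 0.6 octaves of scale. The
cross- and auto-spectral surfaces are divided by scale before smoothing.
Cone-of-influence cells (within √2·scale of either scan edge) are
excluded from the band–time mean by default (`keep-all` is available for
short series). The stored FC value is the squared coherence, bounded in
[0, 1], phase-blind and invariant to rescaling of either series; a flag
exposes the unsquared value. With these windows the no-coupling null
level of the band mean is ≈ 0.35 (SD ≈ 0.045) at 192 volumes — a
consequence of finite smoothing bandwidth, frozen as a regression bound
in the tests, and the reason FC matrices should only be compared within
a fixed spec.

## Graph topology

All measures operate on the complete weighted coherence matrix; no
threshold is applied anywhere because any cutoff would be an unreported
free parameter. Shortest-path edge length is `1/w` (a `−log w`
alternative is exposed); global efficiency is the mean inverse shortest
path length over ordered pairs, with disconnected pairs contributing
zero (unreachable on complete matrices, relevant only under manual
sparsification). Weighted clustering is the Onnela geometric-mean form
on weights normalized by the maximum off-diagonal entry; it reduces to
the proportion-of-triangles definition on binary graphs, which the tests
verify against an independent implementation. Subnetwork metrics are
computed on the induced subgraph of each network's nodes — the
"within-network" reading; paths may not detour through out-of-network
nodes. Between-network FC is the plain mean over all cross-network node
pairs; within-network FC the mean over distinct pairs, diagonal
excluded.

## Quality control

"Frame-wise relative RMS" uses the rigid-body RMS formula over an 80 mm
sphere: for the relative transform `M = T_{i+1} T_i^{-1}`,
`RMS² = (R²/5)·tr(AᵀA) + tᵀt` with `A = M_rot − I`. The point-cloud test
oracle maps sampled sphere interiors through both transforms and agrees
to ~1%. Rotations are in radians, applied X·Y·Z, translations in mm.
Exclusion bounds follow the printed rules and their strictness: mean
relative RMS **>** 0.2 mm; **more than** 20 transitions above 0.25 mm;
behavioral |z| **≥** 2 (inclusive) computed once on the candidate pool
(single pass — no iterative re-exclusion, so removing flagged subjects
and re-running cannot cascade); interval **>** 21 days (21 admissible).
Harmonization drops nodes with < 4 signal voxels per subject and
intersects across subjects, order-preserving.

## Inference

Hierarchical OLS enters blocks in the fixed order age → network measure
→ motion (optionally sex or education as a sensitivity block); R² is
non-decreasing across the nested fits by construction and the final
model's coefficients are the headline outputs. Uncertainty comes from a
case-resampling bootstrap of whole rows (robust to heteroscedasticity;
default B = 2000, batched linear algebra) with BCa intervals: bias
z₀ = Φ⁻¹(fraction of replicates below the estimate; ties counted half),
acceleration from jackknife skewness, endpoints by linear-interpolation
quantiles. A replicate distribution entirely on one side of the estimate
would make z₀ infinite; it is clamped to the 1/(2B) quantile and flagged
in the result rather than hidden. P_bca is defined by interval
inversion — the smallest α on a 0.001-step grid at which the (1−α)
interval excludes zero — floored at 1/B (values at the floor are
flagged); the 95% CI excludes zero iff P_bca < 0.05 up to grid
resolution. More than 1% rank-deficient bootstrap designs aborts the
run, which in practice only triggers at very small n. The `auto`
correlation mode uses Shapiro–Wilk at α = 0.05 on each variable to
choose Pearson vs Spearman. FDR families are corrected separately per
outcome: the 8 subnetwork topology tests form one family and the 6
between-network FC tests another; within-DMN FC is reported uncorrected
as a follow-up quantity. Family composition is configurable since
reasonable alternatives exist.

## Pipeline and reproducibility

One YAML config describes a run; all randomness derives from a single
root seed through named substreams (cohort simulation, each bootstrap),
so stages can be re-run in isolation bit-identically and the whole
result tree is checksum-stable across re-runs. Outputs are TSV with JSON
sidecars and contain no timestamps. The `resume` flag skips the
simulation stage when its outputs exist.

## Problem sizes used in validation

The Monte Carlo studies run at deliberately scaled sizes chosen to keep
the whole validation quick on a single core while leaving the estimates
tight enough to be meaningful: BCa coverage with n = 30, B = 2000, 500
simulations; regression type-I error with 62-subject null cohorts,
B = 500, 500 simulations (the generator's coupling serves as the
topology measure — under the null the choice of readout is immaterial);
power with 62 subjects, 20 nodes (5 per network), full-length scans,
B = 199, 100 simulations of the complete measurement pipeline (the
measured-GE readout correlates ≈ 0.94 with planted coupling at this
size, so attenuation of the planted 0.4 effect is mild); FDR with 10
tests and 500 simulations. The end-to-end determinism check uses the
62-subject, 60-node emulation with B = 2000.

## Known limitations

* The coherence null level depends on the smoothing windows; absolute FC
  values are not comparable across different `WaveletSpec`s.
* BCa coverage for small n sits at the low end of its nominal band
  (~92–94% here), a known property of the method, and P_bca resolution
  is bounded by the α grid and by 1/B.
* Subnetwork efficiency on induced subgraphs ignores paths through the
  rest of the brain; this is a reading of "within-network topology", not
  the only one.
* The behavioral generator's winsorized tails make the |z| ≥ 2 exclusion
  rule exact by construction; cohorts with genuinely heavy-tailed
  behavior would exclude non-planted subjects too, which is the rule
  working as intended rather than a pipeline error.
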
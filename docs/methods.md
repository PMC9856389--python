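# Methods

## Pipeline model

The package treats a resting-state multichannel recording as a set of
band-limited oscillatory processes observed at N electrodes and summarises
inter-channel phase coupling per frequency band as an N × N functional
connectivity (FC) matrix, reduced to a maximum-weight spanning tree whose
topology is described by eight scalars and compared across groups.

### Preprocessing

Order of operations: broadband 0.5–45 Hz band-pass → common average
reference → epoch extraction → per-epoch band split.

* The broadband filter is a second-order Butterworth applied
  forward–backward (`sosfiltfilt`), so its effective magnitude response is
  the squared single-pass response and its phase response is identically
  zero. Zero-phase filtering is used everywhere because any phase
  distortion would bias the phase-difference statistics that everything
  downstream depends on.
* Epochs are consecutive, non-overlapping, exactly `epoch_len_s × fs`
  samples (4096 at 8 s, 512 Hz), taken from the start of the record; a
  window whose peak absolute amplitude exceeds `reject_uV` on any channel
  is skipped. This amplitude screen is a deliberately simple stand-in for
  expert artifact rejection; with clean synthetic data the default is no
  screening. If fewer than the requested number of clean windows exist the
  pipeline stops with an error naming how many were found.
* The band split uses linear-phase windowed-sinc (Hamming) FIR filters,
  applied by convolution with the integer group delay removed, so band
  outputs are zero-phase and length-preserving. The filter order is the
  smallest even number that both spans ≥ 3 cycles of the band's low edge
  and achieves roughly a 1 Hz Hamming transition width (3.3 fs / order),
  capped below a third of the epoch length. The transition-width term is
  what makes the 2-Hz-wide alpha sub-bands meaningful: with the 3-cycles
  rule alone the transition would be ≈ 9 Hz at 512 Hz and the "low alpha"
  output would contain mostly neighbouring-band energy. With 4096-sample
  epochs, ≥ 99% of band-filtered white-noise power lies within 1 Hz of the
  band edges (verified in the tests).
* The montage's ear electrodes (A1/A2) are not analysis channels; the
  network node count is N = 19 scalp positions of the 10–20 system. No
  notch filter is applied: the 0.5–45 Hz pass-band already excludes mains
  frequency.

### Connectivity

Instantaneous phase is the argument of the analytic signal (FFT-based
Hilbert transform) of each band-limited channel, computed per epoch. The
first and last 5% of samples per epoch (configurable) are excluded from all
connectivity sums to suppress Hilbert edge transients.

For a pair of channels with wrapped phase difference Δφ(t) ∈ (−π, π]:

* PLI = |⟨sign Δφ(t)⟩|, with sign(0) contributing 0 — the measure's way of
  discarding exactly-zero-lag mass. Phase differences are computed by
  direct subtraction and wrapping (not via phasor products) so that
  identical channels give an exact 0 rather than ±10⁻¹⁷ round-off whose
  signs would be random.
* PLV = |⟨e^{jΔφ(t)}⟩|, computed for all pairs at once as the Gram matrix
  of the unit phasors.

Both are evaluated over interior samples within an epoch and averaged
arithmetically across epochs. PLV is averaged **across time within an
epoch** rather than across trials at fixed latency: the trial-locked form
presumes stimulus-locked data and is ill-posed for resting state, and
within-epoch time averaging is what makes a per-epoch adjacency matrix
well-defined. The PLI diagonal is 0, the PLV diagonal 1.

A note on a tempting but false invariant: PLI ≤ PLV does **not** hold in
general. Any phase-difference series confined to one half of the circle
but scattered within it (e.g. Δφ ∈ {−1.4, −1.0, −1.2, −0.8}) has a perfect
sign asymmetry (PLI = 1) but imperfect phasor concentration (PLV < 1). The
tests pin this counterexample rather than asserting the false ordering.

### Spanning tree and metrics

The tree maximising total FC weight is extracted with Kruskal's algorithm:
candidate edges sorted by descending weight (ties broken by ascending node
indices for platform-independent determinism), cycles rejected by
union–find. Raw FC weights are used, not 1 − w distances, so the tree
"mean" metric stays on the connectivity scale.

For a tree with N nodes, M = N − 1 edges, degrees k, hop-count distance
matrix d(i,j):

| metric | definition | notes |
|---|---|---|
| leaf number L | #{i : k_i = 1} | 2 (path) … N−1 (star) |
| leaf fraction | L / M | redundant with L at fixed N; carried on the object but not reported as a separate cell |
| diameter d | max d(i,j) | hops |
| hierarchy Th | L / (2 M B_max) | B_max = max normalised betweenness; star → 0.5, long path → 0 |
| kappa | ⟨k²⟩/⟨k⟩ | degree divergence, hub-sensitive |
| assortativity R | Pearson correlation of endpoint degrees over the symmetrised edge list | Newman's standard definition; a star gives exactly −1; NaN (degenerate) values are excluded from statistics with a warning |
| Teff | 1 − d / (N − L + 1) | ∈ [0, 1]; over all 16 807 labelled 7-node trees the maximum is 0.2 (the three-arm spider) |
| ASP | mean d(i,j) over unordered pairs | hops; unnormalised |
| mean | mean edge weight | FC units |

Distances are hop counts throughout — the line/star limiting cases of the
metrics only make sense that way. Shortest paths, betweenness and
assortativity are delegated to networkx and cross-checked in the tests
against hand-rolled BFS and Prüfer-enumeration oracles.

With `mst_per: epoch` (default) a tree is built per epoch and metrics are
averaged across epochs to the subject level; with `mst_per: subject` epoch
FC matrices are averaged first and a single tree is built. The package
default follows the per-epoch reading, but note the estimator caveat under
"Synthetic cohorts" below.

### Statistics

Between groups, every band × measure × metric cell is tested with a
pooled-variance two-tailed Student t (df = n_a + n_b − 2); the
summary-statistic entry point is numerically identical to the raw-value
one, which is how published demographic tables are reproduced. Cohen's d
uses the pooled SD. Benjamini–Hochberg FDR adjustment is applied across
the full family of cells by default (`fdr_family: per_band` restricts the
family).

Within a group, a two-way repeated-measures ANOVA decomposes the metric
table into measure, metric and measure × metric effects with subject as
the blocking factor, each tested against its own subject-interaction error
term; partial η² = SS_effect/(SS_effect + SS_error). Because the eight
metrics live on incommensurate scales (κ ≈ 2, mean weight ≈ 0.5, diameter
in hops), each metric is z-scored across subjects × measures before the
omnibus terms are formed — without this the interaction would be dominated
by units rather than structure. The per-metric paired contrasts (PLI vs
PLV, Bonferroni-multiplied by the number of metrics) are scale-invariant
and unaffected. With a two-level measure factor the measure effect needs
no sphericity correction; no Greenhouse–Geisser correction is applied to
the metric terms by default. Degenerate decompositions (identical measure
columns) are snapped to SS = 0 so F is 0 rather than a ratio of round-off.

The whole statistical layer is exposed as `MSTComparison(metrics_table)`
with `fit()` returning a results object (`between` table, `within` ANOVAs,
`summary()`), in the style of statsmodels model/results pairs.

## Synthetic cohorts

No public recordings accompany the clinical study this design emulates, so
the generator provides ground-truth-bearing inputs:

x_i(t) = cos(θ(t) + δ_i + ε_i(t)) + g_i·s(t) + η_i(t)

* θ(t) integrates an instantaneous frequency drawn uniformly in the band,
  constant within an epoch and redrawn per epoch — band-limited without
  nonstationary chirps.
* δ_i are constant per-channel phase offsets realising an antisymmetric
  pairwise lag matrix (δ_i = lag(i, 0)).
* ε_i(t) is i.i.d. wrapped-Gaussian phase jitter with SD σ (`jitter_sd`);
  smaller σ = stronger coupling. For a pair of independently jittered
  channels the raw-phase PLV is exp(−σ²), an analytic check used in the
  tests (the Hilbert estimate runs slightly above it because broadband
  jitter partially leaves the analytic signal's phase).
* s(t) is an independent oscillator in the same band entering every
  channel with zero lag and gain g_i = `common_source_gain` × topography.
  The topography is heterogeneous (linearly spread over 0.25–1.75) — a
  spatially uniform projection would be removed exactly by the average
  reference and corresponds to no physical source geometry.
* η_i(t) is additive white Gaussian noise (`noise_sd`).

Defaults: 19 channels, alpha-band carrier (8–12 Hz), σ = 0.8, noise SD
0.5, zero lags, no shared source; cohorts of 20 + 20 subjects, 75 epochs
× 8 s at 512 Hz, matching the emulated study design. The **zero-lag base
ensemble** is deliberate: channels couple through the shared jittered
carrier, the average reference removes the common mode and leaves
moderate, heterogeneous residual coupling, and all coupling mass sits at
phase difference 0 mod π. This is precisely the regime in which PLI is
blind to the shared-source confound while PLV is fully exposed to it —
the mechanism the discordance experiment is about. Installing genuine
lagged coupling (`offsets=` argument) moves PLI off its floor but also
breaks the strict immunity: the source's phase pull is then differential
across channels, and both measures respond. The generator does not
attempt 1/f spectra, realistic head geometry or artifact morphology, so
passing tests validate the estimators and their contrast under a known
confound — not performance on real EEG.

All randomness flows through `numpy.random.SeedSequence`; per-subject
seeds are split from the master seed by counter, making cohorts
bit-identical across runs and independent of generation order.

## Study-level experiments

Both experiments keep the study's group sizes (20 + 20) and scale the
per-subject recordings down (2–6 epochs × 2 s, one alpha band) so that
hundreds of cohorts run in minutes; per-subject data volume affects only
Monte-Carlo precision, not the mechanisms under test.

* **Null calibration** — 200 cohorts with no group effect; the fraction of
  nominally significant (p < 0.05) between-group cells must lie in the 99%
  binomial band around 0.05. One measure × metric cell is sampled per
  cohort, rotating through all 16 combinations: cells within a cohort
  share subjects and are strongly correlated (leaf-derived metrics nearly
  duplicate each other), so pooling them would invalidate the binomial
  band; one cell per cohort makes the 200 pooled comparisons independent
  and the band exact.
* **Confound discordance** — 20 replicate cohorts with
  `common_source_gain` 0 vs 0.8. Expected and observed: the PLV-based tree
  mean separates the groups in ≥ 18/20 replicates, the PLI-based tree
  mean in ≤ 3/20, and the within-group measure × metric interaction is
  significant in every replicate. This experiment builds trees from
  subject-averaged FC (`mst_per: subject`, 6 epochs): with tiny per-epoch
  samples, per-epoch trees make the maximum-weight edge selection a
  max-of-noise statistic whose bias tracks the temporal noise structure —
  which the shared source alters — producing a spurious PLI "effect" that
  grows with averaging rather than shrinking. Subject-level FC averaging
  is the estimator under which the experiment converges on the mechanism
  (the measured PLI group drift falls with added data instead of rising).

## Numerical choices and edge cases

* Kruskal tie-break: stable sort on (−weight, i, j); equal-weight inputs
  give the lexicographically first tree on every platform.
* sign(0) = 0 in PLI; phase wrapping convention (−π, π] throughout.
* Assortativity on degenerate trees: NaN is propagated, warned about, and
  excluded cell-wise from group statistics; a within-group ANOVA drops a
  metric (with a warning) if any subject lacks a finite value for it.
* A single-measure run skips the measure ANOVA with a logged notice.
* `summary.json` omits wall-clock timings so identical config + seed
  reproduces byte-identical outputs.
* All-zero channels make instantaneous phase undefined and raise an error
  naming the channel, rather than returning arbitrary angles.

## Known limitations

* The generator's phase jitter is white; band-pass filtering therefore
  removes much of it, and effective coupling after preprocessing is
  stronger than exp(−σ²) would suggest. Parameter values are calibrated
  in terms of pipeline-level behaviour, not raw-signal SNR.
* PLI's confound immunity is exact only for symmetric phase-difference
  distributions; with genuine lagged coupling plus a strong shared source,
  second-order differential-pull effects move PLI too. This mirrors the
  measure's behaviour on real data and is documented, not hidden.
* Sphericity corrections beyond the two-level measure factor are not
  applied by default; mixed models, permutation statistics and
  cluster-based corrections are out of scope.
* EDF reading requires the optional `mne` dependency; only standard
  EDF/EDF+ signals are supported.
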
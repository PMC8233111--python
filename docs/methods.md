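# Methods

## Connectivity statistic

Signals are analyzed in non-overlapping 1-s epochs. Within an epoch each
channel is standardized (zero mean, unit variance, population SD); the
statistic for a pair is the maximum over lags τ ∈ [−L, +L] of the absolute
biased normalized cross-correlation r(τ) = (1/N) Σ_t x[t] y[t+τ]. The lag
bound L defaults to 200 ms (40 samples at 200 Hz): a physiological bound
that avoids spurious maxima from the shrinking overlap at extreme lags.
Ties break toward smaller |lag|, then toward the negative lag, so the
statistic is deterministic.

The score is z = atanh(|r|)/s with the Bartlett-type variance
s² = (1/N) Σ_{|τ|<N} ρ_xx(τ) ρ_yy(τ) computed from the biased epoch
autocorrelations. For white noise s ≈ 1/√N; autocorrelated (band-limited)
signals inflate s, which is what protects the test from the spurious
correlations that slow rhythms would otherwise produce. |r| is clipped at
1 − 1e−12 before the Fisher transform, and s² is floored at 1e−4/N so a
numerically degenerate epoch cannot produce an infinite score; the same
clipping applies to null and observed scores, so calibration is unaffected.

**Permutation null.** Per pair, 500 draws pair a 1-s epoch of one channel
with an epoch of the other channel from a different time (window starts at
least 2 s apart, i.e. separated by at least 1 s of data), scoring each draw
exactly as above. The significance threshold is the nearest-rank 95th
percentile (the 475th of 500 sorted values), so exactly 95% of the null
sample lies at or below it.

**Exclusions.** An epoch-pair whose |cross-correlation| peaks at zero lag is
excluded as volume conduction (entry 0, reason recorded); the exclusion is
per pair-epoch, not per epoch, so other pairs' data survive. A significant
entry is then partialized against the common-average reference: the epoch
segments aligned at the selected lag are each correlated with the
co-temporal segment of the reference, the first-order partial correlation is
formed, and the entry is discarded (reason `reference-artifact`) when the
partialized score no longer exceeds the pair's null threshold. This
operationalizes "large difference between correlation and partial
correlation" as *significant before partialization, not after*, which needs
no additional constant.

Excluded entries count 0 in numerators and stay in denominators of every
fraction downstream, consistent with "fraction of epochs with a significant
connection".

## Aggregation

State networks Q_w and Q_s are bootstrap means: per iteration, N_samp
epochs are drawn with replacement from the state's valid epochs and the
per-pair significant fraction computed; the network is the mean over n_boot
iterations (defaults 11,000 and 1,000; the bootstrap mean equals the plain
fraction in expectation, which the tests verify). Strength is the mean of
the ⌊0.10 · n_pairs⌋ largest upper-triangle entries (floor rule; stable
sort). The windowed series Q_n uses windows of n seconds (default 300)
stepped by 30 s; windows with fewer than 50% valid epochs are flagged
unusable — an artifact-density rule of this package, since heavily
contaminated windows would otherwise contribute noisy fractions. 2-D
correlations are product-moment correlations over the upper-triangle
off-diagonal entries only (the structural zero diagonal would inflate r).
Stability curves concatenate a state's valid epochs in time order across
bout boundaries, then correlate successive non-overlapping Q_n blocks.

Per-connection state differences across subjects use the paired two-tailed
Wilcoxon sign-rank test with Benjamini–Hochberg adjustment at q = 0.05.

## Graph metrics

Degree is the row sum of the weighted adjacency matrix. Clustering and path
lengths are computed on the max-normalized network (every entry divided by
the maximum). Clustering is the geometric-mean (Onnela) weighted variant,
C_i = Σ_{j,h}(w_ij w_ih w_jh)^{1/3} / (k_i (k_i − 1)), where k_i counts
neighbours with strictly positive weight and C_i = 0 when k_i < 2 — the
positive-weight rule matters only for sparse toy networks, as empirical
fraction networks are dense. Edge lengths are 1/w; shortest paths are exact
(Dijkstra per node); the characteristic path length is the mean over
connected ordered pairs, with disconnected pairs excluded under a warning
rather than imputed.

## State decomposition

The usable windows' pair-fraction vectors form the matrix C (pairs ×
windows): each column is standardized (windows with zero variance across
pairs are dropped), then each row is demeaned. PC1 comes from the SVD of C;
loadings are unit-norm with the largest-magnitude loading oriented positive
(all downstream scores are invariant to the sign). A two-component
univariate Gaussian mixture is fitted to the PC1 time course by EM, best of
10 restarts under a fixed seed. The state threshold is the grid point (2,001
points strictly between the component means) where the ratio of the two
weighted component densities is closest to 1; restricting the grid to
between the means avoids spurious intersections in the far tails. A
`mixture_overlap` diagnostic (integral of the pointwise minimum of the two
weighted densities, scaled by the lighter weight) flags near-unimodal time
courses where the threshold is not meaningful. Correspondence against a
hypnogram is the better of the two label-to-state mappings, scored per
window against the majority (sleep vs wake) stage within the window.

## Circadian analysis

Each usable window contributes one value per metric — mean strength (the
mean of all connections, equal to the proportional strength at top fraction
1.0), mean degree, mean clustering, characteristic path length — tagged with
the wall-clock minute of the window start. A window is assigned to wake or
sleep only when at least 90% of its seconds share that state; mixed windows
are dropped (the purity floor is this package's rule). Group profiles pool
values per minute bin across subjects; bins with fewer than five values
carry no mean. The day/night test resamples the 11:00–13:00 and 23:00–01:00
pools with replacement 1,000 times, records the night-minus-day difference
of means, and calls the effect significant when the 95% percentile CI
excludes 0 (the night interval wraps midnight: minutes 1380–1439 and 0–59).

**Pool decimation.** Consecutive 300-s windows at 30-s steps share 90% of
their epochs, so their metric values are strongly autocorrelated. Pools are
therefore decimated to windows at least one window-length apart before
resampling (the profile itself still uses all windows). With fully
overlapping pools the iid bootstrap would understate the variance of the
pool means by roughly the overlap factor and reject far too often under the
null; with decimated pools the empirical null rejection rate is close to
nominal, which the acceptance checks verify.

## Synthetic data

The generator emulates the regime the pipeline targets: multichannel
recordings (19 channels at 200 Hz by default) alternating between two
behavioural states, with

- bout durations 60 s + Exp(mean − 60) — an exponential law truncated below
  at 60 s whose mean equals the configured bout mean (1 h by default). The
  truncated exponential is a simplicity choice with positive support, not an
  empirical infant bout-length law;
- per-channel private band-limited (0.5–30 Hz) Gaussian noise;
- coupling via shared band-limited sources added to both channels of a pair
  with a per-pair lag ≥ 1 sample, so genuine coupling never peaks at zero
  lag and is not destroyed by the volume-conduction rule. Default topology
  is a ring with wake weight 0.4 and sleep weight 0.8 (sleep twice wake),
  which yields top-10% strengths of ≈ 0.09 (wake) and ≈ 0.24–0.32 (sleep) —
  the range empirical infant networks occupy;
- a multiplicative circadian gain 1 + A·cos(2π(t − phase)/24 h) on the
  coupling envelope (default A = 0.3, peak at midnight);
- sparse 0.2-s raised-cosine transients on random channels (default 2/hr at
  25 background SDs) emulating extreme-amplitude artifacts.

What it does **not** emulate: stage-specific EEG spectra (one "sleep" state
stands for N1/N2/N3/REM pooled), referencing artifact, impedance checks,
electrode pops, or non-stationary noise floors. Passing tests therefore
demonstrate that the pipeline recovers lagged-coupling structure, state
switching and circadian gain modulation under realistic noise — not that it
handles every clinical artifact class.

## Problem sizes and numerical choices

The end-to-end checks run at reduced scale chosen as the package's standard
desk-scale configuration: the two-state recovery uses a 20-hr, 6-channel
recording with 200 null iterations, 1,000-epoch × 100-iteration bootstraps,
and no circadian modulation (the circadian effect is assessed separately so
the two factors are not confounded). Circadian calibration treats the
day/night comparison as the group-level analysis it is: each replicate pools
the wake windows of two subjects, each contributing a 2.75-hr, 4-channel
(125 Hz) recording over the daytime window and one over the nighttime
window, with one permutation null bank shared between a subject's two
periods — the Monte-Carlo error of the per-pair thresholds then shifts the
day and night significant-fractions identically and cancels from the
difference of means, which is what keeps the empirical null rejection rate
of the bootstrap near nominal. Twenty replicates are run per amplitude.
Common-average re-referencing is
enabled by default for real recordings but disabled in the low-channel
simulations: with few channels the subtracted average contains a large share
of every source, creating genuine (not artifactual) cross-channel mixing;
at 19 channels the effect is ~1/19 per channel and the pipeline's null
calibration holds with re-referencing on, which the tests cover.

EDF files are written by a minimal 16-bit writer (one record per second,
per-channel symmetric physical range in µV) and read back through MNE;
round-trips are exact to one quantization step.

## Known limitations

- The variance estimator and the partialization rule are stated
  qualitatively in the connectivity literature; the concrete forms here
  (Bartlett sum over all lags, significant-before/not-after rule) are this
  package's operationalization.
- Correspondence scoring uses the majority stage per window; windows
  straddling a state transition are intrinsically ambiguous and bound the
  achievable correspondence below 100%.
- The day/night bootstrap treats decimated windows as independent; residual
  dependence from bout structure is not modelled.
- Characteristic path length on networks with isolated nodes excludes the
  disconnected pairs, so comparisons across networks with different support
  should be read with care.
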
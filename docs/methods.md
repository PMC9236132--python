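# Methods

This note documents the models, parameter choices and numerical decisions
behind `emodyn`, stage by stage, and what the synthetic cohorts can and
cannot tell you about real recordings.

## Signal model and preprocessing

Recordings are channels × samples matrices at fs = 125 Hz on the 15-site
10/20 montage (Fp1, Fp2, F7, F3, Fz, F4, F8, T7, Cz, T8, P7, Pz, P8, O1,
O2). Cleaning applies, in order: a band-stop at the mains frequency
(default 50 ± 2 Hz), an FIR high-pass at 1 Hz (removes DC and drift), an
FIR low-pass at 50 Hz, and common-average re-referencing. All filters are
windowed-sinc (Hamming) designs sized for roughly 50 dB of stop-band
attenuation at the stated transition widths, applied forward–backward so
the chain is zero-phase; filter order and phase policy are deliberate
package choices surfaced in the API, since only the cutoff frequencies are
scientifically constrained. Average re-referencing of a single channel
would null the data and is refused. ICA-based ocular artifact removal is
out of the main path (synthetic data is artifact-free); `mne`'s ICA can be
applied upstream by the caller when working with real recordings.

Epochs are half-open, non-overlapping 4-s windows (500 samples); a
trailing partial window is discarded.

## Band powers via the Hilbert–Huang transform

Each epoch channel is sifted by empirical mode decomposition: cubic-spline
envelopes through the local extrema, envelope-mean subtraction until the
standard-deviation criterion SD < 0.2 (at most 10 sifts per IMF, at most
12 IMFs) — the canonical sifting defaults. The signal is mirror-extended
by half its length on each side before sifting and cropped afterwards,
which tames envelope end-swings on 4-s epochs; the residual is set to
input − ΣIMF so reconstruction is exact by construction. Envelope spline
solves (natural boundary, Thomas algorithm) are numba-compiled: a 500-
sample epoch decomposes in well under a millisecond, which keeps the
cohort-scale simulations tractable.

Per IMF, the analytic signal gives instantaneous amplitude a_j(t) and
frequency ω_j(t) (unwrapped-phase gradient; negative frequencies from
unwrapping glitches are clipped into the lowest bin). Squared amplitudes
are binned on a 0.1 Hz grid over (0, fs/2]; binning conserves energy
exactly. Band power is the mean of the marginal (time-summed) spectrum
inside each rhythm: delta 0–3.9, theta 3.9–7.8, alpha 7.8–13.7, beta
13.7–29.3, gamma 29.3–46.9 Hz. These edges sit on the 62.5/32 =
1.953125 Hz leaf grid of the wavelet-packet tree below, which is why they
differ from textbook 4/8/13/30 Hz bands. Flattening gives 5 × 15 = 75
features per epoch; a per-recording mean is also provided since either
granularity can be wanted downstream.

## Wavelet features

A 5-level Daubechies-10 wavelet-packet decomposition yields 32 uniform
leaf bands. Only a 5-level tree produces 32 leaves and the 1.95-Hz
edge granularity of the band table above, so depth 5 with the db10 filter
is used. Leaves are taken in frequency (sequency) order and summed into
rhythms on contiguous 1-based leaf ranges: delta 1–2, theta 3–4, alpha
5–7, beta 8–15, gamma 16–24 (disjoint ranges; the beta/gamma boundary
falls between leaves 15 and 16, consistent with the 29.3 Hz edge). Series
are zero-padded to a multiple of 32 and transformed with periodization
boundaries, making the transform orthogonal: leaf energies satisfy
Parseval against the time-domain energy to machine precision.

Energy ratios R_i = E_i / E_total use the total over all 32 leaves, so
ΣR_i ≤ 1 with equality when the signal has no energy above 46.9 Hz.
Wavelet entropy W_e = −Σ R_i ln R_i (natural log, 0·ln 0 = 0) is bounded
by ln 5 ≈ 1.609.

## Complexity estimators

Defaults: template length m = 2, tolerance F = 0.2 (r = F·SD of the
series, floored at 1e−12 for constant input), embedding dimension D = 3,
histogram bins K = 16 — the literature's canonical operating points, since
no others are scientifically constrained. All four estimators are checked
against independent O(n²) direct-count oracles in the test suite.

* **ApEn** — Φᵐ − Φᵐ⁺¹ with Φᵐ the mean log fraction of templates within
  Chebyshev distance r, self-matches included.
* **SampEn** — −ln(A/B) with pairwise match counts over the first n−m
  templates, self-matches excluded; zero matches raise an explicit
  "undefined" error rather than returning a silently large number.
* **PEn** — Shannon entropy (bits) of ordinal patterns of overlapping
  length-D windows; ties break by order of appearance (stable argsort),
  bounded by log₂ D!.
* **SSCEn** — the mean-centered series is delay-embedded into length-D
  windows; the correlation (Gram) matrix between *every pair of windows*
  is formed and its strict upper triangle histogrammed into K equal-width
  bins over the observed range; SSCEn is the bin-probability entropy in
  bits, bounded by log₂ K. Pairwise window correlations (rather than the
  D × D window-coordinate Gram matrix) are used because the statistic is
  meant to capture the distribution of similarities *between pieces* of
  the series; a D × D matrix would expose only D(D−1)/2 values and
  degenerate for small D. Mean-centering plus range-relative bins makes
  the statistic affine-invariant, matching the SD-relative tolerance
  convention of ApEn/SampEn.

Sliding windows default to 5 s (the approximate cycle of emotional
change), non-overlapping.

## Feature selection and the emotion trajectory

Features are restricted to the emotion-related channels (Fp1, F7, T7, Cz,
T8, P8, O2) and pooled across participants with the condition as the
binary class variable. The default trajectory feature set is permutation
entropy plus the wavelet features (W_e and the five rhythm ratios) per
channel — one non-linear and one frequency-domain family, both cheap and
both responsive to slow spectral modulation; ApEn/SampEn/SSCEn can be
swapped in through the `estimators` configuration. CFS merit for a k-feature subset is
k·r̄_cf / √(k + k(k−1)·r̄_ff) (Pearson correlations, labels coded 0/1),
grown greedily; ties keep the earliest column. "Subject-independent" is
operationalized as leave-one-subject-out sign stability: the
feature–class correlation must keep one sign in ≥ 80 % of leave-outs
(a within-subject correlation with the class is undefined in a
between-subjects design, where each participant sees one condition).
Screened-out features are used only if the stable pool is smaller than
the requested 15.

The selected columns are z-scored on pooled statistics and embedded *per
participant* with Isomap: symmetric k-NN Euclidean graph (k = 10 by
default; incremented with a log message until the graph connects),
all-pairs geodesics by Dijkstra, classical MDS of squared geodesics
(double centering, leading eigenpair, coordinate √λ·v). Per-subject
embedding is used because the trajectory is an individual time course; a
pooled embedding would entangle participants. The 1-D output is centered
to zero mean (required by the ZCR construction) and sign-fixed so its
first nonzero value is positive — the MDS sign is arbitrary and ZCR_EC is
sign-invariant anyway.

## ZCR_EC, CLI, and the modulation fit

The order-k binomial high-pass L_k{Z(n)} = Σⱼ C(k−1, j−1)(−1)^{j−1}
Z(n−j+1) equals the (k−1)-th backward difference; k = 1 is the identity.
The filtered series is binarized at zero (≥ 0 → 1) and symbol changes
counted. M = 4 orders are evaluated and stored; the reported statistic is
k = 1, the plain zero-crossing count that the method's verbal description
gives. The raw-signal analogue applies the same k = 1 count to each
zero-meaned emotion channel and averages.

CLI is beta/(theta + alpha) with band means over load-sensitive subsets:
alpha over Fp1, Fp2, F3, T8, Cz, P8, O1, O2; beta over Fp1, F3, F7, F8,
Fz, F4, T8, Cz; theta over all 15 sites. Epochs with a non-positive
denominator are excluded and logged. The per-subject CLI is the epoch
mean, and the across-participant fit ZCR_EC = α·CLI + β is ordinary least
squares with the slope standard error from residual variance.

Group comparisons use a hand-decomposed one-way ANOVA (verified against
`scipy.stats.f_oneway`) with partial η² = SS_b/(SS_b + SS_w); Shapiro–Wilk
normality p-values are reported but never gate anything. The ANOVA
computes its degrees of freedom from the data it receives.

## Synthetic cohorts: what they emulate

A cohort is two conditions × 19 participants (per-participant seeds are
`seed + index`, so cohorts are reproducible yet participants independent).
Each recording sums five band-limited oscillations (FIR-filtered white
noise at the rhythm edges, power-scaled by per-condition gains), 1/f
background noise, and a latent emotion state:

* **Latent state** — white noise smoothed with a Gaussian kernel; for the
  resulting squared-exponential autocorrelation, Rice's formula gives an
  expected zero-crossing rate of 1/(π√2·σ), so the kernel width is solved
  from the configured rate. Defaults: 3 sign changes/min in the high-load
  arm, 10/min in the low-load arm.
* **Coupling** — the latent state modulates the theta and alpha
  oscillation amplitudes on the emotion channels by 1 + 0.6·tanh(latent),
  emulating arousal-linked low-frequency power modulation. Spectral-ratio
  and ordinal-complexity features both pick this up, which is what lets
  CFS + Isomap recover the latent tempo.
* **Load contrast** — the high-load ("grayscale") arm gets relatively more
  beta/gamma power (configured-gain engagement ratio 0.75 vs 0.28) and
  more 1/f noise (gain 1.0 vs 0.7), so it has the higher CLI and the
  higher complexity; its slower latent state gives it the lower ZCR_EC.
  Together these make the true trajectory-slope sign negative and the
  raw-signal slope positive, and the generator's `GroundTruth` records
  those orderings for recovery tests.

Channels are z-scored before export (the pipeline is scale-covariant;
tolerances are SD-relative). Within-condition dispersion of CLI and
ZCR_EC is whatever the stochastic generator produces — it is not
calibrated to any particular population, so recovered slope *magnitudes*
are properties of the synthetic conditions only; only signs and orderings
are meaningful claims. The generator makes no attempt at ocular/muscle
artifacts, volume conduction, inter-channel correlation structure, or
non-stationary drifts, so passing tests demonstrate that the pipeline
recovers the constructs it targets when they are present — not that those
constructs are identifiable in arbitrary real data.

## Problem sizes and tolerances

Simulation-based tests use 60-s recordings (15 epochs, 12 feature
windows) with 19 participants per condition and 30 cohort replicates for
sign-recovery checks; `scripts/acceptance.py` uses 10 replicates. These
sizes give stable signs and orderings while keeping a full run in the
minutes range on a single CPU. Estimator-vs-oracle comparisons are exact
to 1e−10 on series up to length 200; spectral assertions use
physically-motivated tolerances (e.g. ≥ 90 % in-band power for a pure
in-band source, 15 % relative error on configured band-power ratios,
20 % on empirical latent crossing rates at ≥ 120 s).

## Known limitations

* EDF export is unavailable (no EDF writer backend); recordings persist
  as CSV + JSON sidecar. EDF *reading* works via `mne`.
* EMD has no uniqueness guarantees; mode mixing on broadband signals is
  inherent to sifting and only mitigated by the mirror extension.
* The CFS consistency screen needs several subjects per condition to be
  meaningful; with one subject it degrades to plain CFS.
* ZCR_EC on short trajectories (12 windows at 60 s) is a coarse count;
  longer recordings sharpen it roughly linearly.
* The modulation fit is plain OLS across participants — no hierarchical
  pooling of within-subject uncertainty.
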
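# Methods

This note documents the models, estimators and numerical choices behind
each pipeline, what the synthetic generators do and do not emulate, and
the known limitations.

## MEA pipeline

**Spike detection.** Traces are band-pass filtered at 300–3000 Hz
(4th-order Butterworth, zero-phase) and thresholded at −k·σ_n with
k = 5 and σ_n = median(|x|)/0.6745, the standard robust noise estimate
that is insensitive to the spikes themselves. A 1 ms refractory lockout
follows each trough; amplitude is trough-to-peak over a 2.5 ms window
with the trough at one third. Events whose full window does not fit
inside the trace are dropped — besides being unmeasurable, the first
millisecond after a zero-phase filter carries edge transients that
would otherwise fire the threshold. Requires ≥ 10 kHz sampling.

**Spike sorting.** Per electrode, waveforms are reduced to 3 principal
components and clustered with full-covariance Gaussian mixtures over
k = 1…8; k is chosen by BIC (reg_covar 1e-4, 3 restarts, fixed random
state, so labels are deterministic). Electrodes with fewer than 20
waveforms get a single unit and a warning. No cross-electrode duplicate
merging or drift correction is attempted.

**Burst detection (Max-Interval).** A burst opens when an ISI ≤ 0.17 s,
extends while ISIs ≤ 0.3 s, closes otherwise; bursts separated by
< 0.2 s merge (spike count then spans the merged range); bursts with
< 3 spikes or < 10 ms duration are discarded. All five parameters are
exposed. The implementation is checked for exact agreement against an
independent brute-force ISI scan on randomized trains, including
tie-heavy and threshold-straddling cases.

**Network metrics.** ASDR counts all sorted spikes per 1 s bin across
the array (half-open bins, recording start at 0); its sum always equals
the total spike count. Autocorrelograms count ordered spike-pair lags
in bins of 0.1 s centered on integer multiples of the bin width within
±15 s (wide enough to contain ~9 s network periodicity); only bins
fully inside the window are kept — a half-covered edge bin shows up as
a spurious dip that distorts peak prominences. The histogram is
symmetric by construction and normalized to peak 1 on request. The
burst period is the lag of the highest local maximum at |lag| > 1 s of
the unit-averaged normalized ACG after an edge-aware 5-bin moving
average, requiring prominence ≥ 0.1; below that the culture is reported
aperiodic (None). The ACG flatness index (max/median beyond ±0.3 s) is
~1 for Poisson firing and ≫ 1 for periodic bursting.

## Calcium pipeline

**ΔF/F.** Baseline F0 is a running 20th percentile over a 30 s window
(edge-replicated); ΔF/F = (F − F0)/F0. The percentile window absorbs
slow drift but sits ~0.84·σ below the noise mean, so the detector
centers the ΔF/F series on its median before thresholding.

**Transient detection.** The noise SD is σ = 1.4826·MAD(diff(ΔF/F))/√2:
first differences cancel the (slow) transients and √2 rescales the
difference of two iid samples. σ is floored at 0.02 ΔF/F so that
noiseless traces keep finite thresholds. The centered series is
smoothed with a 0.25 s moving average — without smoothing, iid noise
crosses 2σ roughly once a minute and transient counting on quiet traces
becomes meaningless; with it, the pure-noise false-positive rate is
< 0.05 events/min. A transient is a maximal excursion above 0.5·σ whose
(smoothed) peak exceeds k·σ, k = 2 by default. The onset is the last
upward 0.5·σ crossing before the peak, refined on the *unsmoothed*
series because the centered moving average pulls the crossing earlier
by about half a window; the return is the first frame after the peak
below 0.5·σ *sustained for 0.5 s* — a single-frame dip below baseline
level during a decaying transient is noise, and counting it as the
return biases t2 short by 20–30% at realistic noise. Excursions that
reach the end of the trace are censored: t2 is reported NaN and
excluded from means. All multipliers and windows are configurable.

**Kinetics oracle.** The simulator plants difference-of-exponential
transients a·(e^{−t/τd} − e^{−t/τr}) normalized to unit peak, with
analytic peak time t* = τr·τd/(τd−τr)·ln(τd/τr) (0.51 s at defaults)
and analytically solvable 0.5·σ crossings; recovered t1 and t2 are
compared against those closed forms. At σ = 0 the return crossing of an
exponential tail is never reached within a finite trace, which is why
the σ floor exists and why noiseless t2 is evaluated against the
floored threshold.

**Generator.** Traces are baseline + linear drift + baseline·Σ
transients + Gaussian noise at 20 Hz (a typical imaging rate; 120 s
default). Onsets follow a hard-core renewal process — exponential gaps
plus a 12 s dead time, parameterized so the mean rate equals
`transient_rate` exactly. The dead time mirrors the refractoriness of
somatic calcium recovery and keeps adjacent events resolvable; a pure
Poisson process at the default rate would merge ~25% of events inside
each other's decay tails and conflate generator overlap with detector
error. Not emulated: bleaching (drift is linear), correlated/shared
noise across ROIs, movement artifacts, and indicator saturation.

## Puncta pipeline

**Spot detection.** Scale-normalized LoG response at the expected spot
scale (σ = 0.2 µm default); local maxima above the 0.995 response
quantile, minimum separation 2σ, refined to sub-pixel precision with a
3×3 center of mass on the response. The quantile threshold adapts to
image content; at SNR 10 it yields ≥ 95% precision and recall on
planted spots.

**Dendritic mask.** 1 µm Gaussian smoothing then Otsu; a uniform
channel gives an empty mask. Skeleton length sums inter-pixel distances
over the 8-connected skeleton (diagonals √2) plus a distance-transform
half-width at each endpoint, compensating the tip retraction inherent
to skeletonization (without it a 50 µm straight process measures
~47 µm).

**Assignment.** One-to-many: a pre spot is assigned iff any post spot
lies within `max_dist` (Euclidean, default 1.0 µm — the synaptic
apposition scale; always report it alongside results since no community
standard exists). Densities are emitted both per 100 µm² of mask area
and per µm of skeleton length. Analysis is 2D (single planes or
projections).

**Chance control.** With post spots shuffled uniformly in the mask, the
per-pre assignment probability is |disk ∩ mask|/A, counted on the pixel
grid; this reduces to the textbook 1 − (1 − πd²/A)^n_post when disks
lie fully inside the mask, but thin (2 µm) processes clip ~12% of the
disk area at d = 0.5 µm, so the exact-geometry expectation is the one
the benchmark tests against (the idealized value is also reported).

**Generator.** Gaussian spots inside a synthetic neurite mask (random
2 µm-wide segments up to the requested coverage). Exactly
⌊coloc_fraction·n_pre⌋ pre spots receive a partner at 0.15–0.85 of the
colocalization radius; all non-partner pre/post pairs are kept beyond
2× the radius so the planted fraction is recoverable without chance
contamination. Same-channel spots keep ≥ 1 µm spacing. Not emulated:
intensity heterogeneity, axial blur, tissue autofluorescence.

## Single-cell statistics

**Normalization.** Depth scaling to the median cell depth then log1p;
zero-depth cells are dropped.

**Per-cell gene sets.** Each cell contributes its top-N (default 200)
genes by per-gene z-score across cells, ties broken by gene identifier
so the result is invariant to input ordering. This preserves the
statistical contract of per-cell signature enrichment — cell set vs
signature vs universe — while replacing the original
multiple-correspondence-analysis ranking with a simpler standardized-
expression ranking; the hypergeometric test downstream is identical.

**Enrichment.** p = P(X ≥ k), X ~ Hypergeom(N, K, n) with N the
detected-gene universe (genes expressed in ≥ 1 cell, configurable),
K the in-universe signature size, n = N_top. BH across cells within
each signature; score = −log10(p_adj); enriched iff p_adj < 0.05.
Group proportions are compared with Pearson chi-square (no Yates
correction; configurable). Groups with < 2 cells are excluded with a
warning. The null calibration (identical groups, 200 simulations) uses
150 cells per group so expected contingency counts are large enough for
the asymptotic χ² reference; at much smaller groups the discreteness of
the 2×2 table visibly distorts the p-value distribution.

**Differential expression.** Per-gene two-sided Mann-Whitney; exact
enumeration when n_A + n_B ≤ 12 and the combined sample is tie-free,
otherwise the normal approximation with tie correction (no continuity
correction, following single-cell practice). log2FC follows the scanpy
convention log2((expm1(mean log1p a)+1e−9)/(expm1(mean log1p b)+1e−9)).
DEG rule: p_adj < 0.05 and |log2FC| > 0.25. All-zero genes get p = 1
and log2FC = 0. Under the simulated null the empirical type-I error at
0.05 is ~0.05 (5000 genes, 200 cells/group).

**Overlap statistics.** DEG-list overlap uses the same upper-tail
hypergeometric test plus an odds ratio from the 2×2 universe-membership
table with a Haldane 0.5 correction when a cell is zero. Hypergeometric
p-values are validated against exhaustive enumeration of all C(N, n)
draws for universes ≤ 12.

**Pseudobulk export.** Sample-level count aggregation is provided for
external count-model DE tools; those models are deliberately not
re-implemented here.

## Synthetic count generator

Negative-binomial counts with per-gene mean (log-normal across genes by
default, median 1) and dispersion α = 0.5 (var = µ + αµ²); per-cell
log-normal library-size factors (sd 0.3) to stress normalization.
Planted DE multiplies the mean of each DE gene by 2^log2FC in exactly
one group. Signature activation is Bernoulli per cell at the group's
active fraction — a population probability, which also gives the
identical-groups chi-square null its binomial sampling variability —
and multiplies signature-gene means by the activation factor (default
4) in active cells. Not emulated: doublets, ambient RNA, batch
structure, gene-gene correlation beyond the planted signatures.

## MEA simulator

Units fire as homogeneous Poisson processes (0.5 Hz background) with
array-wide population bursts: jittered periodic windows (period 9 s,
jitter 0.3 s, duration 1 s) during which every unit elevates to 15 Hz —
the simplest mechanism that reproduces synchronized periodic bursting;
setting the period to 0 yields the rate-matched desynchronized control.
Templates are biphasic (negative trough, positive rebound) with
distinct amplitudes/widths per unit; spike-table mode attaches one
noisy template instance per spike, raw mode renders voltage with
collisions resolved by summation and warns above a 20% collision rate.
Defaults are chosen for testability of the pipeline, not biological
fidelity — real cultures show rate heterogeneity across units,
non-Poisson ISI statistics, electrode crosstalk and slow drift, none of
which are modeled. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated model, not performance
on arbitrary real recordings.

## Benchmark problem sizes

The recovery benchmarks (`neuropheno.benchmarks`, driven by
`scripts/acceptance.py` and the validation tests) use: 10-seed sweeps of
the default 8-electrode × 3-unit, 300 s bursting network; 1000 random
trains for the burst oracle; calcium noise levels {0, 5%, 10%} of the
transient amplitude plus a 30-ROI × 300 s pure-noise set; 10 seeds ×
4 colocalization fractions of 150+150-spot images and 25 shuffle
replicates for the chance control; 5000 null genes × 400 cells for
type-I calibration and 200 simulations for the chi-square null. These
sizes keep every quantity's sampling error well inside the tolerances
being tested while completing in about a minute.
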
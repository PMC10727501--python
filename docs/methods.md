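# Methods

## Stimulus model and regressors

A dark flash is modelled as a luminance deviation of 1 for `off_duration`
(default 1 s) followed by a linear return to baseline over `ramp_duration`
(default 20 s); overlapping flashes combine by pointwise maximum. The
screen protocol is four training blocks of 60 flashes at 60 s intervals
separated by 1 h of rest, a 30 min spontaneous window, 30 min of acoustic
taps (one per 10 s), 1 h of optomotor stimulation in 30 s epochs of
alternating direction, and a 60-flash re-test block after a 5 h retention
period. The imaging protocol is a single 60-flash block sampled at 1.98 Hz
(12 planes at 10 µm steps, 120 µm of axial coverage). Epochs are indexed
1-based: naive = flashes 1–5, training = 6–240, test = 241–300.

The calcium-indicator kernel is a causal single exponential, peak 1 at lag
zero, truncated at 20 s. Nuclear-localised GCaMP decays slowly and only the
qualitative kinetics matter downstream (every comparison is a Pearson
correlation, which is scale-free), so the time constant defaults to
τ = 3.5 s and is configurable; none of the shipped analyses depend on its
exact value beyond the monotone smoothing it applies. Six stimulus
regressors are built as {full stimulus waveform, onset impulse train} ×
{first three, last three, all} flashes of the imaged block, convolved with
the kernel ("full" mode, truncated to the trace length) and peak-normalised.

## Behavioural fingerprints

Movement events carry bend amplitude, latency, displacement, heading
change, duration and velocity. A stimulus counts as responded when an event
with amplitude above the kind-specific gate (3 rad for dark flashes, 1 rad
for taps) starts within a 1 s window of onset — the window matches the
length of the high-speed clips recorded per stimulus. Component values come
from the first qualifying event; non-responses are excluded from every
component except response probability; epochs with incomplete tracking
propagate as missing values.

The default fingerprint has 47 measures: ten O-bend components
(probability, latency, bend amplitude, bend duration, displacement,
velocity, heading change, vigor = amplitude/duration, event count,
multi-response fraction) × three dark-flash epochs, the same ten components
for taps, six spontaneous-swimming statistics, and one optomotor score
(mean signed heading change toward the motion direction per 30 s epoch).
The measure set is config-driven (`MeasureSpec`), since the component
identities are an assay convention rather than a property of the method.

SSMD uses the method-of-moments estimator with sample variances,
`(m_t − m_c)/sqrt(s_t² + s_c²)`, each compound against the pooled vehicle
controls of its own plate; plates are never mixed. Missing values are
dropped for group statistics and imputed to zero only inside clustering
distances. Hit calling is inclusive (|SSMD| ≥ 2). Hits are clustered with
Ward linkage on standardized-Euclidean distances (flat cut 9.5); the
measure correlogram across hits is ordered by average linkage on
correlation distance. Zero-variance columns get unit variance in the
standardization and zero correlation in the correlogram, with warnings.
Viability requires the median number of spontaneous movement events per
fish to exceed a floor (default 0); non-viable compounds keep a viability
flag but no fingerprint row.

## Movement inference in head-embedded fish

Motion power is the standard deviation of a trailing three-frame window of
the frame-registration correlation trace, smoothed with a Savitzky–Golay
filter (window 15 frames, order 2), and z-scored over the whole recording.
The trailing window's leading edge is padded by repeating the first sample
(edge handling is unconstrained by the definition; repetition keeps the
output length equal to the input and is the least surprising choice). The
z-score baseline includes movement frames; excluding them would require a
circular definition of movement. A flash is responded-to when motion power
exceeds 3 (strictly) inside the half-open window (onset, onset + 10 s].
Percent habituation is `100·(P_early − P_late)/(P_early + P_late)` over the
two halves of the 60-flash block, undefined (NaN, with a warning) for fish
that never respond.

Axial-drift QC sums the functional frames into five equal epochs and
matches each epoch image against the 1 µm anatomy stack by Pearson
correlation over z; fish fail when the best-matching slice moves by more
than 3 µm (strictly) relative to the first epoch. Epoch length derives from
the recording length rather than a hard-coded frame count.

## Functional clustering

Candidate ROIs must correlate at ≥ 0.25 (inclusive) with at least one of
the six stimulus regressors, then at ≥ 0.3 with at least five ROIs recorded
in other fish; "five ROIs in a different larva" is read as five matches
pooled over all other fish (both counts configurable). Both filters commute
with each other on the candidate pool.

Affinity propagation runs on the raw Pearson correlation matrix of the
surviving traces with damping 0.9 and preference −9, up to 1000 iterations
with a 15-iteration convergence window; non-convergence raises with
diagnostics rather than returning partial labels. Cluster ids follow the
leaf order of a complete-linkage correlation-distance tree over the
z-scored cluster mean traces (z-scored means are used for the model; the
affinity itself is scale-free so this only affects the exported means).

Taxonomy labels are a quantification of qualitative class descriptions and
are deliberately configurable. Adaptation comes from the ratio of mean
flash-locked peak response over the last three flashes to the first three:
Pot > 1.1 ≥ noA > 0.8 ≥ weakD > 0.5 ≥ medD > 0.2 ≥ strgD. Shape comes from
the flash-locked mean of the first three (naive) flashes: On when the
response first rises to 15 % of peak only after the 1 s lights-off period
(onset times use a half-frame centre correction at the 1.98 Hz frame rate),
otherwise S/M/L by the time spent above half maximum with fixed bounds at
4 s and 8.5 s. Fixed bounds replace a duration-tercile rule: with four
short, four medium and two long classes the terciles of ten values cannot
bracket four of them in the middle bin, so a tercile rule misclassifies one
medium class as long by construction.

Final assignment re-scans every ROI (including filtered-out ones) against
the cluster means, assigning at maximum correlation ≥ 0.3 (inclusive), ties
to the lowest cluster id, otherwise unassigned. Motor correlations per
cluster are Pearson correlations with a motion regressor (inferred movement
events convolved with the kernel); the median's 99.99999 % confidence
interval uses a percentile bootstrap (100 000 resamples by default — the
extreme level needs that many). Treatment-wise cluster proportions
bootstrap ROIs with replacement, 5000 replicates.

## Spatial statistics

Centroids are counted into half-open isometric voxel bins (default 10 µm
edges — "isometric 10 µm voxels"); out-of-extent points are reported, not
silently dropped. All volume comparisons are Pearson correlations over the
linearised grids computed on raw counts (Pearson is location/scale
invariant per map, so normalising to densities changes nothing). Markers
are selected at correlation strictly > 0.15 and displayed row-z-scored in
complete-linkage order. Marker volumes are compared as intensities, not
binarised (configurable by thresholding the inputs). HSV tuning maps set
saturation to the larger of the two regressor correlations (negatives clip
to zero) and hue to the linear preference `corr_A/(corr_A + corr_B)`
between two anchor hues; ROIs with no positive correlation render
unsaturated. Region densities divide cluster counts inside a binary mask by
the mask's voxel count, optionally row-normalised.

## gad1b classification and enrichment

ROIs are gad1b-positive when red/green is strictly above 0.25. ROIs with
green at or below a floor (default: the 5th percentile of green, since the
ratio is undefined at vanishing denominators) are excluded and counted.
Enrichment per cluster uses a 2×2 chi-square (cluster vs rest × positive vs
negative) without continuity correction — per-cluster tables match the
per-cluster significance stars this analysis produces — Bonferroni-corrected
by the number of clusters tested; clusters with any expected cell below 1
are flagged unreliable. Bootstrap distributions (5000 replicates) resample
ROIs within cluster.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions. Twelve archetypes cover
the named functional classes; each is an amplitude sequence over the 60
flashes (geometric decay to a class floor for depression, saturating rise
toward 2× for potentiation, flat for noA) times a per-flash impulse profile
(class-specific onset delay, duration, and envelope: box, rising, decaying,
or dual-lobed), convolved with the indicator kernel. Pure boxcar profiles
cannot realise twelve mutually distinguishable templates under this
taxonomy — classes sharing a shape and adjacent adaptation bins are nearly
collinear under Pearson correlation because their non-negative amplitude
sequences are, so exemplar-based clustering at preference −9 merges them at
150 ROIs per class. The envelopes and onset/duration spreads provide the
temporal fine structure that real neuronal classes exhibit, while the
ordinal relations the labels promise (strgD < medD < weakD < noA < Pot in
late/early ratio; S < M < L in duration; On fires during the ramp) hold for
every class.

Tuned traces are standardized templates plus i.i.d. Gaussian noise of
sd 1/snr, so two same-class ROIs correlate at snr²/(snr²+1) in expectation:
the default snr = 3 gives within-class correlation ≈ 0.9 ("high SNR").
Motor ROIs follow a per-fish event train (flash-evoked with probability
decaying 0.9 → 0.25 plus Poisson spontaneous swims at 0.05 Hz) convolved
with the kernel; untuned ROIs are pure noise. Centroids come from
per-class Gaussian blobs (σ = 25 µm) in a 496 × 1122 × 276 µm atlas-like
box; the spatial statistics are relative, so any consistent space works.

The screen generator draws per-fish event tables from habituating
baselines: response probability 0.9 decaying to 0.25 within a block
(0.65 → 0.30 in the re-test block, reflecting retention), gamma/normal
kinematic components with explicit between-fish and within-fish variance,
tap probability 0.6, spontaneous swims at 1.2/min with lognormal fish
effects, and a 0.2 rad/event optomotor bias. Planted treatment effects
shift the fish-level distribution of a targeted component by
`δ·√2·σ_fish`, so a planted δ is recovered as an SSMD of ≈ δ for
continuous components; for probability measures the recovery is attenuated
by binomial sampling noise on top of the fish-level spread, which is why
planted-recovery checks use a continuous component. A "paralysis" effect
silences a compound's fish to exercise the viability filter.

The simulations do not model biophysical calcium dynamics, optics or
point-spread functions, bleed-through between channels, swimming
biomechanics, or correlated (non-i.i.d.) imaging noise. Passing tests
demonstrate that the pipeline recovers structure it is pointed at under
those idealisations — correct thresholds, formulas, bookkeeping and
planted-effect recovery — not that the biological conclusions would
replicate on new animals.

## Numerical choices and reproducibility

Pearson computations z-score rows and map zero-variance rows to zero
correlation with warnings. Argmax ties break to the lowest cluster id.
Pipeline runs fan a single seed out to fixed per-stage offsets (all below
2³¹) so each stage can be reproduced in isolation; every run writes a
provenance record with the full config, its hash, and the stage seeds. The
shipped problem sizes — 150 ROIs per class across 6 fish for the imaging
arm, 200 simulated compounds for null screens — are the package's default
study conditions and complete in a few minutes on one CPU.

## Known limitations

- Taxonomy thresholds (1.1/0.8/0.5/0.2 ratio bins; 4 s and 8.5 s duration
  bounds; 15 % onset fraction) quantify qualitative class descriptions and
  will need recalibration for indicators or frame rates that differ much
  from nuclear GCaMP at 2 Hz.
- The cross-fish filter pools matches over all other fish; a stricter
  per-fish reading would remove more ROIs.
- The chi-square layout for gad1b enrichment is per-cluster 2×2; a global
  K×2 test with post-hoc cells is a defensible alternative.
- Affinity propagation's cluster count depends on the preference relative
  to cluster sizes; the −9 default is treated as a fixed protocol
  parameter, not re-derived.
- `zdrift_qc` searches pure z translations; combined xy+z drift is matched
  only through its z component.
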
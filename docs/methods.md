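# Methods

This note documents the models, algorithms and design choices behind
`bandstates`, in the order data flows through the pipeline.

## Synthetic data model

The generator produces the structure microstate analysis assumes, with
every downstream quantity known exactly.

**Hidden state sequence.** Per recording and band, a semi-Markov label
sequence: segment lengths are `min_frames` (default 2 samples, a
refractory floor) plus a geometric draw, with the total mean matched to
the target mean duration (default 80 ms, the middle of the 60–120 ms
range typical of resting-state microstates). The successor state is drawn
proportionally to per-state occurrence weights with the current state
excluded, so successive segments never repeat. The floor encodes quasi-
stability: a pure geometric law with minimum one sample would put ~19% of
segments below 24 ms, which contradicts the stability the model is meant
to emulate and is provably unrecoverable under the standard 3-frame
segment rejection (see *Known biases* below). Long-run expectations
(duration, occurrence, coverage per state) are computed exactly from the
stationary distribution of the label chain and returned as ground truth.

**Signal.** `signal(t) = map[label(t)] · carrier(t) + noise(t)`. The
carrier is a unit-RMS amplitude-modulated sinusoid at the band's centre
frequency (0.3 Hz modulation, depth 0.5); the noise is Gaussian with a
squared-exponential spatial covariance over electrode positions (length
scale 0.5 rad of great-circle angle — a stand-in for volume-conduction
smoothness without a head model), band-limited to 1–40 Hz and scaled so
signal power / noise power equals the requested SNR (default 5). Output
is average-referenced. Template maps are scalp fields of one or two
random dipoles inside a unit sphere, average-referenced, unit-norm, and
rejection-sampled until all pairwise |spatial correlations| ≤ 0.7.
Electrode positions come from a bundled 64-channel extended 10–20 table.

**Study design.** Default 24 subjects × 3 conditions (iTBS, cTBS, sham)
× 4 sessions (pre, post1–post3), 4-minute recordings at 128 Hz. Subject-
level parameters (per-state duration; log occurrence weight) are drawn
with between-subject SDs of 8 ms and 0.2 log-units, and each post session
correlates ρ = 0.5 with pre at the parameter level — consistent with the
0.25–0.45 pre/post rank correlations typical of session-to-session
microstate metrics. Planted effects add a shift to one state's duration
or occurrence weight in named condition × session × band cells.
`simulate_metrics_table` draws observed metrics directly from this
parameter model (measurement noise: 3 ms duration, 0.1 Hz occurrence),
which makes Monte-Carlo power studies feasible without re-running EEG
synthesis.

**What the generator does not emulate:** eye/cardiac artifacts (the
artifact mask is a pass-through hook), 1/f broadband background,
between-state topographic drift, electrode impedance drift, or any head
geometry. Passing tests demonstrate the machinery is correct under the
stated model, not that real EEG satisfies the model.

## Preprocessing

Zero-phase (forward-backward) order-4 Butterworth filters throughout, so
topography timing is never shifted: band-pass for the canonical bands
(δ 1–4, θ 4–8, α 8–12, β 15–30, γ 30–40, broadband 1–40 Hz; the 12–15 Hz
gap between α and β is deliberate and kept), an IIR band-stop 48–52 Hz
notch, polyphase anti-aliased resampling (2048 → 128 Hz), common-average
referencing, and Perrin spherical-spline channel interpolation (m = 4,
50 Legendre terms, regularisation 1e-5). ICA-based artifact removal is
out of scope; callers exclude artifact epochs via the per-sample mask.

## Two-level clustering

Maps at GFP local maxima (strict rise from the left, non-rise to the
right; plateaus count once; artifact-masked peaks dropped) are clustered
per recording with polarity-invariant K-means: assignment by maximal
squared spatial correlation; centroid update is the first principal
component of the assigned maps (sign-fixed for determinism), which is
the polarity-proof analogue of the mean. Restarts (default 10–20) are
scored by GEV; initial centroids are random smooth directions drawn from
the seed only, making results invariant to input row order. Empty
clusters are re-seeded from the worst-fitted sample. Per recording the
seven highest-GEV centroids (descending per-cluster explained variance)
are retained — seven because that is the maximum number of distinct
canonical microstate classes — and pooled across recordings per band for
the group-level run over a K range (default 2–8).

**Model order.** Seven criteria are computed on the polarity-invariant
distance d = 1 − corr²: Davies–Bouldin and the microstate
cross-validation criterion vote for their minimum; Gamma (Baker–Hubert),
Silhouette, robust Dunn (average-linkage separation / average diameter —
less outlier-sensitive than min/max), point-biserial, and Krzanowski–Lai
for their maximum (KL needs both neighbours in the range and abstains at
the ends; any criterion abstains where clustering is degenerate). The
modal vote wins; ties go to the smaller K. These are the classical
definitions; where published software offers unpublished variants, the
classical form was chosen.

**Labelling.** Group maps are assigned to canonical A–G templates by the
exact optimal one-to-one assignment maximising total |spatial
correlation| (Hungarian algorithm; exhaustive enumeration serves as the
test oracle). The bundled templates are synthetic idealisations built
analytically from electrode coordinates (A/B the two diagonal
orientations, C anterior–posterior, D/E fronto-central vs occipital
patterns, F/G left/right-lateralised extrema); they fix a reproducible
naming, not an empirical claim. The same routine aligns band-specific
models to a reference model across bands.

## Back-fitting and temporal metrics

Every sample is labelled by maximal |spatial correlation| with the group
maps (ties → lowest state index). Smoothing follows the published
iterative windowed scheme: each assigned sample's label is re-chosen to
minimise `GFP²ₜ(1 − corr²ₜₖ) / (2σ²) − besag · Nₖ(t)`, where σ² is the
mean residual of the current labelling and Nₖ(t) counts equal labels
within ±3 frames (Besag factor 10, ≤ 50 sweeps). Scaling the misfit by
the GFP makes low-power moments — oscillation zero crossings, where the
instantaneous topography is noise — defer to their temporal
neighbourhood, while strongly expressed topographies resist relabelling.
A plain `|corr| + 10·count` score was rejected: with counts in 0..6 it
degenerates to a majority filter that erases genuine short segments.

Segments shorter than 3 frames are dissolved sample-by-sample into the
neighbouring segment whose map correlates better (edge segments merge
inward; short segments with no assigned neighbour become unassigned),
repeated until stable.

**Threshold placement.** The 0.7 correlation threshold excludes noise.
Applied per sample *before* smoothing it unassigns ~20% of samples of a
narrow-band recording (every carrier zero crossing), splitting every
segment and capping measurable durations near the oscillation
half-period. The pipeline therefore assigns all samples, smooths,
rejects short segments, and then unassigns whole segments whose
GFP²-weighted mean |correlation| with their map is below 0.7 — brief
low-power moments inside a well-fitting segment do not split it, while
genuinely noisy stretches are excluded. A `threshold_mode: sample`
switch restores the literal per-sample order.

**Metrics.** Per state: mean duration = mean segment length × 1000/fs
(ms); occurrence = segment count / analysed time (Hz); coverage =
labelled samples / analysed samples. Analysed time excludes artifact-
masked samples but includes unassigned ones, making
occurrence × duration / 1000 = coverage an exact identity. Absent states
report occurrence 0 and missing duration.

**Known biases of the cleaning rules.** Segment rejection and the
threshold are censoring operations: rejection heals splits and removes
sub-24 ms segments (+~25% duration, −~20% occurrence on 80 ms planted
dynamics), and the threshold removes weakly expressed brief segments.
The same signature appears in real band-specific analyses (alpha-band
durations reported ~1.5× those of other bands). Parameter-recovery
validation therefore measures fit + smoothing (errors ≤ ~5% per state on
theta at SNR 5), and the full-cleaning bias is reported as a separate
diagnostic rather than hidden. Narrow-band filtering of fast-switching
topographies additionally mixes adjacent states in time (a 4 Hz-wide
zero-phase filter has an impulse response longer than one segment), so
map-recovery validation runs on the band-limited signal as generated.

## Statistics

Shapiro–Wilk justifies the nonparametric battery. The Wilcoxon
signed-rank test drops zero differences (Wilcoxon's rule), mid-ranks
ties, and computes the exact two-tailed p for n ≤ 25 by dynamic
programming over doubled ranks (exact under ties too; verified against
full 2ⁿ enumeration), with the tie-corrected normal approximation
beyond. The matched-pairs rank-biserial r_b is the Kerby simple
difference (favourable − unfavourable rank share), interpreted as
small < 0.10 ≤ medium < 0.37 ≤ high. FDR is Benjamini–Hochberg within
each (condition × band × parameter) family — the family choice is
configurable. Only within-condition pre-vs-post contrasts are computed;
between-condition comparisons are deliberately absent (conditions live
on different days).

**Coupling-corrected correlation test.** For change scores y − x that
contain the baseline x, corr(x, y − x) is negative under pure test-retest
coupling: with equal variances and observed coupling ρ̂ = corr(pre, post)
its expected value is r₀ = −√((1 − ρ̂)/2) (−0.707 at ρ̂ = 0). The
observed Spearman r(pre, post − pre) is therefore compared against r₀ by
a Fisher-z test with SE 1/√(n−3); the naive test against zero is also
reported for contrast. This analytic-null form is one defensible
instantiation of the regression-to-the-mean correction; a simulation-
based null would be an alternative.

## Validation experiment sizes

Desk-scale sizes, chosen to make each check conclusive: map recovery
uses 24 subjects × 240 s single-band recordings at SNR 5 (the study's
sample size and block length); temporal recovery one 300 s recording;
power and type-I 100 replicates of the 24-subject parameter model;
the coupling null 500 replicates at n = 24; metric identity 1000 random
segmentations; exact-test oracles 200 (Wilcoxon) and 50 (FDR) random
data sets. The planted lasting effect (+8 ms, one state, theta,
post1–post3) mirrors the crossover design's long-lived modulations.

## Limitations

Infomax ICA artifact rejection, TANOVA/topographic consistency tests,
source localisation, transition syntax/entropy analyses and
between-condition statistics are out of scope. The canonical A–G
templates are synthetic surrogates; labelling against them yields
consistent names, not anatomically validated identities. EDF export
writes 16-bit integer samples (≈5 significant digits); round-tripping
through EDF is quantisation-, not bit-exact.
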
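# Methods

## The soundscape ranking index

The package quantifies the acoustic quality of a habitat from one-minute
mono recordings (48 kHz in the default configuration). An expert aural
survey assigns each recording six categorical attributes: bird abundance
(no/few/many), species richness (none / up to two / more than two
species), perceived singing activity (0–100 % of the minute), traffic
type (none/continuous/intermittent), traffic intensity (zero/low/high),
and the presence of other anthropogenic sources. The soundscape ranking
index of recording ℓ is a weighted sum over these categories,

    SRI_ℓ = Σ_i c_i · N_{i,ℓ},

where each attribute level maps to one of five coefficients: c++ ∈ [2, 5]
for strong biophony (many birds, >2 species), c+ ∈ [0, 2] for moderate
biophony and for the *absence* of traffic, c0 = 0 for neutral absences,
c− ∈ [−2, 0] for moderate disturbance (continuous traffic, low
intensity), and c−− ∈ [−5, −2] for strong disturbance (intermittent
traffic, high intensity, other anthropogenic sources). Singing activity
contributes `frac · c++`, with the percentage quantized to
{0, 0.25, 0.5, 0.75, 1.0} over right-closed 25-point intervals. The score
is binned into three quality classes: poor (SRI < 0), medium
(0 ≤ SRI ≤ 2), good (SRI > 2). Multi-recording summaries use the mean;
per-site maps use the median of the per-recording scores.

One consequence of the printed mapping is worth noting: a completely
silent recording earns c+ twice (traffic type "none" and intensity
"zero") and therefore bins as "good" whenever c+ > 1. The package
implements the mapping exactly as defined and leaves any re-weighting to
the user.

## Acoustic features

Two feature families describe each recording; classifiers consume them
raw (no normalization or selection).

**Ecoacoustic indices.** Spectrograms use a 1024-point FFT with a
rectangular window and no overlap, giving a frequency resolution
FR = 46.875 Hz and a time resolution TR = 1/FR ≈ 0.0213 s at 48 kHz;
analysis is restricted to 0.1–12 kHz. Seven indices are computed with
their canonical published definitions: acoustic entropy H (product of
the normalized Shannon entropies of the Hilbert amplitude envelope and
of the mean spectrum), acoustic complexity ACI (per-bin summed absolute
intensity differences over summed intensity), NDSI ((B − A)/(B + A) with
biophony 2–8 kHz and anthrophony 1–2 kHz power), bioacoustic index BI
(trapezoidal dB·kHz area of the 2–8 kHz mean spectrum above its in-band
minimum), spectral centroid DSC (mean over frames of the per-frame
center of mass), acoustic diversity ADI (Shannon entropy of 1-kHz-band
occupancies above a −50 dB threshold relative to the spectrogram
maximum) and acoustic evenness AEI (Gini coefficient of the same
occupancy vector). Two integration patterns are supported: one
cumulative value per minute (the 7-feature schema) and a one-second
time-step series reduced by seven statistical descriptors — min, max,
mean, median, skewness, kurtosis, standard deviation — giving the
49-feature schema.

Because the source analysis names the indices but delegates their
formulas to the standard R ecoacoustics packages, the band edges and the
ADI threshold are exposed in `EcoParams` with the reference-default
values above; all are configurable. Expressing the ADI threshold
relative to the spectrogram maximum (rather than absolute dB) makes all
seven indices exactly invariant under amplitude scaling of the clip, so
per-clip full-scale normalization cannot distort them.

**MFCCs.** Twelve mel-frequency cepstral coefficients per one-second
Hamming window with 50 % overlap (119 windows per minute). Each window is
zero-padded to the next power of two, its power spectrum is pooled by 40
triangular filters with centers equally spaced on the mel scale
mel(f) = 2595·log10(1 + f/700) over 0–24 kHz, energies are floored at
ε = 1e−10 and logged, and an orthonormal type-II DCT yields the
cepstrum. Orders 1–12 are retained: order 0 is a loudness proxy, and
dropping it keeps the features scale-invariant (configurable). No
liftering or delta features. The 84-feature schema applies the seven
descriptors per coefficient order; the 1428-feature schema flattens the
119 × 12 matrix row-major and requires exactly 60 s input (strict mode),
since variable-length recordings would change the feature dimension.

**Descriptor conventions.** Standard deviation uses n−1; skewness is the
adjusted Fisher–Pearson estimator; kurtosis is population-moment excess
kurtosis (so [1, 2, 3] → −1.5); constant series define skewness and
kurtosis as 0. Missing per-second values are excluded from the
descriptors; a cumulative index that is undefined for a clip is imputed
with the table-level column median and flagged in a sidecar column.

## Weight optimization

The four free coefficients are enumerated on a grid with step Δc = 0.1:
c+ ∈ {0.1, …, 2.0} and c− ∈ {−2.0, …, −0.1} (20 values each),
c++ ∈ {2.0, …, 4.9} and c−− ∈ {−4.9, …, −2.0} (30 values each), i.e.
20² × 30² = 360,000 combinations. The published value counts and the
nominal [−5, 5] coefficient ranges cannot both hold at this step; the
package keeps the counts (inner boundary included, outer excluded) and
leaves every set overridable.

For each combination, the labels are scored and binned; the classes
become the target a classifier must predict from the features. The data
are split 80/20 with stratification (a fixed split seed across
combinations, so F1 differences reflect the weights only), the model is
fitted with inverse-frequency class weights W_j = T/(|j|·N), and macro
precision/recall/F1 (mean ± SD over the three classes) are recorded from
the test confusion matrix. A combination collapsing all recordings into
one class is recorded as unevaluable rather than fatal. All combinations
within 1e−12 of the maximal macro F1 are reported as the best set, as
per-coefficient intervals.

Four classifier families are wrapped from scikit-learn: decision tree,
random forest, RBF-kernel SVM in one-vs-all mode, and AdaBoost. Library
defaults are kept except max_depth = 5 for the tree models (the source
tunes this parameter without printing a value) and γ = inverse
feature-count-and-variance scaling for the SVM; class weights are
applied as per-sample weights uniformly across families. Zero-denominator
precision/recall are defined as 0 and flagged.

Two implementation notes. First, distinct weight combinations often
induce identical quality-label vectors; since the features and split
seed are fixed, such combinations provably yield identical metrics, so
evaluations are memoized on the label vector — results are bit-identical
to naive evaluation (asserted by a test) and the full 360,000-point grid
becomes tractable. Second, validation uses repeated stratified k-fold
cross-validation (k ∈ {2, 5, 10} with 200/100/100 repeats in the source
protocol), returning the per-fold macro-F1 sample for summary as
mean ± SD.

## Synthetic data

Because the field recordings are available only on request, the package
generates surrogates at the study's conditions (60 s, 48 kHz) for every
pipeline stage.

*Scenes*: bird song is emulated by quadratic FM chirp events
(0.08–0.35 s, smooth squared-sine envelopes) inside 2–8 kHz, with event
rate set by abundance (0/18/60 events · min⁻¹ at full activity) scaled
by the singing-activity fraction, and 2 or 4 distinct chirp motifs for
the two richness levels; traffic is 4th-order-Butterworth low-passed
noise below 2 kHz, continuous or gated into 1.5–4 s bursts for
intermittent traffic, at RMS 0.35/1.6 relative to the unit-RMS bird
track for low/high intensity; "other sources" adds a steady 120 Hz hum.
Mixtures are peak-normalized to −3 dBFS (keeping the relative ADI
threshold meaningful) over a −60 dBFS noise floor. Labels are validated
for internal consistency (e.g. abundance "no" forces zero activity).
These surrogates exercise band energy, temporal modulation and event
structure — what the indices actually measure — but are not realistic
avian vocalizations, contain no geophony, reverberation or recorder
coloration, and so say nothing about absolute index values on real
field audio.

*Feature tables*: labels are drawn attribute-wise (rejection-sampled to
balance the three quality classes induced by a chosen true weight set),
and features are class-conditional Gaussians with unit SD and means
separated by `class_separation` SDs per class step (default 6,
near-separable; 0 gives the null model). These tables validate the
optimizer: with separation 6 the grid search must recover weights whose
induced labels agree ≥ 95 % with the generating weights' labels, and
with separation 0 the best sub-grid F1 must stay near chance — a guard
against selection-bias bugs inflating scores. Passing both says the
search loop is correct, not that real features support any particular
F1.

## Problem sizes and numerical choices

The test suite and the acceptance script run on deliberately small
problems chosen to exercise every code path: scenes of 1–10 s for index
properties (plus single one-minute scenes for the frame/feature-count
checks), feature tables of 90–300 recordings, and 16–81-point sub-grids
for recovery/chance experiments; the structural quantities (grid
cardinality, resolutions, schema sizes, split sizes at n = 1220) are
computed exactly at full scale. Determinism: every stochastic component
takes an explicit seed; grid-search parallelism is not needed at these
sizes but per-combination evaluations are pure and order-independent.
Degenerate inputs raise typed errors (`DegenerateInputError`,
`UndefinedIndexError`, `ValidationError`, `ConfigurationError`) rather
than propagating NaN.

Known limitations: no recorder frequency-response correction; no
geophony in labels or scenes; per-clip full-scale normalization assumes
no cross-device amplitude calibration; headline F1 values of the
original field study depend on its non-deposited recordings and are out
of reach of synthetic data by construction.
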
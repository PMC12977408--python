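# Methods

This document records the scientific conventions implemented by `dyadsync`
and the reasoning behind the choices that a method name alone does not pin
down. Interfaces are described at the level needed to interpret results;
see the module docstrings for exact signatures.

## Experimental design assumed by the pipeline

Two participants per dyad — a Guide who sees a reference path through a
field of icons and a Drawer who moves a cursor — are recorded
simultaneously: 16 fNIRS channels per head at 7.81 Hz (two wavelengths,
760/850 nm, 3 cm source–detector separation), speech on/off streams and the
cursor trajectory at 10 Hz. A rest block precedes and follows the task. A
disruption in mid-task splits the session into *pre* and *post* periods;
dyads belong to a *control* or *experimental* group. Channels map onto six
regions of interest (ROIs): left/right frontopolar PFC, dorsolateral PFC
and temporoparietal junction, compared homotopically across heads.

## Preprocessing (per participant)

1. **Optical density.** `OD(t) = −ln(I(t) / mean(I))` per channel and
   wavelength, with the per-channel mean intensity over the whole recording
   as reference. If the true absorbance is `a(t)`, this reference makes
   `OD(t) = a(t) + ln(mean(e^{−a}))` — exact up to a per-channel constant,
   which the band-pass nature of all downstream analysis ignores.
2. **Motion detection** per channel: a sliding window flags samples where
   the signal change exceeds `sd_thresh` standard deviations or
   `amp_thresh` in amplitude within `t_motion` seconds; flagged windows are
   padded by `t_mask` seconds.
3. **Spline interpolation** (smoothing parameter `p = 0.99`) subtracts the
   slow excursion inside each flagged segment, re-leveling it to its
   neighbors. Segments shorter than 3 samples pass through with a warning.
4. **Wavelet correction** (Daubechies-2, stationary transform): detail
   coefficients outside `1.5 × IQR` are set to zero, removing isolated
   transients while preserving the band of interest.
5. **Systemic PCA filter.** Channels share cardiac (~1 Hz), Mayer (~0.1 Hz)
   and respiratory (~0.25 Hz) physiology. The spatial principal components
   accounting for the leading 80% of variance are **removed**. The
   configuration exposes `pca_mode: remove|keep` because the literature
   also contains the complementary convention; `remove` is the established
   systemic-noise-filter reading and the default.
6. **Modified Beer–Lambert law** with shipped extinction coefficients and
   partial pathlength factors converts OD to O2Hb/HHb concentration
   changes. The two-wavelength system is solved exactly per sample.
7. **Channel quality and ROI averaging.** A channel is good iff its Welch
   PSD (30-s Hann segments, 50% overlap) shows a cardiac peak: max power in
   0.8–1.2 Hz at least 2× the median power of the surrounding 0.5–2.5 Hz
   band. Good channels are averaged per ROI. A ROI whose channels are all
   bad is discarded; a participant missing more than one ROI is excluded
   (and with them their dyad).

## Wavelet transform coherence

The analytic Morlet wavelet with `omega0 = 6` is used at 12 voices per
octave. Coherence is the magnitude-squared cross-spectrum normalized by the
smoothed auto-spectra; smoothing is a Gaussian in time with standard
deviation equal to the scale, followed by a 0.6-octave boxcar across
scales. All transforms are FFT-based; the `CoherenceEngine` caches each
signal's transform and smoothed auto-spectrum so the all-pairs
permuted-dyad control costs one cross-smoothing per pair.

**Cone of influence.** Edge effects extend `tau(f) = sqrt(2)/f` seconds
into the record at frequency `f` (reported rounded up: 142 s — 2 min 22 s —
at 0.01 Hz; 18 s at 0.08 Hz). COI masking is applied on the *full* record
before cropping to the task window, so the flanking rest blocks absorb the
edge effects of the analysis band.

**Band and features.** Coherence is analyzed in 0.01–0.08 Hz, below the
systemic rhythms. Per dyad × ROI × period:

- **level** — mean coherence over valid (unmasked) time–frequency cells;
- **slope** — ordinary-least-squares slope (coherence per second) of the
  frequency-averaged coherence time series; at least 10 unmasked samples
  are required, otherwise the value is NaN (a flagged missing value, never
  silently imputed);
- **%DET** — determinism of the same time series via recurrence
  quantification: embedding dimension 1, radius selected per signal by
  bisection to a 10% ± 2% recurrence rate, Theiler window 1, minimum
  diagonal line length 40 samples. The recurrence rate and %DET exclude
  the Theiler band from numerator and denominator. `lmin = 40` (≈5 s at
  7.81 Hz) means %DET counts only sustained stretches of similar coherence;
  on short or weakly structured series it is legitimately 0.

**Permuted-dyad control.** Every Guide is re-paired with every Drawer they
never interacted with (`n(n−1)` permuted pairs for `n` dyads), and the
real-vs-permuted difference in pre-period IBS level is tested with
`level ~ DyadType + (1|ROI)`.

## Behavior

- **Speech features** per period: total speaking time (sum of both
  speakers' on-time) and the Guide/Drawer speech ratio. A silent Drawer
  makes the ratio undefined; it is flagged invalid rather than clamped.
- **Path error**: each trajectory sample's exact Euclidean distance to the
  nearest point of the reference polyline (closed-form point-to-segment
  projection, not sampling), summed and averaged per period.
- **Difficulty ratings** (one per participant per period) are modeled with
  individual-level random intercepts.

## Statistics

All hypothesis tests are likelihood-ratio tests (LRTs) between nested
linear mixed models fitted by **maximum likelihood**. REML likelihoods are
not comparable across different fixed-effects structures, so ML is the
default wherever a fixed effect is tested; a `reml_lrt` switch reproduces
the literal REML-comparison procedure for compatibility, clearly labeled.

- **Primary models:** `feature ~ Time × Group + (1|Dyad/ROI)` against the
  no-interaction reduced model, for each of level, slope and %DET. Time and
  Group are treatment-coded with *pre* and *control* as references. On
  non-convergence the random structure falls back to crossed intercepts
  `(1|Dyad) + (1|ROI)` with a logged notice.
- **Moderation:** behavioral change scores (post-minus-pre speaking time
  and speech ratio) enter as `Time × Group × Delta` with crossed random
  intercepts; the 4-degree-of-freedom LRT tests all delta-involving terms.
  The three-way design requires at least 4 alternating-group dyads to be
  identified; smaller studies record the analysis as skipped.
- **Effect sizes:** standardized betas (outcome- and design-column-SD
  scaled) with Wald confidence intervals, marginal R² (fixed-effects
  variance over total) and partial R² (marginal R² difference full vs
  reduced, floored at 0).
- **Degenerate data** (constant outcome) skips the affected test with a
  logged note rather than crashing or fabricating a p-value. Boundary
  variance estimates (a variance component at 0) are reported as such.
- **Sensitivity analysis:** Monte-Carlo power of the interaction LRT over
  an effect grid on tables simulated from the nested generative model; the
  minimal detectable effect at 80% power is linearly interpolated. At zero
  effect the rejection rate estimates the realized type-I error.

## Synthetic ground truth

The generator produces coupled dyad dynamics by mixing a shared latent
band-limited process into both partners' ROI signals with weight `kappa`
(`x = kappa·s + sqrt(1−kappa²)·p`), yielding an expected squared coherence
of `kappa⁴` above the smoothing floor. Systemic physiology enters as
narrowband quasi-periodic rhythms with low-rank spatial structure (so the
PCA filter can remove them without destroying the neural dynamics), HHb
co-varies negatively with O2Hb for neural dynamics and positively for
blood-volume rhythms, and dead optodes are cardiac-free noise. Because the
coupling parameter enters only arithmetically, identical seeds give
identical noise realizations across coupling levels — simulation studies
over `kappa` are automatically paired (common random numbers).

## Provenance

`run_pipeline` validates the full configuration against a single defaults
tree (unknown keys are rejected with the accepted alternatives listed),
caches per-participant preprocessing keyed by input-file and parameter
hashes (interrupted runs resume without recomputation), logs every stage
per dyad to a JSON-lines file, and records content hashes of all outputs
in `run_record.json`.
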
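# Methods

`synflux` quantifies presynaptic function from live-cell fluorescence
movies of cultured cortical neurons and validates every stage against a
synthetic-movie generator with known ground truth.  This note documents
the models, the parameters that matter, and the choices made where the
underlying experimental description left the design open.

## Quantification pipelines

### Vesicle pools (sypHy)

SypHy is synaptophysin carrying a pH-sensitive GFP in the vesicle lumen:
quenched at vesicular pH (~5.5), fluorescent once fusion exposes it to
neutral pH.  With bafilomycin A1 blocking re-acidification, the signal
is cumulative, so a recording at 1 frame/s reads out pool sizes
directly: a 15 s baseline, 40 AP @ 20 Hz (releasing the readily
releasable pool, RRP), 900 AP @ 20 Hz (the total recycling pool, TRP),
and a terminal NH4Cl pulse that unquenches every sypHy copy and defines
the total pool.

Processing follows the standard ImageJ-style recipe, stage by stage:

1. **Activity map** — pixel-wise max projection over the 70 frames after
   the 900 AP train minus the max projection of baseline frames 3–13,
   clipped at zero.  Only stimulus-responsive puncta survive this
   subtraction.
2. **Punctum detection** — Laplacian-of-Gaussian filtering at the PSF
   scale proposes blob candidates; non-maximum suppression enforces a
   minimum separation of 2 PSF sigmas; candidates are kept where the
   PSF-scale-smoothed map exceeds median + 5·MAD.  The median/MAD
   threshold makes detection exactly invariant to global intensity
   scaling and offsets.  This detector is a deliberately simple,
   deterministic stand-in for probabilistic synapse-detection plugins;
   it is validated against the generator's ground truth (precision and
   recall ≥ 0.9 at SNR 10) rather than against any external tool.
3. **Traces** — per-frame means over circular ROIs (default radius 3 px)
   at the detected centers, averaged into one trace per recording.
   Edge-clipped ROIs are dropped with a logged reason.
4. **Background** — one scalar per recording: the mean over pixels
   outside the union of ROIs dilated by 2 px, averaged over frames.
5. **Bleach correction** — a single exponential `a·exp(−t/τ)` is fitted
   to the background-subtracted mean trace of a paired no-stimulation
   recording; the stimulated trace is divided by `exp(−t/τ)` normalized
   to 1 at the first frame.  A fit with no measurable decay (τ longer
   than 50 recording lengths) degrades to the identity.  Fitting, rather
   than frame-wise division by the reference, avoids injecting the
   reference's shot noise.  The no-stim movie is quantified with the
   ROIs detected on the stimulated movie of the same field.
6. **Normalization** — `(F − F_min)/(F_max − F_min)` with `F_min` the
   mean of baseline frames 3–13 and `F_max` the mean over the NH4Cl
   window.  A window mean is used for `F_max` (robust to shot noise
   versus a single-frame max).  If the dynamic range does not exceed
   3 baseline SDs, there was no NH4Cl response and the recording is
   rejected.
7. **Pool fractions** — RRP = mean of normalized frames 23–37, TRP =
   mean of frames 130–159 (1-based inclusive).  Both windows are
   protocol data, not constants, so other timings remain usable.

The order background → bleach → normalization treats bleaching as
multiplicative on the background-free fluorescence, which is exactly how
the generator produces it.  Because normalization is affine-invariant,
the whole pipeline is invariant to rescaling the movie and adding an
offset — a property test asserts this.

### Paired-pulse glutamate (iGluSnFR)

Two field stimuli 100 ms apart, three epochs per recording (10 s
recovery), 60 frames/s.  Per epoch: F0 = mean of the 50 frames preceding
the first pulse (after background subtraction); P1 = post-pulse-1 peak −
F0.  Because the indicator has not fully decayed at the second pulse,
the trough between the peaks is subtracted from the raw second peak to
give the accumulation-corrected P2; PPR = P2/P1.  Peak searches use an
80 ms window after each pulse (configurable; the window must not reach
the next pulse).  Epochs whose P1 is below 3 baseline SDs are discarded
with a log entry (default-on quality control, disable with a flag);
epoch values are averaged into one value per recording.  PPR is
invariant to intensity scale and offset, and when the trace fully decays
between pulses the corrected P2 equals the naive baseline-subtracted P2
— both are property-tested.

### Evoked calcium (synGCaMP6)

Protocols: 5 single stimuli at 0.1 Hz (15 fps), 5 paired stimuli 100 ms
apart at 0.1 Hz (83 fps), and one 30 AP @ 40 Hz burst (15 fps), each
after a 15 s baseline.  Amplitude = peak dF/F0 in the post-stimulus
search window (300 ms for single stimuli; burst duration + 300 ms for
bursts) relative to the pre-stimulus F0, averaged per stimulation type
per recording.  The paired-stimulus amplitude is the raw accumulated
peak above the epoch baseline: the published group magnitudes (paired ≈
2.2× single under control conditions) identify it as the uncorrected
accumulated response, and the package follows that reading.

### Nuclear pCREB (ICC)

Nuclei are segmented from the nuclear-stain channel (Otsu + connected
components, specks < 40 px ignored); a nucleus is neuronal when its
centroid falls inside the Otsu-thresholded MAP2 mask dilated by 5 px —
a stand-in rule, since how MAP2-positivity was decided per nucleus is
not described.  A fixed-radius ROI (6 px; "spherical ROI" with no stated
size) at each centroid is transposed to the pCREB channel; the
per-nucleus mean minus the per-image background (mean outside all
nuclei dilated by 8 px) is recorded.  The visual field is the
statistical unit; field means are normalized to the same-experiment
control mean (CTRL ≡ 100 %), cancelling day-to-day staining and
illumination factors.

### Statistics

Per-group Shapiro–Wilk at α = 0.05 routes each table: all groups normal
→ one-way ANOVA + Dunnett versus control (unpaired t-test for exactly
two groups); any group non-normal (or n < 3) → Kruskal–Wallis + Dunn
versus control with Šidák family control over the control-vs-treatment
contrasts; tables with a second factor (external calcium) → two-way
ANOVA with Šidák-corrected within-condition contrasts.  Dunnett's
adjusted p-values come from the multivariate-t dependence structure
(scipy); the test suite cross-checks them against an independent
100 000-draw Monte-Carlo max-|t| null and verifies the ANOVA path's
empirical type-I error on 2000 null replicates.  α is fixed at 0.05; no
outlier removal.

## The synthetic-movie generator

Every punctum is an isotropic Gaussian spot (σ = 1.5 px — a
diffraction-limited bouton under a 60×/1.2 NA objective) at an integer
pixel position, with peak brightness drawn lognormally (CV 0.3).  Frames
are background + Σ brightness × kinetic(t) × bleach(t), with Poisson
shot noise on expected counts plus additive Gaussian read noise
(σ = 2 counts) — the usual EMCCD approximation — clipped at zero and
held under 16-bit full scale (a saturating punctum is an error).
Photobleaching is a single exponential with a ~300 s time constant of
illumination time, i.e. 300 frames at 1 fps and proportionally more at
higher frame rates.  Bleaching multiplies total punctum fluorescence
(quenched and unquenched sypHy alike); this matches the multiplicative
correction the pipeline applies and is a simplification — in reality
quenched fluorophores bleach more slowly.

**Condition presets.**  Each preset carries the published group means
for one treatment (vehicle control, LSD, DMT, psilocin): sypHy pool
fractions, paired-pulse ratio, evoked-calcium amplitudes, nuclear pCREB
level, and a relative glutamate-release scale (only the +50 % / +70 %
ratios for psilocin/DMT were published, so control is fixed at 1.0).
Per-recording parameters are drawn around the preset means with the
published across-recording CV (SD/mean) per metric; the glutamate P1
CV was not published and defaults to 0.15, on the grounds that each
recording already averages 30–80 release sites.  Per-punctum
heterogeneity (lognormal, CV 0.25; CV 0.10 for pool fractions) sits on
top with its mean preserved, so cohort means remain calibrated — an
ensemble-calibration test asserts this.

**sypHy kinetics.**  The unquenched fraction rises first-order during
each train (time constants 1 s for the RRP phase, 15 s for the TRP
phase), with the rise normalized to saturate exactly at train end —
release only happens while stimuli are delivered, and the analysis
windows then sit on exact plateaus, which makes the noise-free pipeline
an identity check to 1e-6.  The series is monotone (bafilomycin) and
steps to exactly 1 inside the NH4Cl window.  Resting (quenched) sypHy
fluorescence is 15 % of the unquenched level; normalization removes
this affine factor exactly.  The paired `syphy_nostim` modality renders
the same field (same centers, brightness, bleach) with no stimulus
response.

**Transient kinetics.**  Glutamate transients rise in one frame and
decay exponentially (τ = 80 ms); calcium transients likewise with
τ = 0.5 s; bursts ramp up over the train and peak at its end
(saturating summation).  Responses superpose additively.  For paired
pulses the second-pulse increment is calibrated numerically so that the
standard accumulation-corrected measurement applied to the noise-free
trace returns exactly the drawn PPR — the generator inverts the
measurement model, so the published group means are interpretable as
ground truth for the measured quantity rather than for an unobservable
microscopic parameter.

**External-calcium hook.**  Release probability scales with external
calcium (scale 1.0 at 2 mM, 0.55 at 1 mM).  P1 scales proportionally,
and PPR follows a two-pulse depletion/facilitation rule
PPR = φ·(1 − p) with baseline release probability p = 0.35, calibrated
so the 2 mM value equals the preset mean.  This reproduces the
qualitative low-calcium facilitation increase (ratio ≈ 1.24 at 1 mM)
without claiming a quantitative microscopic model.

**ICC fields.**  10–15 elliptical nuclei (semi-axes 6.5–10 px) per
256×256 field; ~75 % sit inside a MAP2-positive soma disk.  Neuronal
nuclear pCREB means are field level × per-nucleus lognormal (CV 0.3),
where the field level is the control level (120 counts over a
40-count background) × the preset's percent-of-control × a between-field
lognormal draw; non-neuronal nuclei are rendered at 60 % of the field
level and are excluded by the MAP2 gate.  In noise-free configurations
all draws collapse to their means, making the rendered field an exact
generator identity.

## Problem sizes and defaults

| modality | field | puncta | frame rate | frames |
|---|---|---|---|---|
| sypHy | 256×256 | 100–200 | 1 fps | 180 |
| iGluSnFR | 128×128 | 30–80 | 60 fps | 1651 |
| synGCaMP6 single/burst | 256×256 | 150–250 | 15 fps | 901 / 316 |
| synGCaMP6 paired | 256×256 | 150–250 | 83 fps | 4666 |

The live-imaging fields are crops of the camera frame (the reference
workflow likewise crops stacks before analysis); sizes were fixed once
so that full recovery cohorts (8–30 recordings per condition) render in
minutes on a single core while keeping punctum densities low enough
that ROI neighbourhoods stay uncontaminated.  Punctum peak brightness
defaults to 600 counts (sypHy, at full unquenching) or 300 counts
(resting iGluSnFR/GCaMP) over backgrounds of 100/80 counts.

## What the simulations do and do not show

Passing recovery tests demonstrates that the pipeline is an unbiased,
correctly normalized estimator of the generator's ground truth under
realistic shot/read noise, bleaching, punctum density and
between-recording dispersion — and that every printed formula (min-max
normalization, window means, the trough-subtraction rule, percent
change, CTRL normalization) is implemented exactly.  The generator does
not emulate focal or stage drift, z-structure, neuropil or diffuse
sensor background, spontaneous (non-evoked) activity, inter-punctum
kinetic correlations, or non-exponential bleaching; real recordings
violate these simplifications, so recovery here bounds algorithmic
error, not total experimental error.  Known residual biases, visible in
the tests: dF/F0 amplitudes run a few percent high in dense fields
(background over-estimation from undetected puncta plus PSF tails), and
detection preferentially keeps brighter puncta.  Both effects cancel in
ratios (PPR, percent-of-control) and are well inside the recovery
tolerances for amplitudes.

## Numerical choices and degenerate inputs

Protocol windows are 1-based inclusive (ImageJ slice convention) and
converted to 0-based half-open slices at exactly one place.  Bleach fits
run on log-linear initial guesses with a Levenberg–Marquardt refinement;
non-positive or non-finite references are errors, τ ≤ 0 is an error with
the fit diagnostics, and τ → ∞ degrades to the identity.  Detection on
an all-zero map, a trace with no NH4Cl response, zero neuronal nuclei,
an experiment without a control group, and all-constant statistical
groups are explicit errors rather than silent NaNs.  ROI radius 0
degrades to single-pixel sampling.  All simulation randomness flows
from integer seeds through `numpy.random.default_rng`; identical
(modality, preset, config, seed) gives bit-identical movies, and a
stimulated recording shares its field with its same-seed no-stim
reference.
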
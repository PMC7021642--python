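# Methods

`rtmseeg` implements the analysis chain of a three-arm (Real / active
control / sham) high-frequency rTMS trial in adult ADHD: an EEG biomarker
extracted from the quiet intervals between stimulation trains, scalp-level
statistics relating it to clinical improvement, TMS-evoked potential (TEP)
component contrasts, and the clinical outcome layer. Because no trial data
are distributed, the package ships a synthetic cohort generator with known
ground truth; every statistical claim the pipeline makes is validated by
recovering effects that the generator planted.

## The biomarker

During a treatment session, 18 Hz trains (2 s, 36 pulses) alternate with
20 s inter-train intervals (ITIs), measured from train end to the next
train onset — the only reading of the protocol under which the ITI
decomposes exactly into a 1 s artifact gap, seven 2 s analysis segments,
and a 5 s pre-train guard. Each ITI is segmented accordingly; epochs
overlapping artifact-flagged samples are dropped.

The marker is the ratio of low-gamma (30–40 Hz) to alpha (8–14.5 Hz)
absolute band power in the **first** post-train segment (seconds 1–3) of
the first session. The direction is gamma/alpha: low-gamma indexes the
transient cortical response evoked by the train (it decays across the ITI),
alpha a stable, trait-like level of cortical inhibition (it does not), so a
large marker means a cortex that responds strongly relative to its tonic
inhibition — and the marker's correlation with symptom improvement comes
out positive. Both orientations of the ratio circulate in this literature;
we fix gamma/alpha, the direction consistent with the sign structure of
the components (alpha negatively, gamma positively coupled to
improvement), and expose `invert` for the reciprocal convention.

Band powers come from Welch periodograms (Hann window, 1 s segments, 50%
overlap → 1 Hz resolution on 2 s epochs), integrated over the band by the
trapezoid rule on the frequency grid, endpoints inclusive. Marker values
are log-transformed before correlation by default — power ratios are
right-skewed — with a flag for the linear scale.

## Referencing

Two reference schemes are supported and reported separately:

* **AVR** — average reference; subtracts the instantaneous cross-channel
  mean.
* **CSD** — current source density, concretised as the Perrin-style
  spherical-spline surface Laplacian with stiffness m = 4, regularisation
  λ = 1e-5, 50 Legendre terms and a 9.5 cm head radius — the community
  defaults; "CSD" alone underdetermines the algorithm, so the concrete
  choice is fixed here and exposed as parameters. The
  transform is precomputed as a 64×64 linear operator; it annihilates the
  spatial constant, so raw and AVR input give identical CSD output. The
  implementation is cross-checked in the test suite against MNE-Python's
  independent spherical-spline CSD to ~1e-12 relative error.

Both references are linear per sample, hence commute with epoch selection;
reference transitions are recorded on the epoch container and double
referencing is an error, never silent.

## Montage

The emulated setting is a TMS-compatible 64-channel cap with 54 lateral
electrodes; the exact label set is this package's explicit choice of a
standard layout: 10 midline channels (Fpz, AFz,
Fz, FCz, Cz, CPz, Pz, POz, Oz, Iz) and 27 mirror pairs including the
mastoids M1/M2. Positions are generated analytically on the unit sphere
from regularised 10-10 angles (18° grid), which makes left/right positions
exact sagittal reflections and needs no coordinate files. The channel
adjacency used by cluster statistics is a great-circle threshold graph;
the default threshold (0.46 rad) gives degrees between 3 and 8 (median 7),
is connected, and is invariant under the left↔right relabeling — so scalp
statistics commute with mirroring.

## Scalp statistics

**Cluster-based permutation test.** Per-channel statistics (Pearson r
against a covariate, independent or paired t, or a one-way F across arms)
are thresholded at the two-tailed α = 0.05 critical value, suprathreshold
channels are clustered by adjacency separately per sign, each cluster is
scored by the sum of its member statistics, and observed masses are
referred to the Monte-Carlo distribution of the maximum absolute mass
under design-appropriate relabelings (covariate shuffles, group
relabelings, sign flips). p = (1 + #{null ≥ observed})/(1 + n_perm), which
cannot return zero; the seed is mandatory. Zero-variance channels are
excluded with a warning. The test suite checks the implementation against
exhaustive enumeration on ≤ 7-subject instances and verifies family-wise
error control on 200 spatially correlated null cohorts.

**Inter-hemispheric balance model.** Per lateral channel e: the
first-order partial correlation between the (log-)marker at e and
improvement, controlling for the homologous contralateral channel —
removing the variance the two hemispheres share. The permutation machinery
does not compose with this two-step residualisation, so inference is
parametric (t with df = n − 3) with Benjamini–Hochberg FDR over the 54
lateral channels. A restricted variant runs the same model for resting
alpha power over the eight prefrontal channels FC4, FC2, F4, F2 and their
left homologues, FDR over that set. The dual-channel explained variance is
the OLS R² of improvement on {e, pair(e)}.

**ITI dynamics.** Per band and subject, power in ITI segment k is divided
by segment-1 power; the segment × band repeated-measures ANOVA
(pingouin's implementation; segments 2..7, both bands) tests the
divergence of gamma decay from alpha stability. Degrees of freedom are
always derived from the data and design actually analysed, never assumed.

## Clinical layer

Improvement is the pre-to-post drop of the standardized total-symptom
t-score (population mean 50, SD 10). The 2-way mixed ANOVA (time within,
group between) uses the classical sums-of-squares decomposition — with two
time levels it splits exactly into a between-subject ANOVA on subject
means and a within-subject ANOVA on change scores, valid for unbalanced
groups; it matches pingouin's mixed ANOVA to machine precision. Post-hocs
are per-group pre-vs-post F tests against the within error, Bonferroni ×
number of groups. Effect sizes: partial η² = F·df1/(F·df1 + df2);
Cohen's d with the pooled SD (several d variants circulate; comparisons
against other reports should verify the convention). Responders
have ≥ 25% reduction of the **raw** score (boundary inclusive); rates are
contrasted by Fisher's exact test, two-sided by the probability-mass
convention (scipy's implementation behind the module surface).

## The synthetic cohort generator

The generator is the package's test bed: its defaults are the study
conditions (n = 15/14/14; 40 trains × 2 s × 18 Hz, 20 s ITIs, 1440 pulses
per session; 50 TEP pulses 5 s apart; 500 Hz sampling; baseline t-scores
≈ N(76, 8)). Signals are sums of

* 1/f background noise (3 µV per channel, independent across channels);
* alpha: narrowband noise (±1.5 Hz around the subject's individual alpha
  frequency, drawn from 9–11.5 Hz), amplitude `alpha_amp` (log-normal,
  median 8 µV, σ_log 0.4), an occipitally emphasised topography, a
  left/right weighting exp(±asym/2), and a small per-session amplitude
  wobble (σ_log 0.05). Channel realisations are independent — like real
  alpha, the rhythm is not phase-locked across the scalp, which is what
  lets it survive average referencing;
* low-gamma: 30–40 Hz band noise with a Gaussian right-prefrontal
  topography centred on FC4 (width 0.9 rad). Its envelope is the resting
  level `rest_gamma` (log-normal, median 2 µV) plus, after each train,
  `gamma_resp · exp(−t/τ)` with `gamma_resp` log-normal (median 15.7 µV,
  σ_log 0.5) and τ log-normal (median 3 s, σ_log 0.2). The evoked term is
  scaled 1 / 0.25 / 0 for Real / AC / sham — the sham arm keeps its
  resting gamma pattern during treatment, the focal off-target AC
  stimulation evokes a response comparable to the resting floor
  (attenuating but not abolishing the rest-vs-treatment correlation), and
  the Real response dominates it;
* during trains, samples are saturated and flagged; the segmentation must
  avoid them. No attempt is made to simulate realistic TMS artifact decay:
  the analysis windows are designed around the artifact, so only the
  avoidance logic needs exercising;
* TEPs: Gaussian deflections at 45/60/75/100/180 ms with the canonical
  alternating polarity, amplitudes 3.5/3/5/4.5/3.5 µV (sized so that
  50-pulse TOI estimates resolve a treatment-scale change at trial-size
  groups), an F4-centred topography, a per-subject log-normal scale, and a
  ±300 µV artifact burst over −2..10 ms around each pulse. The planted
  treatment effect multiplies the Real group's post-treatment N75 by 0.6.

Clinical improvement is planted as

    improvement = β₀ + β₁·log(gamma_resp/alpha_amp) + β₂·asym + ε

for the Real group (β₀ = 2 t-points of nonspecific gain; ε ~ N(0, 2.75));
controls receive β₁ = β₂ = 0 with noise matched to the Real group's total
SD. The defaults (β₁ = 9.3, β₂ = 8.2, asym ~ N(0, 0.3)) give a Real-group
mean improvement of ≈ 8.3 t-points (SD ≈ 7), an FC4 marker–improvement
correlation of ≈ 0.85 and a dual-channel explained-variance ceiling of
≈ 85%. Raw scores are modelled as t − 30, which puts the ≥ 25%-reduction
responder rule near 40% (Real) and 7% (sham).

**Planted-correlation bookkeeping.** The population correlation between
the *measured* FC4 log marker and improvement is computed in closed form
by Gauss–Hermite quadrature over the generative traits: the gamma half of
the marker is `½·log` of the window-averaged power of
`gamma_resp·e^(−t/τ) + rest_gamma` over seconds 1–3, integrated over the
log-normal (gamma_resp, rest_gamma, τ) distribution; the alpha half
contributes its trait variance, the session wobble, and the asym/2
leakage. `CohortConfig.with_target_r(r)` inverts this relation for β₁, so
"plant r = 0.9" refers to exactly the quantity the pipeline estimates.
The quadrature is verified against a direct Monte-Carlo simulation of the
generative model in the tests; the remaining unmodelled attenuation
(spectral estimation noise, the 1/f floor inside the analysis bands) is
below 2% of the correlation at the problem sizes used.

Every random quantity derives from the cohort seed through per-subject
`SeedSequence` spawns; recordings are synthesised lazily (a full cohort of
continuous 64-channel sessions would not fit in memory) and are
bit-identical across regenerations, which the manifest checksums verify.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: volume conduction and realistic source mixing;
ocular/muscle artifacts (and with them the question of whether in-treatment
low-gamma is cortical or myogenic, which the trial itself leaves open);
realistic TMS artifact waveforms; non-stationary alpha reactivity;
dropout, missing sessions, and rater effects in the clinical scores.

## Problem sizes and numerical choices

Validation suites run at reduced sizes chosen to keep each battery's
Monte-Carlo error well inside the property being asserted: 250 Hz
sampling (the 30–40 Hz band needs ≥ 200 Hz), 4–20 trains per session
instead of 40, 200 replicates for calibration batteries (two-sided MC
band 2·SE ≈ 0.031 around α = 0.05), 8–12 replicates for power batteries,
n = 100 subjects for tight correlation recovery (sampling SE ≈ 0.02 at
r = 0.9). The analysis scripts use a trial-sized cohort (15/14/14, 12
trains, 50 TEP pulses). Generator defaults always remain the full
protocol.

Other numerics: permutation p-values use the add-one estimator;
degenerate inputs (zero-variance channels, missing homologues, subjects
missing segment 1, unpaired TEP sessions) are excluded with warnings
rather than errors wherever the analysis can proceed without them, and
errors otherwise; the TEP artifact window −2..10 ms and baseline
−200..−10 ms clear the earliest component's window with margin; TOI
bounds default to N45 [35,55], P60 [55,70], N75 [70,90] (the one range
anchored in prior reports), N100 [90,130], P180 [150,250] ms, all
overridable; TOI statistics use mean amplitude with signed peak as an
option.

## Known limitations

* The balance model's parametric p-values assume bivariate normality of
  the residualised pairs; with n = 15 and log-transformed power ratios
  this is an approximation.
* Under the default β-split, the resting-alpha balance model recovers the
  FC4-negative coupling in >90% of trial-sized cohorts but the weaker
  FC3-positive leg only in ~70% — the joint sign pattern is
  underpowered at n = 15, matching the exploratory status of that
  analysis.
* The cluster test's interaction screen for TEPs (one-way F on change
  scores) is a pragmatic stand-in for a full mixed-model interaction
  statistic.
* EDF export requires an optional backend (`edfio`); without it, cohorts
  are stored in the package's npz + JSON container. EDF *reading* works
  through MNE.
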
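# Methods

This note documents the models, numerical choices and limitations behind
`ratvar`. It is written for users who need to judge what the pipeline
computes and what passing its tests does and does not demonstrate.

## Signal model and beat extraction

The package treats an arterial-pressure recording as a uniformly sampled
trace (default 2 kHz) containing one systolic peak per cardiac cycle.
Systolic peaks are local maxima whose *prominence* exceeds 10% of the
overall signal excursion; prominence is used instead of an absolute
threshold so that detection is invariant to constant offsets and to slow
baseline drift relative to the pulse amplitude. A first prominence-only
pass estimates the median pulse interval; the final pass enforces a
refractory period of 0.4 × that median, which suppresses secondary
(dicrotic) maxima at rat heart rates of roughly 300–450 bpm. A trace
whose total excursion is below 1 mmHg is reported as "no beats detected"
rather than yielding spurious peaks; NaN samples are rejected outright.

Per beat, SAP is the peak sample, DAP the minimum between that peak and
the next, and the per-beat mean pressure the sample average over the same
span. The pulse interval PI is defined systolic-peak-to-systolic-peak so
that the tachogram and systogram share beat indexing, which the
coincident-fragment selection requires. The recording-level summary uses
HR = 60000 / mean(PI) (an exact unit contract, tested as such), per-beat
means for SAP/DAP, and a PI-weighted time average of the per-beat mean
pressure for MAP (i.e. MAP is measured from the signal, not approximated
as DAP + PP/3; the approximation is used only as a fallback for beat
series read from files that carry no waveform information).

## Stationary-fragment selection

Spectral parameters are estimated on stationary stretches of about 300
beats. A sliding window qualifies when, split into thirds, the
sub-window means differ by less than `k_mean` × the window SD and the
sub-window variances differ by less than `k_var` × the window variance
(defaults 0.5 and 1.0). These thresholds were chosen so that genuine
white noise of the target length virtually always qualifies, while a
mean step of a few SDs excludes every window that substantially straddles
it; windows that overlap a disturbance by only a handful of beats can
still qualify, which is the usual price of any finite-sample
stationarity screen. Qualifying windows are taken non-overlapping,
greedily left to right. For the joint tachogram/systogram analysis a
window must qualify in both series; the pair then shares the tachogram's
mean beat interval. "No stationary fragment" and "series shorter than
the window" are distinct errors.

## AR spectral decomposition

Each mean-centred fragment is fitted with an autoregressive model
`x_k = Σ a_i x_{k-i} + e_k` by the Burg recursion, which minimizes
forward plus backward prediction error and guarantees a stable model
(all characteristic roots strictly inside the unit circle). The model
order is chosen by AIC(p) = n·ln(σ²_p) + 2p over p = 8–20 (configurable);
ties break toward the smaller order. On white noise AIC usually bottoms
out at the lower boundary, but spurious reflection coefficients of size
~n^(-1/2) push it higher in a noticeable fraction of realizations — this
is a property of AIC, not a defect, and the tests treat it
distributionally.

The characteristic polynomial is factored (numpy root finding); each
real root contributes one spectral component and each complex-conjugate
pair one oscillatory component. Component powers are residues of the
spectral density at the poles (doubled for a pair), so they sum to the
AR-implied process variance; the test suite verifies this against direct
numerical quadrature of the spectral density to 0.5%. Residue powers of
tightly clustered poles can be marginally negative; band sums are floored
at zero. Poles with |z| > 0.9995 trigger an ill-conditioning warning —
note that a nearly deterministic sinusoid legitimately produces such
poles.

Pole angles are cycles-per-beat frequencies; they are mapped to Hz by
dividing by the fragment's mean beat interval (s), the standard
convention for beat-sampled cardiovascular series, and assigned to the
rat bands VLF [0, 0.2), LF [0.2, 0.75), HF [0.75, 3.0] Hz (half-open
lower edges give deterministic boundary behaviour). Components above
3 Hz are excluded from band sums. Total HRV (ms²) and SAPV (mmHg²) are
defined as the fragment variance, not the AR-implied variance; the two
agree to ~1% for well-conditioned fits.

## Indices and aggregation

LF/HF and α_LF = √(LF_HRV/LF_SAPV) are ratios, so they are computed per
animal and then averaged across a group; the group mean of per-animal
ratios differs systematically from the ratio of group means (Jensen
gap), which is why the two must not be interchanged when comparing
against published group tables. When an animal yields several stationary
fragments, absolute band powers and peak frequencies are first averaged
across its fragments and the ratio indices computed from those per-animal
averages. A zero denominator (HF power, or systogram LF power) makes the
corresponding index missing (NaN), never infinite; missing values are
excluded per field during aggregation, with counts reported. Normalized
units are recomputed from the averaged powers, so LF nu + HF nu = 100
holds exactly whenever both powers are defined.

## Factorial statistics

The 2×2 design (diabetes × renal denervation) is analyzed with an
unbalanced two-way ANOVA using Type-III sums of squares under
sum-to-zero contrasts. In a 2×2 each effect has one degree of freedom,
so the Type-III test of an effect is the F-test of its sum-coded
regression coefficient; the implementation is a closed-form OLS in
numpy, and statsmodels' `anova_lm(typ=3)` serves as an independent
oracle in the tests (agreement to machine precision). The cell means,
SDs and counts are sufficient statistics for this model, so the ANOVA
can be reconstructed exactly from printed per-cell summaries by
generating a deterministic sample with exactly those moments — useful
for verifying published tables without raw data.

The Student–Newman–Keuls post-hoc ranks the four cell means and compares
span extremes against studentized-range critical values whose parameter
is the span size, proceeding from the widest span downward; a
non-significant span is homogenized (nothing nested inside it is
tested), which guarantees that no significant pair is ever inside a
non-significant span. With unequal group sizes the standard error uses
the pooled within-group mean square and the harmonic mean of the two
group sizes — the common textbook extension. For two groups the
procedure reduces exactly to a two-sided pooled t-test.

Urinary albumin is log-transformed (natural log) before analysis, and
displayed as median [quartile interval]. Densitometric values are
normalized per membrane so that the control-group mean is 100 AU; pooled
control means across membranes therefore average near, but not exactly,
100. Percent differences and fold changes default to nearest-integer
display, matching the convention of narrative results ("~12% higher",
"4-fold"); the exact values are always available.

## Synthetic-data generator

The generator is the test harness's ground truth and emulates the study
conditions of a streptozotocin-diabetic SHR renal-denervation experiment:

* **Beat series.** PI_k = mean PI + LF and HF sinusoids + white Gaussian
  noise, with beat times accumulated from successive PIs; the SAP series
  is built the same way. Sinusoid band powers are analytic (A²/2), which
  gives every spectral test an exact target. Non-positive PI draws are
  clipped at 10 ms with a logged warning; systolic draws that fall to the
  diastolic level are clipped just above it.
* **Waveform.** Each beat peaks at its systolic value exactly at its
  beat time, decays exponentially to its diastolic value and rises
  linearly (25 ms upstroke) into the next peak. Morphology is
  deliberately schematic: only extrema and timing matter downstream.
  Per-beat extrema match the beat series within one sample's
  interpolation error at 2 kHz, and simulate → detect round-trips
  recover the beat count exactly and PI within 1 ms.
* **Cohorts.** Four groups spanning the factor grid, with per-group
  Gaussian outcome distributions parameterized from the reference group
  tables (sizes 7/6/6/5); urinary albumin is log-normal with moments
  matched to the printed median and bracketed interval (both the
  interquartile and the min–max reading of the bracket are supported,
  defaulting to interquartile). Initial glycemia in diabetic groups is
  drawn truncated above the 300 mg/dL induction threshold because the
  design describes the cohort that passed inclusion; day-45 glycemia is
  untruncated. Sinusoid amplitudes are set to √(2 × printed band power)
  and the white-noise SD absorbs the remaining printed total
  variability. One printed systogram row (RD-STZ-SHR) is internally
  inconsistent — LF + HF powers exceed the printed total — so its noise
  SD is floored at 1 mmHg and the simulated total exceeds the printed
  one.

What the generator does **not** emulate: closed-loop baroreflex coupling
between PI and SAP (their oscillations are phenomenologically parallel,
not causally linked), 1/f fractal variability, respiration-locked
nonstationarity, movement artefacts, and measurement noise of real
catheter systems. Passing tests therefore demonstrate the correctness of
the *analysis* (detection, estimation, decomposition, statistics) under
known ground truth, not the physiological fidelity of any simulated
index value; in particular, group-level spectral means of the simulated
cohort inflate printed band powers by the share of broadband noise that
falls in each band.

## Problem sizes and determinism

Defaults: 1000 beats per simulated animal (up to three 300-beat
fragments), 2 kHz waveforms, AR orders 8–20. The factorial
power/type-I-error checks use 200 replicates at n = 50/group for the
effect detection and 1000 replicates for the null rejection rate; the
sinusoid-recovery check uses 200 replicates of 300 beats. All randomness
flows from a single integer seed through `numpy.random.SeedSequence`
(one stream per group), so identical design + seed reproduces outputs
byte-for-byte.

## Known limitations

* Beat detection assumes a dominant systolic peak per cycle; signals
  with severe dicrotic notches of comparable prominence would need a
  stricter refractory fraction.
* The stationarity screen is a heuristic; it admits windows that clip
  the first/last few beats of a disturbance.
* SNK controls the familywise error only under the complete null, as is
  well known for the procedure; it is provided because it is the
  convention in this literature, not because it is optimal.
* The "HRD" group label that appears in some narrative albumin results
  of the emulated study is undefined there; it is presumed to mean
  RD-SHR and is not encoded anywhere in this package.
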
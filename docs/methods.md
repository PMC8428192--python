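# Methods

This note documents the models, conventions and numerical choices behind
`fraghr`, in the order data flows through the package.

## NN-series extraction (`nn_io`)

Beat annotations are (time, label) records with labels N (normal sinus),
S/V (supraventricular/ventricular ectopy) and A (artifact); unknown labels
are coerced to A with a warning rather than rejected, since artifact is the
conservative reading of an unrecognised code.  Sleep stages come in fixed
30-s epochs.

The analysis window runs from **sleep onset** (start of the first non-Wake
epoch) to **sleep termination** (end of the last non-Wake epoch).  Wake
time inside this window is retained; stage changes never break the series.
An NN interval is kept only if both bounding beats are labeled N and lie in
the window.  Every excluded beat starts a new *run*, and successive
differences (the basis of both the fragmentation symbols and rMSSD) are
computed within runs only, so an ectopic beat removes exactly the two
intervals adjacent to it and contributes nothing to any difference
statistic.

Inter-beat intervals above **3000 ms** are treated as annotation gaps: the
pseudo-interval is discarded and a run boundary inserted.  Physiologic NN
intervals essentially never exceed 3 s; anything longer indicates missed
beats, and carrying it forward would corrupt both the symbolization and the
spectral estimates.  Intervals are stored in milliseconds throughout;
thresholds expressed in seconds (n/SF) are converted at use sites.

Subject eligibility requires ≥ 120 minutes of combined REM + non-REM sleep
(0.5 min per non-Wake epoch).  Beat and epoch clocks are assumed aligned;
no resynchronization is attempted.

## Fragmentation metrics (`hrf`)

Successive differences ΔNN are symbolized on {−1, 0, +1} with the no-change
band (−n/SF, n/SF), n = 1 by default.  Boundary values — which occur
exactly when NN values sit on the ECG sampling grid — classify as ±1 per
the non-strict inequalities.  The comparison uses a relative tolerance of
1e−9 on the quantum so grid-exact differences are not misclassified by
float round-off.

Inflections are evaluated on the quantized symbols, not raw ΔNN, so the
no-change band and the inflection rule are mutually consistent: a pair is a
hard inflection iff the symbols are opposite nonzero signs, soft iff
exactly one is zero, and a (0, 0) pair is never an inflection.

- **PIP** = 100 · (hard + soft) / (within-run adjacent symbol pairs).  The
  denominator convention (evaluated pairs rather than NN intervals) is
  recorded in the output metadata; the two normalizations agree
  asymptotically for long series.
- **PNNLS** = 100 · (ΔNN in nonzero segments of length ≥ 3) / (all ΔNN).
- **PNNSS** = 100 · (ΔNN in nonzero segments of length < 3) / (ΔNN in
  nonzero segments of any length).

Counts are pooled across runs (no per-run averaging), so each subject is
one sample.  Undefined metrics (empty denominators) are NaN with a warning,
never 0 — a short all-zero-symbol recording has *no* fragmentation value,
not a fragmentation of zero.

Because PNNSS and PNNLS use different denominators they sum to 100 exactly
only when no zero symbols occur; this identity is enforced in tests.

## HRV indices (`hrv`)

The series is partitioned into tumbling (non-overlapping) 300-s windows
anchored at sleep onset; an interval belongs to the window containing its
terminating beat time (half-open [start, start + 300)), and a trailing
partial window is dropped.  A window qualifies if it has **≥ 150 NN
intervals** and its NN intervals cover **≥ 75% of the window duration**.
The coverage reading of the NN-fraction rule is used because the
complementary reading (excluding windows with *more* than 75% NN content)
would discard nearly all clean data; coverage is computable from the NN
series alone and penalises both ectopy and gaps.

Per window: mean NN, sample SD (N−1 divisor), and rMSSD over within-run
successive differences, all in ms.  AVNN is the mean of qualified-window
means — keeping all four indices on the single windows-then-average rule;
for near-complete nights this is indistinguishable from the whole-night
mean.

HF power (0.15–0.4 Hz, ms²) comes from the Lomb periodogram of the
mean-subtracted NN values at their uneven beat times: grid from 1/300 Hz to
half the mean beat rate at 4× oversampling, trapezoidal band integration.
The raw periodogram is converted to a density with the **2T/N factor**
(T = window span, N = points), which makes the full-spectrum integral equal
the series variance for evenly sampled data and gives A²/2 for an in-band
tone of amplitude A.  The alternative of rescaling each spectrum so its
full-grid integral equals the variance was rejected: when beat times are
modulated by the NN values themselves (always the case for interbeat data),
a pure in-band tone sheds a spurious harmonic at twice its frequency, and
self-normalization lets that artifact steal ~15–20% of the in-band power.
With the absolute normalization a 0.25 Hz, 50 ms tone over 300 s yields
1243 ms² against the 1250 ms² closed form (< 1% error).  Windows with fewer
than 16 points return NaN.  Subject-level values average each index in
linear units over qualified windows; ln transforms are applied once to the
aggregated rMSSD, SDNN and HF.

## Synthetic NN generator (`synth.simulate_nn`)

Beat-by-beat model:

    NN_i = mean + A·sin(2π f_r t_i) + ε_i + alternation term,

quantized to the 1/SF grid (the origin of the no-change quantum), with beat
times accumulating the generated intervals.  With per-beat probability p a
two-beat alternation event fires (+δ then −δ), modelling fragmentation as
an intermittent beat-to-beat reversal process — a phenomenological choice,
not a mechanistic one.  Ectopic beats replace normal beats at a Poisson
rate per hour and split runs exactly as in real extraction.

Defaults: mean NN 950 ms (sleep heart rate ~63 bpm), respiratory frequency
0.25 Hz (15 breaths/min), amplitude 30 ms, Gaussian noise 5 ms, δ = 25 ms,
SF 256 Hz, duration 1800 s.  Parameter combinations driving NN ≤ 200 ms are
rejected as non-physiologic.

Both A (genuine vagal modulation) and (p, δ) (fragmentation) inflate rMSSD
and HF — deliberately confounded, since separating them is precisely what
the fragmentation metrics add.  What the generator does **not** emulate:
sleep-stage-dependent dynamics, baroreflex feedback, apnea-related cyclic
variation, circadian drift, or realistic artifact morphology.  Passing
tests therefore show the metrics behave correctly on a controlled
oscillation + reversal process, not that they are robust to every
real-world PSG pathology.

### Age-sweep mapping

The age-sweep experiment maps age → (A, p) over 55–85 years:
A = 48 − 1.2·(age − 55) ms and p = 0.12 + 0.009·(age − 55) +
0.0003·(age − 55)², with δ = 35 ms.  Amplitude decays linearly (declining
vagal modulation); the event probability rises with a mild convexity,
reflecting accelerating accumulation of fragmented dynamics at older ages.
This shape was chosen so the construction exhibits the canonical contrast
the sweep is designed to demonstrate: fragmentation indices rise monotonely
and near-linearly with age, while rMSSD/SDNN trace a U (high in the young
from modulation, high in the old from fragmentation).  A linear p-profile
under a steep amplitude decline instead produces a sigmoidal PIP trend,
because alternation events are partially masked while A is large and PIP
saturates near its ceiling at high p.

## Synthetic cohort generator (`synth.simulate_cohort`)

Per subject: age ~ N(68, 9²); a PNNSS-like exposure
66.3 + 0.8·(age − 68) + N(0, 11.7²), clipped to [0, 100] — implied
population SD ≈ 13.7%, rising with age; sex (46% male), three education
levels (30/24/46%), income indicator (29%), log-normal NT-proBNP
(ln-scale 4.21 ± 0.96).  The exam-1 score follows a linear model on
*population*-standardized covariates (defaults: intercept 88, −1.3 per SD
age, −0.5 per SD exposure, education effects 0/+3.4/+4.2, −0.5 male,
residual SD 7); the exam-2 score adds a change model whose decline steepens
with age and exposure (−0.8 and −0.44 per SD) plus mild regression to the
mean (−0.1 per nominal baseline SD of 7.5) and residual SD 5.5, with
follow-up fixed at 6.4 years.  Population (not sample) standardization
makes the per-SD coefficients structural constants and, combined with
per-subject RNG substreams spawned from the global seed, guarantees that
growing the cohort never changes earlier subjects.

These frequencies and effect sizes are config-driven defaults chosen to be
demographically realistic for an older multi-ethnic cohort; they are a test
bed for the estimation machinery, not a claim of replicating any particular
study population.

## Regression program (`cohort`)

- **Transforms:** ln for rMSSD, SDNN, HF, physical activity, NT-proBNP;
  ln(x+1) for the zero-inflated pack-years, %time SpO₂<90, ODI and CAC.
  The applied registry is returned with the table; negative inputs error
  with the offending column and row.
- **Standardization:** z-scores over non-missing rows with a scaling
  registry, so coefficients are per one-SD increments; outcomes stay on
  their native scale.
- **Fits:** OLS on complete cases, t-based 95% CIs, two-sided p-values,
  adjusted R², Gaussian log-likelihood.  Rank-deficient designs error with
  the collinear terms listed.  The five standard adjustment sets (none;
  dementia risk score; demographics + education; fully adjusted CV/
  behavioral/socioeconomic; + NT-proBNP) are predefined; the dementia risk
  score is accepted as a precomputed column.
- **Change-score models:** ΔY on Y₁ + exposure + covariates.  The
  algebraic equivalence with regressing Y₂ on the same design (identical
  slopes; Y₁ slope shifted by exactly 1) is asserted in tests to 1e−10.
- **LRT:** 2·(llₑ − ll_b) = n·ln(RSS_b/RSSₑ) on identical rows, chi-square
  with df = added parameters.  Significance at p < 0.05, borderline at
  p < 0.1.
- **Quartiles:** empirical 25/50/75 cuts with ties to the lower quartile;
  ANOVA for continuous and chi-square for categorical variables;
  Mann-Whitney for two-group contrasts.

## Validation problem sizes

The validation suite uses: 1,000 random ternary sequences (length ≤ 100)
against a brute-force enumerator; a 400-interval alternating series for the
closed-form identities; one 300-s window for the spectral tone check;
5 × 50 replicates of 600-s series for the fragmentation-monotonicity
property; 20 replicates of a 13-point age grid at 1800 s per series for the
age-trend shapes; and for the regression harness 300 cohorts of n = 2,000
(CI coverage), 1,000 cohorts of n = 500 (LRT type-I) and 5 cohorts of
n = 400 (change-score identity).  These sizes give Monte-Carlo standard
errors comfortably inside the asserted bands while keeping a full run in
the low minutes on one CPU.

## Known limitations

- The no-change quantum assumes the annotation times derive from a uniform
  ECG sampling grid; resampled or jittered annotations blur the symbol
  boundaries.
- The gap threshold (3000 ms) and the coverage reading of the window
  qualification rule are documented conventions, not canonical choices.
- The PIP denominator (evaluated symbol pairs) differs negligibly from
  per-interval normalization for whole-night series but matters for very
  short, heavily fragmented recordings.
- The cohort generator's linear structural model cannot probe robustness
  to nonlinearity, heteroscedasticity or informative missingness; the
  change model's regression-to-the-mean term is a simple linear shrinkage.
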
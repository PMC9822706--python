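# Methods

`collocerp` implements the analysis path of an EEG study of collocation
processing during continuous speech: corpus-based condition assignment,
stimulus/EEG synchronization, ERP extraction over four scalp regions, and
permutation-based condition comparison — together with a synthetic
continuous-speech EEG generator that provides exact ground truth, because
the original human recordings are not redistributable.

## Collocation scoring

Association strength of an adjective–noun bigram is pointwise mutual
information in bits,

    MI = log2( (AB · N) / (A · B · K) ),

with A, B the corpus counts of the two words, AB their co-occurrence count
within a span of K word positions, and N the corpus size. All frequencies
are handled as per-million relative frequencies, under which N cancels and
the formula becomes `log2(f_AB · 1e6 / (f_A · f_B · K))`.

Numerical conventions:

- **Span K defaults to 1.** Corpus interfaces often describe a symmetric
  span (e.g. ±3 words), but the packaged item table's printed MI values are
  reproduced (±0.05 bits, consistent with their 3-decimal frequency
  rounding) only with K = 1. K is an explicit parameter.
- **Zero co-occurrence maps to MI = 0**, not −∞, matching how corpus tools
  print such items. A flag records when the convention fired.
- **Classification** uses two bounds: items at or below 4.83 bits are
  non-collocations, at or above 6.72 bits collocations, and the open
  interval between them is a buffer zone whose members are excluded. The
  bounds are stated at two-decimal precision, so scores are rounded to two
  decimals before comparison; without this, an item whose true score is
  6.7191 would be pushed into the buffer by rounding noise even though it
  prints as 6.72. Both bounds and the rounding precision are parameters.
- Three rows of the packaged item table print MI = 0 despite a nonzero
  co-occurrence frequency, and two more print values ~0.2–0.9 bits away
  from the formula; these are irreproducible from the printed frequencies
  (presumably different counting conventions upstream) and are excluded
  from numeric reproduction checks. All of them classify as non-collocations
  either way.
- **Condition matching** (word length in characters; mean per-million
  frequency of the two words) is verified with a two-sided Mann–Whitney
  rank-sum test per property; conditions count as matched when p > 0.2.
  Absolute standardized mean differences are reported alongside, since a
  non-significant test alone is weak evidence of matching.

## Synchronization

Word onsets from forced alignment are rendered as rectangular unit pulses
(default 10 ms — the true hardware pulse shape is not documented, and the
estimator is insensitive to it). The recorded copy of this pulse train on
an auxiliary EEG channel is delayed by an unknown number of samples; the
lag is the argmax of the full normalized cross-correlation, with ties
broken toward the smallest absolute lag. Sub-sample lag is not modeled:
at a 250 Hz working rate one sample is 4 ms, finer than the ~10 ms accuracy
of the alignment itself. Event onsets then map to sample indices as
`round(onset · fs) + lag`; events mapping outside the recording are dropped
and counted, never silently.

## Preprocessing

- **Band-pass 0.1–30 Hz**, zero-phase FIR (windowed design, transition
  widths from the standard firwin heuristics). The passband is flat within
  1 dB over 1–25 Hz and attenuation at 50 Hz exceeds 20 dB.
- **ICA cleaning**: a fixed-point ICA decomposition (fixed seed, iteration
  cap 200) is fitted on the filtered channels; components are ordered by
  the variance their back-projection explains and the top two are removed,
  in place of baseline correction. The removal assumes high-variance
  artifact components (ocular activity) dominate; on artifact-free
  synthetic data the removed components are quasi-random noise directions
  and the step costs a few percent of signal amplitude — one reason the
  recovery tolerance below is ±0.1 μV rather than the noise floor. The
  unmixing matrix is fitted on every 4th sample (the usual economy for long
  band-limited recordings) and applied to all samples. Removed-component
  variance shares and topographies are reported for audit.
- **Epoching** −200…+800 ms around critical-word onsets (251 samples at
  250 Hz), absolute amplitudes retained: no baseline correction, because in
  continuous speech the pre-stimulus interval is not quiescent.
- Recordings at the 2.5 kHz hardware rate are decimated (zero-phase FIR
  low-pass + subsampling) to the 250 Hz working rate.

## ERP measures

Per-participant evoked responses are within-condition trial means; grand
averages weight participants equally regardless of trial counts (standard
ERP convention). The scalar of interest is the mean amplitude over an ROI's
channels and the 300–500 ms window, endpoints inclusive at sample
resolution. The four ROIs are left/right × anterior/posterior groups of
9/9/7/7 electrodes in 10-10 montage labels.

## Permutation statistics

The condition comparison is a two-sample permutation test conditioning on
the observed amplitudes: with T the sum of group-1 values, under random
relabeling

    E(T) = n1·ȳ,   Var(T) = n1·n2 / (n(n−1)) · Σ(y−ȳ)²,

and z = (T − E(T))/√Var(T) is the standardized linear statistic. Two-sided
p-values come from the asymptotic normal tail, from Monte-Carlo resampling
with the add-one rule (b+1)/(B+1), or from exact enumeration (n ≤ 20).
Resampling comparisons of |z| use a small relative guard so floating-point
ties count as at-least-as-extreme. Degenerate all-equal input yields z = 0,
p = 1 with a warning.

Units of observation: trial-level amplitudes pooled across participants by
default, with participant-level evoked means as an option — sub-μV
condition differences only reach p < 0.001 with trial-level pooling. No
multiplicity correction across the four ROIs by default (a Bonferroni
option exists). The cross-site analysis runs pairwise two-sample tests
between ROI amplitude distributions within one condition (6 pairs) plus a
max-|z| summary; amplitudes at different sites come from the same trials,
and this pairing is deliberately ignored to keep the statistic identical to
the condition tests.

## Synthetic data generator

The generator emulates the recording situation, not the physiology:

- word stream at 2.5 words/s (inter-word intervals jittered uniformly
  ±20%), with one critical noun per ~7.5-word "sentence" (every 8th word),
  mirroring the stimulus material's sentence statistics;
- per channel, background noise = 1/f^α noise (α = 1, SD 1 μV) + white
  noise (SD 2 μV); the 1/f part is generated by spectral shaping, so its
  fitted slope is exact by construction;
- at each critical-word onset, a Gaussian-envelope component (center
  400 ms, SD 60 ms, truncated at 4 SD) is added to all channels of each
  ROI, scaled so that the injected 300–500 ms window mean equals the
  configured ROI × condition amplitude matrix cell exactly. The default
  matrix is the study's reported grand-mean amplitudes (LA −0.55/+0.31,
  RA −0.32/−0.08, LP −0.21/−0.02, RP −0.15/−0.59 μV for
  collocation/non-collocation);
- collocations additionally evoke a later left-posterior negativity
  (Gaussian at 650 ms, SD 80 ms, peak −0.4 μV); the N400 gain in that cell
  is solved so the combined window mean still hits the matrix exactly;
- the trigger pulse train is copied into a recorded trace delayed by a
  per-participant lag drawn uniformly from ±500 samples;
- options: two high-variance frontally-weighted blink-like sources (for
  exercising the ICA stage), a 2.5 kHz "hifi" rate (for exercising
  decimation), and a preset with 13 items per condition mirroring the
  study's power situation.

Default design size is 31 participants × 100 critical words per condition —
the study's participant count, but more trials than its 13 items, so that
recovery tolerances are informative at desk scale. Everything is
deterministic under the configured seed (per-participant child seeds are
spawned from it).

What the generator does **not** emulate: overlapping evoked responses from
non-critical words, realistic volume-conduction topographies (ROI
membership is binary so ground truth stays exact; a smooth spatial falloff
would blur it), non-stationary noise, and real ocular/muscle artifact
morphology. Passing recovery tests therefore validates the pipeline's
bookkeeping, filtering, synchronization, averaging and statistics — not its
robustness to physiological confounds.

## Known systematic effects and tolerances

- The 0.1 Hz high-pass removes each channel's mean, part of which is the
  injected evoked train's own mass. At the default critical-word density
  this shifts recovered window means by up to ~+0.04 μV (largest where the
  injected amplitudes are most negative); ICA removal adds a few-percent
  amplitude loss. Both land well inside the ±0.1 μV recovery tolerance; the
  noiseless-exactness tests (1e-6 μV) therefore run with filtering and ICA
  disabled, where recovery is pure arithmetic.
- The exact permutation p counts ties inclusively; against the asymptotic
  normal tail this produces gaps up to ~0.04 at n = 20 for moderate p —
  inherent discreteness, not an implementation artifact.
- Default problem sizes for the full synthetic run (31 × 200 critical
  words, ~650 s of speech per participant at 250 Hz) were chosen so a
  complete run finishes in minutes on one core.

## Degenerate inputs and tie-breaks

Constant trigger traces are rejected (lag undefined); merged trigger pulses
warn but proceed (natural speech has short gaps); zero-variance amplitude
vectors give z = 0, p = 1 with a warning; cross-correlation ties resolve to
the smallest |lag|; events whose epoch window leaves the recording are
dropped and counted. Bigram records with a co-occurrence frequency
exceeding a component frequency warn (corpus rounding) instead of failing.
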
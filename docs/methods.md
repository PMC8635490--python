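# Methods

This note documents the models, conventions and design choices behind
`facemimic`, in the order data flows through the pipeline.

## 1. Data model

The atomic object is an AU intensity series: a frames × 9 matrix at 30 fps
over the fixed channel order AU1, AU2, AU4, AU6, AU12, AU15, AU20, AU25,
AU26 (frown, eyes and mouth regions of a FACS-based intensity detector).
Raw values are Ekman's six ordinal categories N/A/B/C/D/E mapped to the
integers 0–5; filtered values are reals in the same range. A *snippet* is
one stimulus–response episode carrying its design coordinates
(participant, humanlikeness group, embodiment, phase, emotion, trial) and
an occlusion flag.

## 2. Synthetic cohort generator

The generator emulates a 3 × 3 + 1 mixed design: 45 participants in three
humanlikeness groups of 15; four embodiments (virtual agent, physical
robot, video-recorded robot, video-recorded human control); two phases
(spontaneous observation, instructed imitation); 12 snippets per
embodiment per phase (2 trials × 6 basic emotions), i.e. 48 snippets per
participant per phase. Trial orders are randomized with no emotion shown
twice in a row (rejection-sampled permutations; a valid order always
exists for 2 × 6 items), and embodiment order is shuffled per participant
and phase.

**Stimuli.** Each emotion has a 5-s onset–apex–offset template: linear
rise over the onset, hold at the peak, linear decay, re-quantized to the
ordinal grid. The 1 s / 3 s / 1 s split is an assumption (the source
design states only a 5-s total); it is configurable. Peak AU sets are
modest FACS prototypes (e.g. happiness AU6=3, AU12=4; anger AU4=4), each a
superset of at least one detection alternative so the detector can in
principle fire on a faithful copy.

**Spontaneous responses.** With per-embodiment probability `p_mimic_rfr` /
`p_mimic_cfr` (defaults 0.25 / 0.35, inside the range of observed
spontaneous-mimicry frequencies), the target emotion's first pattern
alternative is injected at low intensity (peak 1–2, the "subtle" regime),
lasting 3–15 frames, starting at a uniform latency inside the respective
window (0–800 ms for RFR, 1100–4000 ms for CFR). Injections are sampled
exactly as specified — no truncation at the window edge — so a late RFR
injection may legitimately spill ≥ 3 frames into the CFR window; studies
that need clean per-window rates switch the other window off. A
per-participant propensity offset (SD 0.08) added to both probabilities
creates the between-participant variance that the questionnaire coupling
and the regressions operate on. Baseline flicker (per-frame probability
0.01 of a one-frame, intensity-1 activation on a random channel) models
detector noise; single-frame events cannot satisfy the 3-frame rule.

**Instructed responses.** The response is the stimulus delayed by a
sampled lag (0–6 frames), scaled by a gain ~ N(1, 0.15), perturbed by
N(0, 0.3) noise per frame and channel, re-quantized to 0–5, and padded
with 1-s neutral buffers on both sides (the segmentation convention for
instructed snippets). Setting lag = 0, gain SD = 0 and noise SD = 0 makes
the copy exact, which pins down the closed-loop behaviour of the CRQA
stage.

**Missingness and questionnaires.** Occlusion is snippet-level with
per-phase probability (defaults 0.15 spontaneous / 0.06 instructed,
chosen so that after the block-level exclusion rules the realized
exclusion fractions land near the ~20% / ~9% range typical of
unconstrained vs instructed viewing). Eight 1–5 perception scales are
generated as 3 + c·z + noise, where z is the cohort-standardized latent
mimicry propensity of the participant × embodiment cell and c is a signed
coupling (default likability −0.25, co-presence −0.20, …, perceived
threat +0.08, noise SD 0.5); these defaults yield pooled standardized
regression slopes around −0.2, the size typically reported for such
couplings.

**Reproducibility.** Every snippet draws from
`default_rng([seed, tag, participant, phase, embodiment, snippet])`; the
ground-truth bundle records all sampled latents (injection windows,
starts, durations, peaks, lags, gains, noise seeds, flicker events), and
each response series can be reconstructed from it exactly — a property
the tests assert. Cohort files are byte-identical under a fixed seed.

**What the generator does not emulate.** Real AU-detector error structure
(autocorrelated confusion between adjacent intensity categories,
identity- and pose-dependent bias), valence-congruent or inverse mimicry,
head motion, frame-level dropout, and any coupling between emotion
recognition accuracy and mimicry. Passing recovery tests therefore shows
the pipeline is correct and well-calibrated *given* ordinal AU series of
this structure; it does not validate the upstream computer-vision stage.

## 3. Preprocessing

* **Smoothing:** centered moving average, window 10 samples. An even
  window needs a centering convention: frame t averages [t−5, t+4]. At
  the edges the window shrinks to the available frames, so no data is
  invented and constants are preserved. (The 10-sample window at 30 fps
  spans 333 ms; a published "(33.3 ms)" annotation for the same filter
  equals one sample and is treated as a typo.)
* **Trimming:** instructed snippets lose 30 frames at each end; snippets
  too short to trim are marked invalid rather than raising.
* **Validity:** occluded snippets are invalid. Spontaneous rule: if
  missing snippets exceed half of the block's nominal 12 (strictly more
  than 6), the whole participant × embodiment block is excluded; exactly
  half is kept. The denominator is the nominal 12 by default
  (configurable to the recorded count). Instructed rule: blocks with ≤ 5
  valid snippets are excluded. Both filters are idempotent.
* Spontaneous detection runs on the **raw** binary activations by
  default: activation is coded 0/1 with intensity disregarded, and
  whether the published procedure filtered before thresholding is
  unstated. A config switch thresholds the smoothed series at ≥ 0.5
  instead for sensitivity analyses.

## 4. Spontaneous detection

Windows are defined on frame onset times: at 30 fps, RFR = frames 0–29,
CFR = frames 30–149. A window fires when some pattern alternative has all
its AUs simultaneously active for ≥ 3 consecutive frames *inside that
window*; each window is evaluated independently, so a straddling run
counts for a window only if ≥ 3 of its frames fall inside — the least
arbitrary reading of a rule that is silent about straddling.
Combination patterns are conjunctive, alternatives disjunctive. The fear
row "AU20, AU1 + AU2 + AU4" is read as the two alternatives {AU20} and
{AU1, AU2, AU4} by analogy with the other rows; the mapping is
overridable. Detection targets the stimulus's own emotion only
(emotion-congruent mimicry).

## 5. CRQA

* **Threshold semantics:** ε = 2 with *strict* inequality (Manhattan
  distance exactly 2 is non-recurrent), following the definition "a match
  only when the distance … was less than two". The Heaviside-at-zero
  inclusive convention of standard recurrence software is available as
  `theta_convention="inclusive"`.
* **Normalization:** cRR divides by N·M, the actual matrix size, not N²
  — N ≠ M is possible after trimming — and is reported as a percentage.
* **Channels:** the feature vector uses the target emotion's pattern-AU
  union (1–4 channels; the published analysis used 3 unspecified
  channels). Because ε is a fixed Manhattan budget, higher-dimensional
  feature vectors are effectively stricter per channel; an optional
  `scale_eps_by_dim` rescales ε by d/3 (off by default).
* **Line counting:** every maximal diagonal run counts as a line of its
  exact length — isolated points are length-1 lines, and runs touching
  the matrix border count at their visible length. Hence
  Σ l·P(l) = number of recurrent points, a conservation law the tests
  assert. No Theiler window: the two systems are distinct, so the lag-0
  diagonal carries signal.
* **DET conventions.** The default `normalized` variant divides
  recurrent points on lines ≥ l_min by *all* recurrent points and is
  bounded in [0, 1], matching the stated range of determinism. The
  `as_printed` variant divides by the line *count* Σ P(l); it can exceed
  1, and published tables whose DET ≈ 2.7 (with L ≈ 5.5 < l_min = 8) are
  only reproducible under that formula or a different effective l_min —
  the two published statements are mutually inconsistent, so both knobs
  are exposed rather than silently resolved.
* **Finite-size note.** A fully recurrent N × N plot has DET(normalized)
  = 1 − 2·Σ_{l<l_min} l / N² (0.99751 at N = 150), not exactly 1: the
  corner diagonals are shorter than l_min. Similarly, a perfect copy of a
  *non-constant* stimulus yields L_max = N but cRR < 100, because cRR
  compares all frame pairs, not just simultaneous ones; only
  near-constant trajectories give cRR = 100.
* Aggregation is the arithmetic mean of per-snippet cRR, L, L_max, DET
  over valid snippets per participant × embodiment; L is reported as 0
  (flagged) when no line reaches l_min, and an empty plot yields all
  zeros with a `defined_empty` flag.

## 6. Statistics

The mixed-design decomposition is delegated to `pingouin.mixed_anova`;
the test suite holds it against an independently hand-coded
sums-of-squares GLM oracle to 6 significant figures. Uncorrected degrees
of freedom are the default (Greenhouse–Geisser behind a flag), no
sphericity correction matching the reporting convention of repeated-
measures tables with plain F(2, 80)-style df. The artificiality
follow-up collapses the three artificial embodiments to their
per-participant mean before a 2-level within × 3-level between ANOVA.
Post-hocs are pairwise paired t-tests with p multiplied by the number of
pairs (capped at 1); whether pooled or pairwise error terms were used in
the original analyses is unstated, and pairwise is the documented choice
here. Regressions standardize both variables and pool participant ×
embodiment rows (df = n−2 at that grain), deliberately ignoring
within-participant clustering to mirror the published df convention; the
r² = β² identity for single-predictor fits is asserted to machine
precision. Missing cells are deleted listwise within each analysis, and
zero-variance regressions return flagged undefined results.

## 7. Monte-Carlo validation (problem sizes)

`facemimic.simulation` treats the whole loop as a black box:

* **Type-I calibration:** 1000 replicates of a null cohort, scaled down
  to 12 participants (4/4/4), spontaneous phase and the three artificial
  embodiments only — the null distribution of the embodiment F does not
  depend on the full design size, and this keeps 1000 replicates in the
  ~90 s range on one core. Rejection rate ≈ 5% at α = .05.
* **Power:** 100 replicates at the full n = 45 with a 0.25 CFR
  injection-probability gap on one embodiment; detection ≈ 100%.
* **Sign recovery:** 100 replicates at n = 45 with likability coupling
  −0.4. The recovery condition uses a clearly negative coupling rather
  than the realistic default −0.25 because binomial measurement noise in
  rates over ~11 valid snippets attenuates the observed slope; at −0.25
  the recovered β is still negative in the large majority of replicates,
  but a sign-recovery check is about the direction of a known effect,
  not about power at the detection boundary.
* **Closure:** one full-size cohort with CFR injections at 0.7, no
  occlusion and no participant heterogeneity; the detected rate matches
  to within ~0.01 (3 Monte-Carlo SDs ≈ 0.03).

## 8. Known limitations

* The generator's ordinal noise model is far simpler than real AU
  detector output; absolute CRQA levels (e.g. mean cRR ≈ 56 under the
  default noise) characterize the synthetic regime, not any real cohort.
* The regression stage reproduces the pooled-observation convention and
  therefore understates standard errors in the presence of participant
  clustering; a clustered-robust option exists but is off by default.
* Valence-congruent mimicry, intensity-weighted scores, vertical-line
  CRQA measures (laminarity), and embedding/delay reconstruction are out
  of scope.
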
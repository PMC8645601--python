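# Methods

`eventseg` analyses event-segmentation experiments: observers watch
continuous action videos (here: Taekwondo form sequences of the WT and
ITF styles) and press a button whenever they judge one meaningful action
unit to end and the next to begin.  The package computes, from raw
button-press logs, the within-subject and group-level measures of such
an experiment, and ships a generative model of the whole study so every
stage can be validated against known ground truth.

## Measures

**Grain size — TBR.**  For one participant, video and block with
responses `t_1 < … < t_n` (n ≥ 2), the time between responses is the
mean successive gap, `TBR = (t_n − t_1) / (n − 1)` seconds.  Video time
before the first and after the last press is excluded by construction.
Fewer than two responses leave TBR undefined (NaN, never 0).  A small
TBR means fine-grained segmentation.

**Within-subject consistency — ROO.**  Each participant's 0-back
target-detection trials (latencies gated to the recordable 100–1500 ms
window) yield a reaction-time mean and sample SD (n − 1).  The rate of
overlap is the percentage of block-2 responses for which a block-1
response lies within ±`0.25 · SD_RT`, with the half-window floored at
one video frame so a degenerate SD of 0 cannot make matching
impossible.  Matching is an existence test with an inclusive window
boundary; a greedy one-to-one variant and the reverse (block-1
anchored) direction are available as switches because the two
directions are not equivalent in general.

**Group agreement — afv and n-bound.**  For each video frame `f` at
time `t_f = f / frame_rate`, the added frame value counts the response
units with at least one press in the trailing half-open bin
`(t_f − 1 s, t_f]`; within a bin a unit counts at most once.  The unit
is a participant × block pair by default (both blocks are summarized,
so the maximum afv is twice the group size); `units="participant"`
implements the stricter one-count-per-participant reading.  The
boundary threshold is `mean + 2 · SD` over the nonzero bins (the SD is
taken over the same nonzero bins by default; an all-bins SD is a
switch).  Agreed boundaries are maximal contiguous runs of frames
strictly above the threshold, and `n_bound` is their count per video
and group.

*Minimal peak duration.*  A run must span at least 0.2 s
(`min_peak_width_s`, converted to frames with a floor of one frame so
coarsely binned profiles keep every run) to count as a boundary.  This
resolves a genuine ambiguity in run-based peak counting: thresholding
any stationary, unstructured agreement profile at mean + 2 SD produces
on the order of ten hairline crossings of 40–180 ms per minute of
video — an intrinsic property of noise excursions, not agreement — and
counting them would swamp the contrast between structured and
unstructured groups.  Peaks counted on profile plots are episodes of
sustained agreement; 0.2 s (10 frames at the 50 Hz stimulus rate) is
the smallest span that is visually resolvable as a peak at typical
plot scales.  The cutoff is configurable and setting it to 0 restores
raw run counting.

**Referee overlay.**  A designated rater (e.g. an expert referee) is
excluded from their group's profile; each of their responses occupies
the frames of its trailing 1-s bin and overlaps a boundary when any of
those frames falls inside an agreed run.  Their block-1 vs block-2
same-bin repetition rate is reported alongside.

**Kinematics.**  Marker trajectories are smoothed per axis with an
order-1 Savitzky–Golay filter (0.1 s window — a centered moving average
in the interior with exact linear behaviour at the edges, suppressing
the noise amplification of double differencing); velocity and
acceleration come from second-order central differences.  The default
signal is the signed time-derivative of speed, because marking extremes
"in the positive or negative direction" requires a signed signal;
unsigned magnitude and per-axis components are switches.  Extreme
periods are maximal runs beyond mean ± 2 SD (SD over all frames).
Boundary/extreme overlap is tabulated per marker; each agreement run
`[s, e]` is widened to its response-support window `(s − 1 s, e]`
before intersection, since the trailing bin makes agreement runs lag
the kinematic event they reflect by up to one bin width.  A
circular-shift permutation test (hit count and mean covered fraction as
statistics) attaches an empirical p-value; this test is an extension —
the original comparison was a descriptive visual overlay.

## Inferential layer

Participant-level TBR and ROO are compared with Mann–Whitney U between
groups and paired Wilcoxon signed-rank (Pratt zero handling; identical
samples report p = 1) within participants, with rank-biserial effect
sizes.  `n_bound` is compared treating videos as cases: both groups
score every video, so the one-way repeated-measures F with group as the
within-video factor equals the squared paired t on per-video
differences, reported with df (1, V − 1) and partial η².  Style and
difficulty effects on per-video n-bound, mean TBR and mean ROO are
assessed per group with per-outcome between-cases F tests plus a Pillai
multivariate omnibus; neither gates the other.  No multiple-testing
correction is applied; the number of tests run is reported so readers
can adjust.  Degenerate inputs are defined deterministically: zero
difference variance gives F = 0, p = 1 (zero mean) or F = ∞, p = 0
(constant shift).

## Synthetic cohort

The generator emulates the study design: 12 videos (six ~51 s ITF, six
~71 s WT at 50 frames/s; half easy, half difficult), two blocks, 24
expert-like and 29 control-like participants, 0-back RT trials, and
marker trajectories for six body markers.

Per video, K = 10 ground-truth boundary times are drawn uniformly
subject to a 2 s minimal gap (order-statistics construction, exact, no
rejection), at least 1 s from the edges.  Each participant keeps each
boundary of their set with a persistent probability `grain_q` drawn
once per participant from Beta(1.2, 0.6) — the same kept-set in both
blocks, which is what produces high block-to-block grain reliability;
kept boundaries are detected per block with `p_detect = 0.75` and
answered with latency Normal(0.4 s, 0.3 s); idiosyncratic presses
arrive as a Poisson process at 0.05 /s.  Experts share the video's
ground-truth set; each control carries an independent individual set of
the same size.  Because all rate parameters are identical, expected
response counts are analytically matched across groups: grain size
carries no group signal, and only boundary *sharing* differs — the
design isolates n-bound as the discriminating statistic.  RT latencies
are Normal(385, 120) ms truncated to [100, 1500]; 10 target trials per
run, two runs.  Trajectories integrate a speed profile of a slow
baseline plus Gaussian bursts (σ = 0.25 s) centered at the ground-truth
boundaries, with positional jitter.

Defaults were chosen once to mirror the study conditions: group sizes,
video counts and durations, and the RT mean are the study's; K = 10 and
the wide grain distribution reproduce the study's response-rate scale
(~8 responses per video here vs a reported median of ~10) and its high
test–retest grain reliability (r ≈ 0.75–0.85 vs 0.86); p_detect,
latency parameters and the idiosyncratic rate are plausible detection
and simple-RT values.

All randomness derives from one master seed; per-participant, per-video
and per-block streams are derived by stable (blake2b) hashing of
identifiers, so datasets are byte-identical across runs and independent
of iteration order.

**What the generator does not emulate.**  (1) Block-to-block latencies
are independent, so simulated ROO sits at a few percent rather than the
~25–35 % seen when observers reproduce their timing precisely;
persistence lives entirely in the kept-set.  ROO comparisons on
synthetic data are therefore meaningful only relatively (monotone in
grain persistence, decreasing in latency noise), not in absolute level.
(2) Response counts are capped near K + Poisson noise, narrower than
the huge empirical spread (≈5–36 responses/video).  (3) Controls are
fully idiosyncratic; real novices likely share some low-level salience,
so their real agreement profiles carry weak genuine structure.
Passing tests show the pipeline recovers the generative structure under
these assumptions; they do not certify behaviour on real data beyond
that.

## Numerical choices

- Frame `i` (0-based) occurs at `i / frame_rate` s; a video has
  `round(duration × frame_rate)` frames.  Responses are real-valued
  seconds from onset.
- afv bin membership uses exact float comparisons `t_f − w < t ≤ t_f`;
  the implementation (searchsorted on the frame grid) is bit-identical
  to the definitional triple loop.
- Sample SDs use n − 1 throughout.
- Duplicate timestamps within participant × video × block are collapsed
  to one event with a warning; loaders never drop a row silently.
- Ties in a run's peak resolve to the earliest frame.
- Undefined metrics propagate as NaN and are excluded from unweighted
  means with exclusion counts reported.
- Problem sizes in the test-suite simulations (cohort counts, seeds per
  property, permutation shifts) are scaled to keep the full suite in
  the tens of seconds while leaving Monte-Carlo standard errors well
  inside the asserted margins.

## Known limitations

Hierarchical (partonomic) segmentation structure is out of scope, as
are fitting the generative model to real data and cross-correlation of
boundary trains with limb kinematics.  The referee and kinematics
overlaps are descriptive; only the clearly labelled permutation
extension quantifies them.  The 0.2 s minimal peak duration is a
methodological commitment; raw run counting remains available and
yields systematically higher boundary counts for unstructured profiles.
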
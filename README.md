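# eventseg

Analysis of **event-segmentation experiments**: observers watch videos of
continuous activity (here, Taekwondo form sequences) and press a button
whenever one meaningful action unit ends and the next begins.  The
package turns raw button-press logs into the standard measures of such
experiments and asks the question the paradigm was designed for: *do
experts implicitly agree on where actions are segmented?*

It is aimed at motor-cognition / behavioural-neuroscience researchers
running segmentation studies, and provides:

- **io**: validated CSV readers/writers for response logs, 0-back
  reaction-time trials, video metadata and marker trajectories, with
  structured load reports (no silent row drops).
- **rt**: per-participant RT calibration from the 0-back task, yielding
  the individualized response-matching window `±0.25 · SD_RT`.
- **metrics**: grain size **TBR** (mean gap between successive presses,
  s) and within-subject consistency **ROO** (% of block-2 responses
  matched by a block-1 response within the individual window).
- **agreement**: the core group statistic — the per-frame **afv**
  profile (number of participant×block units responding within the 1-s
  bin ending at each frame), the `mean + 2·SD` threshold over nonzero
  bins, and **n-bound**, the count of supra-threshold agreement peaks
  per video and group; plus referee overlays.
- **kinematics**: marker acceleration profiles, mean ± 2 SD extreme
  periods, and their overlap with agreed boundaries (with a
  circular-shift permutation test).
- **stats**: Mann–Whitney / Wilcoxon comparisons, the videos-as-cases
  repeated-measures ANOVA on n-bound (F = squared paired t), and
  style/difficulty MANOVAs.
- **simulate**: a seeded generative model of the full study (shared vs
  individual boundary sets, persistent per-participant grain, latency
  jitter, idiosyncratic presses, RT trials, kinematic bursts) with
  ground truth for recovery testing.

## Worked example

Simulate the default study (24 experts sharing ground-truth boundary
sets per video, 29 controls with individual sets, 12 videos, 2 blocks)
and run the full pipeline:

```python
from eventseg import SimConfig, generate_cohort, analyze

dataset = generate_cohort(SimConfig(seed=1))
bundle = analyze(dataset)

wide = bundle.nbound.pivot(index="video_id", columns="group", values="n_bound")
print("n-bound  expert %.2f  control %.2f" %
      (wide["expert"].mean(), wide["control"].mean()))
anova = bundle.stat_results["nbound_group_anova"]
print("videos-as-cases ANOVA  F(1,11) = %.1f, p = %.1e" %
      (anova["statistic"], anova["p"]))
print("TBR  expert %.1f s  control %.1f s   (group MWU p = %.2f)" % (
    bundle.participants.groupby("group")["tbr_s"].mean()["expert"],
    bundle.participants.groupby("group")["tbr_s"].mean()["control"],
    bundle.stat_results["tbr_s_group"]["p"]))
print("TBR re-test r = %.2f" % bundle.stat_results["retest_reliability"]["r"])
```

prints

```
n-bound  expert 6.75  control 2.92
videos-as-cases ANOVA  F(1,11) = 46.6, p = 2.9e-05
TBR  expert 8.1 s  control 7.7 s   (group MWU p = 0.38)
TBR re-test r = 0.85
```

The dissociation is the paradigm's signature: experts agree on more than
twice as many boundaries as controls (they share *where* to segment),
while grain size (TBR) shows no group effect and is highly reliable
within participants across blocks — response *rate* carries no expertise
signal, response *placement* does.

The same pipeline runs from the shell on any dataset manifest:

```bash
eventseg simulate --out data/ --seed 1
eventseg analyze --manifest data/manifest.json --out results/
eventseg report  --manifest data/manifest.json --out results/   # + figures
```

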
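# affectmap

Some people read emotional facial expressions effortlessly; others struggle.
One candidate explanation is the shape of a person's *internal* emotional
landscape: if anger, happiness and sadness *feel* consistent and distinct to
you, you may also hold consistent and distinct *visual templates* of how
those emotions look on other faces — and recognize them more accurately.

`affectmap` implements the full analysis pipeline for a behavioural battery
that tests this idea, together with a synthetic-cohort generator so every
stage is testable without any participant data:

1. **Task designs** — deterministic enumeration of the five trial tables:
   105 image-pair similarity trials (5 images per emotion), 55 triplet-choice
   trials per condition (11 targets, every unordered pair once, plus an
   attention-check "trap" image), 48 speed-dial trials for the
   expression-template and visual-matching tasks (dial bounded at 25–300% of
   the recorded speed), and 108 point-light-face (PLF) recognition trials.
2. **Experience scoring** — similarity ratings are embedded into a 2-D
   landscape by metric MDS (SMACOF stress majorization); mean embedded
   distances *within* and *between* emotion clusters index emotion
   differentiation. Triplet choices are scored for transitive consistency:
   with rank scores `r(i)` = times image `i` was chosen, the score is
   `sum over trials of r(chosen) − r(unchosen)`, at most 220 on the 11-image
   design, attained exactly when choices obey a strict total order.
3. **Representation scoring** — representational consistency is
   `−1 × SD` of the true speeds (pixels/frame, `percent/100 × recorded
   speed`) attributed to repeated presentations of one expression; distances
   between representations are absolute differences of mean attributed
   speeds; matching difficulty is the mean absolute percent deviation in the
   visual matching task; recognition accuracy is the correct-emotion rating
   minus the mean of the two incorrect ratings; and *representation
   matching* is the per-emotion product of representational consistency and
   matching difficulty.
4. **Model search** — a four-step structural-model construction: Boruta-style
   shadow-feature screening with a random-forest backend; sequential ML
   path-model building (variables enter by importance while the nested
   likelihood-ratio test improves); systematic reversal of every path with
   BIC comparison (ΔBIC 2–6 positive, >6 strong evidence; covariance-
   equivalent reversals tie at ΔBIC = 0); and a final refit with effect
   decomposition (indirect effects as path products with Sobel standard
   errors). The ML fitter uses the RAM parameterization
   `Sigma = F (I−A)^{-1} S (I−A)^{-T} F'`, supporting latent variables with
   indicators and nonrecursive loops.

## Worked example

```python
import affectmap as am

# an 8-participant synthetic cohort and its five response tables
cfg = am.CohortConfig(n_participants=8, seed=3)
cohort = am.generate_profiles(cfg)
responses = am.simulate_responses(cohort)

scores = am.build_score_table(responses, cohort.profiles, seed=3)
print(scores[["participant_id", "emotional_consistency", "mean_between",
              "rep_consistency", "matching_difficulty", "accuracy"]].head(3))
```

prints (seed 3):

```
  participant_id  emotional_consistency  mean_between  rep_consistency  matching_difficulty  accuracy
0          p0001             186.666667      9.549509        -0.341795            26.559240  1.718190
1          p0002              30.666667      8.715042        -0.228423            24.836956  1.412551
2          p0003             162.666667      8.885948        -0.376553            25.550012  0.936903
```

Each row is one participant: `emotional_consistency` is the mean transitivity
score over the three emotion conditions (max 220 — p0002's emotional
experience is very noisy), `mean_between` the mean MDS distance between emotion
clusters (landscape modularity), `rep_consistency` the −SD of attributed
speeds in pixels/frame (0 = perfectly stable visual template),
`matching_difficulty` the mean percent deviation when matching two displayed
expressions, and `accuracy` the mean recognition score on the −10..10 scale.

The same pipeline runs from the shell:

```bash
affectmap run --seed 3 --out run/      # simulate -> score -> model -> report
affectmap fixtures --out fixtures/     # small extreme-profile test cohort
```

`run/report.txt` ends with the fitted structural model and its effect table
(estimate, z, p, standardized beta per path).

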
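# Methods

This note documents the generative model behind the synthetic cohorts, the
scoring conventions, the structural-model machinery, and the design choices
made where the procedures were genuinely open.

## The measurement battery

Five task parts are modelled. (1) Pairwise similarity ratings over 15
affect-inducing images (5 per emotion; 105 unordered pairs) on a 0–10 scale
with 4-decimal resolution. (2) Triplet choices: per condition (anger,
happiness, sadness, and a colorfulness control) the 11 target images appear
in every unordered pair across 55 trials, each trial carrying one
attention-check trap drawn from the opposing category (a grayscale image in
the control). (3) An expression-template speed task and (4) a visual
matching task, both 48 trials (4 actors × 3 emotions × 4 repetitions) on a
dial bounded at 25–300% of the recorded speed; matching start speeds form
the 50–200%-in-10%-steps grid, template-task start speeds are seeded-uniform
within the dial. (5) A point-light-face recognition task crossing 4 actors ×
3 emotions × 3 spatial × 3 kinematic levels (108 trials, 12 per spatial ×
kinematic cell), rated on three 0–10 scales per trial.

Trap assignment and template-task start speeds are seeded-random because no
specific mapping is prescribed by the task descriptions; trap images may
repeat across trials. Image identifiers are synthetic stable strings —
stimulus identity never enters any score.

## Generative model of a participant

Each simulated participant carries:

* **Affect plane.** A 2-D latent plane (axes readable as valence/arousal)
  with one cluster centre per emotion at radius `modularity` (default mean
  6, SD 1.5, truncated at 0.5). Centre angles are fixed so the
  anger–sadness chord is ~0.69 of the other two chords, reproducing the
  empirically reported asymmetry (anger and sadness overlap more with each
  other than either does with happiness). Image positions are centre +
  N(0, 1.5² I) offsets, fixed per participant.
* **Experience noise** `sigma_exp` (log-normal, median 1 plane unit):
  perturbs image positions per similarity trial and evoked intensities per
  choice trial. Similarity is a monotone kernel of the perturbed distance,
  `10·exp(−d/λ)` with λ = 5 plane units — the task only defines the rating
  scale, so the kernel is an artifact choice; any monotone map yields the
  same ordinal structure.
* **Evoked intensities.** Per condition, the 11 target images get intensities
  ~ N(3.5, 0.8²) per participant (matching the reported stimulus-intensity
  scale); choices are the argmax of intensity + N(0, sigma_exp) noise. With
  probability `lapse_prob` (Beta(1, 30), mean ≈ 3%) a trial lapses to the
  trap, is counted, and is retried with fresh noise — the scorer sees only
  final choices plus the lapse count, mirroring the forced in-task retry.
  The control condition uses an independent noise scale `sigma_ctrl`, so
  colorfulness consistency carries no emotional signal by construction.
* **Representation speeds** `s_e` per emotion ~ N(m_e, 0.45²) pixels/frame
  with m = (3.85, 2.80, 1.63) for anger/happiness/sadness — the reported
  mean attributed speeds. Template-task attributions are N(s_e, sigma_rep)
  converted to dial percent against the actor's recorded speed
  (`v0(actor, emotion)` = emotion mean × actor factor 0.9–1.2) and clipped
  to the dial; clipping rather than resampling is observationally
  equivalent at the bound.
* **Matching noise** `sigma_match` (log-normal, median 30 percent points):
  matching attributions are N(100%, sigma_match) clipped to the dial; the
  reference video plays at the recorded speed, so the start speed does not
  bias the response.
* **Recognition.** Stimulus speed is `v0 × kinematic/100`. Each rating scale
  is a Gaussian tuning curve `10·exp(−(v̂ − ŝ_e)²/(2τ²))` (τ = 1
  pixel/frame) plus N(0, 0.5) rating noise, clipped to 0–10, where
  ŝ_e ~ N(s_e, sigma_rep) is the trial's sampled template and
  v̂ = v_stim + N(0, 1.5·sigma_match/100·v0) is the stimulus speed as
  perceived through that scale's matching operation. Drawing v̂ per scale —
  and letting matching noise enter recognition at all — is a deliberate
  generator choice: recognition is a template-matching act, so both the
  stability of the stored template (sigma_rep) and the precision of the
  matching operation (sigma_match) must shape accuracy. Without this term
  accuracy would be independent of matching ability and the
  representation-matching composite could never be recovered as a predictor;
  the weight 1.5 makes the two noise sources contribute comparably over
  their cohort ranges.
* **The experience–representation link.** A Gaussian copula correlates 1/sigma_exp with
  1/sigma_rep across participants at `rho_cons` (default 0.6): people with
  precise emotional experience also hold precise visual templates. At
  rho_cons = 0 the two are exactly independent. The copula fixes the rank
  correlation; Pearson correlations of derived scores are attenuated by the
  log-normal marginals and measurement noise (score-level r ≈ 0.5 at
  rho_cons = 0.6, n = 400).
* **Traits.** AQ ~ N(19, 6.8) clipped 0–50, TAS ~ N(48, 11.6) clipped
  20–100, NVR ~ N(61, 15) clipped 0–100 (the reported sample moments).
  TAS shifts modularity by −0.25 SD per SD, echoing the alexithymia →
  less-modular-landscape association.

What the generator does **not** emulate: reaction times, questionnaire item
structure, sex/culture moderation, block order, practice trials, and any
appearance dimension of templates other than speed. Passing recovery tests
therefore show that the *pipeline* recovers the assumed structure, not that
real data have that structure.

## Scoring conventions

* **Dissimilarity** = 10 − similarity (scale maximum minus rating); the
  transform is only fixed up to a monotone map by the task description.
* **MDS**: metric SMACOF, default 2 dimensions (landscapes are read as
  planar; the dimension is a parameter). Initialization is classical
  (Torgerson) scaling plus seeded random restarts (default 8, 300
  iterations, eps 1e−10); the lowest-stress solution is kept and the
  reported stress is normalized, sqrt(raw / Σδ²). In practice the classical
  start already reaches the best stress on this 15-point problem, so the
  cohort studies run with a single start and 80–150 iterations — the
  solutions are numerically identical (r = 1.0 against the full setting).
* **Consistency score**: ranks count final choices only; lapsed-and-retried
  trials contribute their final choice and a lapse counter (whether the
  original scoring re-included retried traps is not documented; final-choice
  scoring matches the task's forced-retry logic). One caveat discovered by
  enumeration: a single choice swap between two items *adjacent* in the
  preference order yields another perfectly transitive order and leaves the
  score at the 220 ceiling; every non-adjacent swap strictly lowers it. The
  property tests assert exactly this.
* **Representational consistency**: sample SD (n−1 denominator; the
  denominator is not documented) over the 4 repetitions per actor × emotion,
  on converted speeds (pixels/frame) by default with a percent-scale option,
  ×(−1), averaged over actors then emotions. The +2.52 display constant used
  in the original figures is presentation-only and never enters scores.
* **Median split**: participants at or below the cohort median deviation are
  "high matching" (ties go high; ties have measure zero under continuous
  simulation).
* **Composite**: raw per-emotion products, exactly as defined; a
  standardized variant sits behind a flag.

## Structural models

The fitter uses the RAM parameterization: directed coefficients A (paths
and loadings), symmetric S (residual variances, free for every variable;
covariances free between exogenous structural variables, except variables
explicitly *isolated*), implied covariance F(I−A)⁻¹S(I−A)⁻ᵀFᵀ. Latent
scales are fixed by the first loading = 1; variables are z-scored before
fitting; N in BIC is the number of participants. Estimation minimizes the
normal-theory ML discrepancy by L-BFGS-B (ftol 1e−8, 5 seeded restarts —
perturbed starts guard against local minima, which were never observed on
these model sizes); standard errors come from the central-difference
Hessian of the log-likelihood; standardized betas from model-implied
variances; indirect effects are sums of simple-path products with
delta-method (Sobel) standard errors.

**Sequential building.** "Significant improvement" is operationalized as a
nested likelihood-ratio test at alpha = 0.05 (the original criterion and
threshold are unnamed). Nesting is exact: the outcome starts isolated (zero
covariance with every candidate), candidates keep a saturated covariance
block throughout, and each accepted step frees exactly one path into the
outcome (df = 1).

**Path reversal.** Each structural edge is reversed one at a time and the
model refit; ΔBIC = BIC(reversed) − BIC(original) with the conventional
evidence scale (|Δ| < 2 tie, 2–6 positive, > 6 strong). Ties retain the
original direction — two-variable reversals are covariance-equivalent and
always tie, which the tests exercise. The reversed direction is retained
only when it wins by more than the tie threshold; the final model assembles
retained directions, is refit, and is checked against all of its own
single-reversal variants. Automatic creation of feedback loops is not
attempted (the joint criterion under which both directions should be kept
is not documented); nonrecursive loops fit correctly when specified
explicitly.

**Importance screening.** Default backend is permutation importance of a
random-forest regressor over 100 shadow iterations with a two-sided
binomial classification at alpha = 0.01; an impurity-importance backend
(the classic Boruta flavour) is available and is what the replicated
recovery studies use, at 15 iterations and 50 trees per forest — decisions
on the strong effects involved are identical across backends at these
cohort sizes.

**Association screen.** Participant-level OLS stands in for the original
mixed-effects screens; with one row per participant there is no grouping
structure to model, so the fixed-effect estimates coincide.

## Study sizes in the shipped tests

The recovery studies run at the sizes they describe: the consistency-link
study uses 50 replicate cohorts of n = 400 per condition (rho_cons 0.6 and
0); the collider-reversal study 10 replicates at n = 2000; the
full-pipeline retention study 10 replicates at n = 1000 with the
reduced-iteration MDS/screen settings noted above, which were verified to
reproduce the full-setting decisions.

## Known limitations

* The generative model is an artifact: the real tasks define no
  distributions, so all recovery results are statements about the pipeline.
* The ML fitter assumes multivariate normality and complete rows; there is
  no missing-data (FIML) estimation and no robust (WLSMV-style) estimator.
* Identification is not checked symbolically; non-identified specifications
  surface as singular Hessians or non-convergence.
* The reversal search explores single-edge reversals only, as specified —
  it is a direction check, not a full structure search.
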
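# Methods

`paco2est` implements a complete intraoperative analysis chain for
estimating arterial CO2 tension (PaCO2, mmHg) from noninvasive monitoring,
together with a synthetic-cohort generator that stands in for clinical
data.  This note records the models, the defaults and why they were chosen,
the numerical conventions, and what the synthetic experiments do and do not
demonstrate.

## 1. Problem and pipeline

During general anesthesia, PaCO2 is measured intermittently by arterial
blood gas analysis (ABGA), while end-tidal CO2 (ETCO2) from capnography is
available continuously.  The arterial-to-end-tidal gradient is 3–5 mmHg in
healthy lungs but widens unpredictably with dead space, V/Q mismatch, low
cardiac output and hypothermia, so a fixed offset is unreliable.  The
pipeline estimates PaCO2 at a *trigger time* shortly before each blood draw
from a 60-second window of monitor and ventilator channels plus clinical
covariates, and evaluates the estimate the way a method-comparison study
would.

Stages (each a module, each a CLI subcommand):

1. **simulate** — generate a synthetic cohort (clinical table, 14 biosignal
   channels, ABGA events).
2. **align** — refine each ABGA database timestamp to an estimated draw
   time via MAP-surge detection; build trigger and observation window.
3. **extract** — clean and median-summarize each window; engineer
   physiological indices; listwise-delete incomplete events.
4. **train** — case-grouped nested cross-validation of a gradient-boosted
   tree regressor (LightGBM) against two ETCO2 baselines.
5. **evaluate** — fold-averaged error metrics with 95% CIs, capnia
   subgroups, Bland-Altman, ICC(2,1), clinical-utility bins, and additive
   feature attributions.

## 2. Event alignment

The database timestamp of an ABGA record marks result *entry*, not the
draw.  Drawing blood through the arterial line transiently occludes it,
producing a brief MAP surge.  The detector z-scores the MAP samples in the
20-minute lookback window preceding the recorded timestamp against that
window's own mean and sample SD (ddof = 1), takes maximal runs of samples
with z > 3 (one-sided: draws raise pressure), and picks the run whose
boundary is nearest the recorded time; the estimated draw time is the
moment of maximum z within that run.  Events with no qualifying run are
excluded as unreliably timed.

Conventions the detector fixes where the procedure is underdetermined:

- **Reference distribution** — the lookback window itself.  Self-contained
  and robust to case-level drift; no global baseline needed.
- **Representative time** — argmax z within the chosen period; the pressure
  peak best marks line occlusion.  Note this lags the true draw onset by a
  few seconds (the surge rises over seconds), so the median of
  (recorded − estimated) sits slightly below the median entry delay.
- **Nearest** — by interval boundary distance (zero if the recorded time
  falls inside a period); ties go to the later period.
- **No lookahead** — only samples at or before the recorded timestamp are
  inspected, so the method is usable retrospectively and in near-real time.
- **Blackout** — the interval between window end and trigger defaults to
  0 s (the 60-s pre-trigger already separates the window from the draw);
  configurable.

Trigger = estimated draw − 60 s; observation window = the 60 s ending at
(trigger − blackout), half-open `[start, end)`.

## 3. Feature extraction

Per aligned event and channel: slice the window, drop samples outside
clinical plausibility bounds (documented defaults in
`config.DEFAULT_PLAUSIBILITY`; these are configuration, not fitted values),
then drop samples outside `[Q1 − 3·IQR, Q3 + 3·IQR]` (quartiles by linear
interpolation), then take the median.  Plausibility runs first so that
physically impossible values cannot distort the quartiles.

Engineered indices (from the window medians and clinical fields):

| feature | formula | units |
|---|---|---|
| TV/IBW | tidal volume / Devine ideal body weight | mL/kg |
| SpO2/FiO2 | oxygen saturation / inspired O2 fraction | — |
| PEEP/FiO2 | PEEP / FiO2 | cmH2O |
| CRS | TV / (Pplat − PEEP); missing if Pplat ≤ PEEP | mL/cmH2O |
| RSBI | RR / TV(L) | min⁻¹·L⁻¹ |

The pulmonary-function grade uses spirometric cutoffs FEV1/FVC < 0.70
(obstruction) and FVC < 80% predicted (restriction); both → mixed, absent
PFT → none.  Cardiac output is an optional channel: the pipeline runs with
or without it.

Events missing any predictor are removed (listwise deletion) with
per-reason accounting; nothing is imputed.  Continuous features are
robust-scaled, `(x − median)/IQR`, with state fitted on the training rows
of the current fold only (degenerate IQR → scale 1, feature flagged
constant).  Categorical features (sex, surgery type, approach, ASA class,
PFT grade) pass natively to the tree model; the linear baseline uses only
ETCO2.

## 4. Models and validation

Splitting is at the surgical-case level: 7 outer folds estimate
generalization, and each outer training set is split into 6 inner folds
for hyperparameter selection, so no patient's events ever straddle a
train/test boundary.  Fold assignment is a seeded permutation balanced to
±1 case.

The regressor is gradient-boosted decision trees (LightGBM,
`deterministic=True`, single-threaded) behind a small fit/predict/attribute
contract, so the backend is swappable.  Hyperparameters are chosen by
seeded random search — depth 3–10, learning rate log-uniform 0.01–0.3,
100–1000 trees, L2 leaf regularization 1–10, 20 trials by default —
minimizing the mean MAE across the inner validation folds; the winner is
refit on the full outer training set.  MAE is the search objective because
it is the headline evaluation metric.

Baselines, refit per outer fold where applicable:

- **offset** — PaCO2 = ETCO2 + 5 mmHg (no fitting);
- **linear** — OLS of PaCO2 on ETCO2 alone.

## 5. Evaluation

All differences are `predicted − actual`.  Per model:

- **Error metrics** — MAE, MSE, RMSE computed per outer fold (RMSE = √MSE
  within each fold) and summarized as mean with a Student-t 95% CI across
  the 7 fold values.  Subgroup blocks (hypocapnic < 35, normocapnic 35–45
  inclusive, hypercapnic > 45 mmHg, by *actual* PaCO2) are computed per
  fold within subgroup, then CI-averaged; folds with an empty subgroup are
  skipped with a warning.
- **Bland-Altman** — bias = mean difference; limits of agreement =
  bias ± 1.96 × sample SD of differences; per-point tables are written for
  plotting.
- **ICC** — ICC(2,1), two-way random effects, absolute agreement, single
  measurement, computed from the two-way ANOVA mean squares with the
  standard F-based CI and p-value.  Absolute agreement is the right variant
  alongside Bland-Altman because it penalizes systematic offset; the
  variant is recorded in the report.
- **Utility bins** — |error| < 5 mmHg highly acceptable, 5–10 inclusive
  moderately acceptable, > 10 unacceptable; percentages sum to 100.
- **Attribution** — exact additive tree attributions (LightGBM
  `pred_contrib`), computed out-of-fold: each outer fold's model scores its
  own held-out events.  The additivity identity (base + Σ attributions =
  prediction) is checked row by row; features are ranked by mean
  |attribution| with a Spearman signed-dependence against feature values.

## 6. The synthetic cohort

The generator emulates the statistical structure the analysis assumes; it
is first-class, tested code, and its hidden truth (draw times, surge
flags) is used only to score the pipeline, never by it.

- **Clinical table** — age uniform 18–80 y; sex; height/weight from
  sex-specific normals and BMI; ASA 1–5 (weighted); surgery type and
  approach; PFT present in 75% of cases.
- **Ventilator settings** — per-case constants with small observation
  noise: TV ≈ 6–8 mL/kg IBW, RR 10–16, PEEP 4–6 cmH2O, FiO2 0.40–0.60,
  Pplat = PEEP + TV/CRS with true compliance ~N(50, 12) mL/cmH2O.
- **Physiology channels** — Ornstein-Uhlenbeck mean-reverting noise around
  per-case baselines (ETCO2 mean ~N(35, 3) mmHg; SpO2, HR, BT, CO
  likewise), sampled at 2-s intervals.  MAP is sampled at 1 Hz because
  surge detection consumes it.
- **MAP baseline noise** — two random-phase sinusoids (periods 14–22 s,
  Mayer-wave band, and 45–90 s, slow vasomotor band) plus bounded uniform
  jitter, overall SD ≈ 4 mmHg.  This bounded quasi-periodic form was chosen
  deliberately: the max-deviation-to-SD ratio of any full lookback window
  stays below 3, so a surge-free window can never trip the z = 3 detector,
  making the generator's surge flags exact ground truth.  Gaussian-type
  noise cannot give that guarantee (its window maxima routinely exceed
  3 SD).
- **Surges** — smooth unimodal bumps of 20–40 mmHg over 15–40 s starting at
  the draw, peaking at 25% of their duration (fast occlusion rise, slower
  decay).  A configurable fraction of draws (default 0.114) has no surge.
  Distractor bumps (default 0.2/h) exercise nearest-period selection but
  are kept outside each draw-to-recorded interval and outside the lookback
  of surge-free events, preserving exact flag semantics.
- **Entry delay** — recorded time = draw time + log-normal delay with
  median 34 s and quartiles ≈ 22/54 s (parameters
  `μ = ln 34, σ = 0.666`), capped at 600 s.
- **Targets** — PaCO2 = window-median ETCO2 + gradient, where
  gradient = γ0 + γ_age(age−50)/10 − γ_bt(BT−36.5) − γ_sf(S/F−400)/100
  − γ_crs(CRS−50)/10 + N(0, σ_g), with defaults γ0 = 6.65, γ_age = 0.6,
  γ_bt = 1.5, γ_sf = 0.5, γ_crs = 1.0, σ_g = 1.5 mmHg.  The signs encode
  the physiology (gradient widens with age, hypothermia, poor oxygenation,
  stiff lungs); γ0 was calibrated once by Monte Carlo so the cohort mean
  gradient is ≈7.6 mmHg, with cohort mean ETCO2 ≈ 35 and PaCO2 ≈ 42.5, and
  the capnia subgroups split roughly 3/72/25%.
- **Draw schedule** — draws spaced ≥ ~22 min apart so every lookback is
  clean; with 50–120-min cases this yields ~2.5 events/case, i.e. roughly
  700 modeled events at the default 300 cases.  That problem size keeps a
  full nested-CV run within minutes while leaving every acceptance margin
  wide.

**What passing on synthetic data shows — and does not.**  The generator
has slowly varying, stationary channels, exactly linear gradient structure,
i.i.d. Gaussian target noise, and surge artifacts that are by construction
detectable exactly when flagged.  Success here demonstrates that the
pipeline's mechanics are correct (alignment, leak-free validation, correct
statistics, recoverable attributions) — not that the model achieves any
particular accuracy on real operating-room data, where timing error,
nonstationarity, missingness patterns and unmodeled physiology all bite.
No real-data figure is reproduced or claimed.

## 7. Numerical conventions and degenerate inputs

- Quartiles: linear interpolation everywhere (filtering and scaling).
- Zero-variance z window → all z = 0 (nothing abnormal relative to it).
- IQR = 0 in scaling → scale 1, constant flag; in filtering → fence
  collapses to the common value, identical samples survive.
- Pplat ≤ PEEP → compliance missing (invalid driving pressure), event
  dropped by listwise deletion; TV = 0 → RSBI missing.
- Empty window slice → missing median → listwise deletion.
- ICC on a zero-variance table → NaN with a warning; fewer than 2 fold
  values → CI undefined with a warning.
- Ties in nearest-period selection → later period.
- All randomness flows from one global seed through per-stage derived
  seeds; reports serialize with sorted keys so identical seeds give
  byte-identical JSON.

## 8. Known limitations

- The surge heuristic is validated only against the generator's own
  surge model; no gold-standard draw times exist here (or in the study
  setting it emulates).
- The estimated draw time is the surge *peak*, biasing alignment a few
  seconds late relative to draw onset; the 60-s pre-trigger absorbs this.
- Per-channel distributions are plausible clinical ranges, not fitted to
  any dataset; the entry-delay family (log-normal) is an assumption
  matching published summary statistics only.
- Sequence/temporal features, imputation, waveform-resolution pressure
  synthesis and real-data ingestion are out of scope.
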
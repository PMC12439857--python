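# paco2est

Estimating arterial CO2 tension (PaCO2) from noninvasive intraoperative
monitoring.

During general anesthesia, ventilation is steered by end-tidal CO2
(ETCO2), but the quantity that matters physiologically is arterial PaCO2,
measured only intermittently by arterial blood gas analysis (ABGA).  The
PaCO2–ETCO2 gradient is 3–5 mmHg in healthy lungs yet widens unpredictably
with dead space, V/Q mismatch, hypothermia and low cardiac output, so
neither a fixed offset nor a simple regression on ETCO2 is reliable.  This
package implements, as a tested reusable pipeline, a retrospective
analysis for learning PaCO2 from routinely monitored parameters:

1. **Event alignment** — an ABGA record's database timestamp marks result
   *entry*, not the blood draw.  Drawing through the arterial line
   transiently occludes it, producing a mean-arterial-pressure (MAP)
   surge; the pipeline z-scores the MAP trace over the 20 minutes
   preceding each recorded timestamp, takes abnormal periods with z > 3,
   and refines the event time to the nearest surge (events without one are
   excluded as unreliably timed).
2. **Feature extraction** — from the 60-s observation window before the
   trigger (60 s before the estimated draw): plausibility and 3×IQR
   filtering, per-channel medians, and engineered indices — TV/IBW,
   SpO2/FiO2, PEEP/FiO2, respiratory-system compliance
   C_RS = TV/(P_plat − PEEP), and the rapid shallow breathing index
   RR/TV(L) — plus clinical covariates and a spirometric PFT grade.
   Events with any missing predictor are listwise-deleted.
3. **Modeling** — a gradient-boosted decision-tree regressor (LightGBM,
   native categorical handling) trained under case-grouped nested
   cross-validation (7 outer / 6 inner folds, random-search tuning on the
   inner folds), against two baselines: ETCO2 + 5 mmHg and OLS of PaCO2 on
   ETCO2.  Robust scaling (median/IQR) is refit inside every fold.
4. **Agreement evaluation** — fold-averaged MAE/MSE/RMSE with Student-t
   95% CIs, overall and within capnia subgroups (hypocapnic < 35,
   normocapnic 35–45, hypercapnic > 45 mmHg); Bland-Altman bias and limits
   of agreement (bias ± 1.96 SD of predicted − actual); ICC(2,1) with
   F-based CI; clinical-utility bins at |error| 5 and 10 mmHg; and exact
   additive tree attributions, computed out-of-fold.

Because the clinical dataset itself is not shipped, the package includes a
first-class **synthetic-cohort generator** reproducing the statistical
structure the analysis assumes (surge-marked draws with log-normal entry
delays of median 34 s, a configurable fraction of surge-free draws, slowly
varying physiology and ventilator channels, and a ground-truth gradient
model that widens with age, hypothermia, low SpO2/FiO2 and low
compliance, averaging ≈7.6 mmHg).  Every stage is testable against the
generator's hidden truth.  See `docs/methods.md` for the full model
description and its limitations.

## Worked example

```python
import dataclasses
from paco2est import PipelineConfig, run_all

cfg = PipelineConfig(seed=7)
cfg.generator = dataclasses.replace(cfg.generator, n_cases=80)
cfg.search = dataclasses.replace(cfg.search, n_trials=5)
res = run_all(cfg, out_dir="results/demo")

print(f"modeled events: {len(res.features)}  "
      f"(of {res.report['provenance']['n_abga_events']} ABGA records)")
for m in ("offset", "linear", "gbm"):
    block = res.report["models"][m]
    print(f"{m:7s} MAE {block['metrics']['all']['mae']['mean']:.2f} mmHg   "
          f"ICC {block['agreement']['icc']:.2f}   "
          f"|err|<5 mmHg: {block['utility']['pct_lt5']:.1f}%")
top = res.report["attribution"]["features"][0]
print(f"strongest feature by mean |attribution|: {top['feature']}")
```

prints

```
modeled events: 172  (of 202 ABGA records)
offset  MAE 3.01 mmHg   ICC 0.60   |err|<5 mmHg: 83.1%
linear  MAE 1.82 mmHg   ICC 0.77   |err|<5 mmHg: 98.3%
gbm     MAE 1.74 mmHg   ICC 0.78   |err|<5 mmHg: 97.7%
strongest feature by mean |attribution|: etco2
```

Reading it: ~15% of the 202 synthetic ABGA records were excluded (no
detectable MAP surge, or a missing predictor); on the rest, the fixed
ETCO2 + 5 offset misses by 3 mmHg on average and underpredicts (the
cohort's true mean gradient is ≈7.6 mmHg), the single-predictor
regression absorbs the average gradient, and the tree model additionally
exploits age, temperature, oxygenation and compliance — its advantage
grows with cohort size (at the default 300 cases it reaches MAE ≈ 1.4 mmHg
and ICC ≈ 0.88).  The attribution ranking confirms ETCO2 as the dominant
input, as physiology demands.

`run_all` also writes `events.csv`, `features.csv`, `predictions.csv`,
`report.json`, per-table summaries (`metrics.csv`, `agreement.csv`,
`utility.csv`, `attribution.csv`), Bland-Altman point tables, and a
manifest with config hash and file checksums.

## Command line

The same chain is available as stages over CSV files:

```sh
paco2est simulate --n-cases 80 --seed 7 --out data/
paco2est align    --signals data/signals.csv --abga data/abga.csv --out data/events.csv
paco2est extract  --events data/events.csv --clinical data/clinical.csv \
                  --signals data/signals.csv --out data/
paco2est train    --features data/features.csv --out data/ --budget 20 --seed 7
paco2est evaluate --predictions data/predictions.csv --features data/features.csv --out data/
# or everything at once, from a YAML config:
paco2est run-all --config config.yaml --out results/
```

Identical seeds give byte-identical reports.

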
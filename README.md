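# rtconf

Sequential-sampling models of binary choice, response time, and decision
confidence: joint probability densities, trial-level simulators,
maximum-likelihood fitting, prediction, and subject/group-level model
comparison.

Implemented model families:

* **Diffusion-based** — dynaViTE (post-decisional accumulation, parallel
  visibility process, accumulation-time penalty) and its special cases
  dynWEV (`lam = 0`), 2DSD (`lam = 0, w = 1`) and DDConf
  (`w = 1, tau = 0, lam = 0.5`).
* **Wiener race** — two accumulators with increment correlation 0
  (IRM/IRMt) or −0.5 (PCRM/PCRMt); confidence from the balance of evidence,
  optionally combined with decision time (the *t* variants). Closed-form
  first-passage densities by the method of images.
* **MTLNR** — multiple-threshold log-normal race: ballistic accumulation
  with log-normal boundary distances and rates, confidence from the log
  ratio of crossing times.

All models share the discretization of an internal confidence variable into
K ratings by response-specific thresholds, and a uniform non-decision time.

## Python API

```python
import rtconf

# data: tidy CSV/TSV, one row per trial
trials = rtconf.ingest_trials("trials.csv",
                              column_aliases={"rating": "confidence"},
                              n_ratings=4)

# fit several models to every subject (one output row per subject x model,
# with negLogLik, AIC, AICc, BIC)
fits = rtconf.fit_models(trials, ["dynaViTE", "IRMt"], n_ratings=4,
                         simult_conf=True, restr_tau="simult_conf",
                         n_jobs=4, seed=1)

# subject-level weights and group-level random-effects model selection
weights = rtconf.subject_model_weights(fits, measure="BIC")
bms = rtconf.group_bms(fits, measure="BIC")
print(bms.summary(), bms.bor)

# predicted outcome distributions and RT densities from a fitted row
row = fits.iloc[0]
disc = rtconf.predict_discrete(row)
dens = rtconf.predict_rt(row, rt_grid=(0, 9, 0.01), scaled=True,
                         discrete_table=disc)
quants = rtconf.pdf_to_quantiles(dens, probs=[.1, .5, .9],
                                 group_columns=["response", "rating"])

# simulation (per stimulus x condition from a fitted row, or low level)
sim = rtconf.simulate_fit_row(row, n=1000, seed=2, gamma=True)
```

Direct density access: `density_dynavite`, `density_dynwev`,
`density_2dsd`, `density_ddconf`, `density_race`, `density_mtlnr`,
`fpt_density_ddm`, `fpt_density_race`. Each returns
`P(rt, response, c in [th1, th2])`. The `precision` argument is calibrated
so the mean absolute density error is about `10**-precision` (default 6;
fitting uses 3).

Recovery and benchmarking pipelines: `run_parameter_recovery`,
`run_model_recovery`, `run_precision_benchmark`, with
`ParameterSampler`/`sample_parameters` drawing generating parameter sets
(ordered difficulty levels, admissible start ranges, simplex confidence
weights, thresholds at simulated confidence quantiles) and `ccc` (Lin's
concordance correlation) for agreement.

## Command line

```bash
rtconf fit trials.csv --models dynaViTE,IRMt --n-ratings 4 \
       --simult-conf --restr-tau simult_conf --seed 1 --out fits.csv
# full defaults: ~12k-candidate coarse search, 5 starts x 5 restarts x 5000
# evaluations -- hours per subject x model; shrink with --grid-size,
# --n-starts, --n-restarts, --max-evals for quick passes
rtconf compare fits.csv --out bms.csv            # + fits weights table
rtconf predict-conf fits.csv --out conf.csv
rtconf predict-rt fits.csv --grid 0:9:0.01 --probs 0.1,0.5,0.9 --out rt.csv
rtconf simulate --model IRMt --params row.csv --n 500 --out sim.csv
rtconf recover-params --model 2DSD --n-sets 10 --out ccc.csv
rtconf recover-models --generators 2DSD,IRMt --out confusion.csv
rtconf benchmark-precision --model dynaViTE --out precision.csv
```

Exit codes: 0 success, 1 computational failure, 2 usage error. Every run
writes a `<out>.log` with version, options and seeds.

## Notes

* RT unit is seconds; no automatic millisecond detection.
* Outlier filtering is never applied automatically;
  `filter_rt_outliers` applies a user-stated lower cutoff and a
  mean + k·SD upper cutoff per subject.
* Unused rating categories are handled post hoc: unused extreme categories
  get ±inf sentinel thresholds, unused interior categories coincident
  thresholds; the reported free-parameter count reflects the reduction.
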
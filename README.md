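# nerveblock

Duration and intensity analysis of sensory nerve blocks measured with rodent
thermal-latency assays.

## The problem

Preclinical studies of local anesthetics (e.g. plain bupivacaine
hydrochloride vs extended-release liposomal bupivacaine, in healthy mice vs
mice with streptozotocin-induced diabetic peripheral neuropathy) quantify a
sciatic nerve block by how long an animal tolerates a radiant heat stimulus:
the plantar test (cutoff 15 s) or the tail-flick test (cutoff 4 s).  Readings
at the cutoff are right-censored — the stimulus is removed to prevent tissue
damage.  Analgesic effect at time *t* is scored as the percent of maximal
possible effect against the animal's own trimmed baseline,

```
%MPE(t) = 100 · (post(t) − pre) / (cutoff − pre),   clamped to [0, 100]
```

Because one analgesia meter serves a whole group, animals are interleaved on
a balanced-incomplete-block schedule: a 1.5-min slot grid over a 270-min
horizon, each mouse measured exactly once per 13.5-min window (180 grid
points per arm).  Group block kinetics are then summarized as mean %MPE per
window; the block counts as **diminished** once that trajectory falls below
15% and stays there, and the time of that crossing (from injection) is the
**sensory block duration** — reported as censored when the trajectory is
still above 15% at 270 min.  Discrimination between treatments and between
neuropathy conditions is quantified with ROC curves built from the %MPE
scores (trapezoidal AUC, Hanley–McNeil SE, χ² contrast of two independent
areas), and cohort covariates are compared with two-sample t-tests.

The package implements that whole chain as a tested library plus CLI, along
with a synthetic study generator (cohorts with realistic baseline/glucose
distributions, censored block trajectories with onset, optional mid-course
partial release and rebound) so every stage can be exercised and calibrated
without animal data.

## Worked example

```sh
nerveblock simulate --seed 1 --out sim/
nerveblock analyze --cohort sim/cohort.csv --measurements sim/measurements.csv --out out/
nerveblock report --report out/report.json
```

prints

```
== block durations ==
  control:BH         105.2 min (interval_means)
  control:LB         121.1 min (interval_means)
  dm_pn:BH           127.8 min (interval_means)
  dm_pn:LB           censored_above_total
== ROC models ==
  LA:BH              AUC 0.63 (SE 0.089, n=20+20)
  LA:LB              AUC 0.82 (SE 0.068, n=20+20)
  condition:control  AUC 0.54 (SE 0.092, n=20+20)
  condition:dm_pn    AUC 0.97 (SE 0.029, n=20+20)
== AUC comparisons ==
  LA         chi2=2.90 p=0.0886 (notably significant (p < 0.1))
  condition  chi2=19.58 p=9.67e-06 (significant (p < 0.05))
== covariate t-tests (dm_pn vs control) ==
  baseline_latency_s   t=3.19 df=22 p=0.0042 (significant (p < 0.05))
  glucose_mmol_L       t=19.31 df=22 p=2.76e-15 (significant (p < 0.05))
  weight_g             t=-8.57 df=22 p=1.85e-08 (significant (p < 0.05))
```

Reading this: the three single-release arms release their blocks after
roughly 105–128 min, while the neuropathic liposomal-bupivacaine arm is still
above the 15% threshold at the 270-min horizon (censored) — its generator
profile contains a partial release near 93 min followed by a rebound.  %MPE
discriminates anesthetics almost perfectly within the neuropathic condition
(AUC 0.97) but barely within controls (AUC 0.54), and discriminates
condition far better under the liposomal formulation (0.82 vs 0.63).  The
covariate tests recover the induced phenotype: higher fasting glucose, lower
weight, and elevated baseline plantar latency in the neuropathic group.

The same stages are available as library functions — `trimmed_baseline`,
`compute_mpe`, `generate_schedule`, `summarize_intervals`, `fit_cubic`,
`extract_landmarks`, `block_duration`, `roc_from_scores`, `compare_auc`,
`t_test_from_summary`, `generate_study`, `run_pipeline` — see
`docs/methods.md` for the model and estimator details.

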
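# sizeflm

Functional linear models (FLMs) for size-structured contributions of social
insect workers to colony demography.

Bumblebee (*Bombus*) colonies contain workers whose body sizes vary several
fold, and workers of different sizes perform different tasks.  Whether more
large workers (or more small ones) actually improve colony performance is
hard to read off behavioural observation alone.  `sizeflm` implements the
scalar-on-function regression approach to this question: each weekly
colony-level vital rate is regressed on the colony's *worker size
composition* — the vector of worker counts per intertegular-span (IT) bin —
with a coefficient that is a smooth function of body size,

    g(E[Y_n]) = β₀(colony) + Σₓ β(s_x) · W_{n,x}  (+ log days offset),

where `W_{n,x}` is the number of workers of size `s_x` present in week `n`
and `β(s)` is the size-specific per-capita slope, represented as a natural
cubic regression spline (at most five knots) with a second-derivative
penalty.  Five vital rates are supported, each with its field-standard
family: weekly egg production (negative binomial with a log-days offset),
larval development time (negative binomial), daily larval survival
(binomial day trials), and the mean and CV of callow — newly emerged —
worker size (Gaussian).

The package covers the full analysis path:

* `sizeflm.brood_data` — brood-cell fate records from weekly photo mapping,
  cell-count imputation for undifferentiated clumps, and the exclusion
  rules for ambiguous fates (unseen cells with photo gaps over 8 days);
* `sizeflm.vital_rates` — vital-rate response tables and lagged size
  compositions (previous week, or averaged over a cell's development
  window);
* `sizeflm.flm` — the penalized-IRLS FLM engine as a scikit-learn-style
  estimator (`FunctionalLinearModel`), with GCV (default) or approximate
  REML smoothing selection, profiled negative-binomial overdispersion,
  approximate Wald p-values, a unimodality screen and shape labelling;
* `sizeflm.selection` — likelihood-ratio term tests, knot selection, and
  pooled-versus-separate AIC treatment comparisons;
* `sizeflm.synthetic` — a weekly colony-census simulator with known
  coefficient functions, for end-to-end parameter-recovery scoring;
* `sizeflm.pipeline` / the `sizeflm` CLI — one-command orchestration.

## Worked example

Simulate a two-treatment study in which more large workers raise egg
production, then run the full analysis:

```python
from sizeflm import RunConfig, run_study, SyntheticConfig, simulate_colony_study

cfg = SyntheticConfig(treatments=("low", "high"),
                      n_colonies_per_treatment=3, n_weeks=8, seed=21)
cfg.true_beta["egg_production"] = ("increasing", 1.0)
brood, workers, truth = simulate_colony_study(cfg, out_dir="study")

tmap = {c: c.rsplit("_", 1)[0] for c in workers["colony_id"].unique()}
rc = RunConfig(brood_path="study/brood.csv", workers_path="study/workers.csv",
               treatment_map=tmap, n_bins={"low": 14, "high": 17},
               out_dir="study/out", seed=1)
bundle = run_study(rc)
print(bundle["table2"][["vital_rate", "treatment", "wsc_sign", "wsc_trend"]])
```

The run prints a shape-label table whose egg-production rows are

```
       vital_rate treatment  wsc_sign   wsc_trend
   egg_production      high      none        none
   egg_production       low     mixed  increasing
```

i.e. in the treatment carrying the injected effect the fitted coefficient
function is negative at small sizes and positive at large sizes
(`mixed`) and rises with size (`increasing`), while the null treatment shows
no detectable per-capita effect.  `study/out/` also receives the fit
summaries (EDF, AIC, approximate smooth-term p-values), the
coefficient-function table with pointwise standard errors, predicted
responses for 2.5 / 3.5 / 4.5 mm workers, and the pooled-versus-separate
AIC comparison table.

The same analyses run from the shell:

```
sizeflm simulate --out study --seed 21
sizeflm fit --config run.yaml
sizeflm recover --shape increasing --magnitude 1.0 --replicates 20 --seed 1
sizeflm plot --bundle study/out
```

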
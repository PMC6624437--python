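# embryopt

Neuro-fuzzy response-surface modeling and multi-objective optimization of
in-vitro somatic embryogenesis culture conditions.

The package provides an end-to-end pipeline:

1. **simulate** — generate a replicated factorial tissue-culture dataset
   (24 treatments × 45 replicates = 1080 rows) over eight inputs: 2,4-D and
   BAP concentrations, three carbohydrates (sucrose, glucose, fructose), and
   the RGB coding of the light-quality treatment.  The noise-free response
   surface is calibrated so the published optimal medium yields an
   embryogenesis frequency (EF) of 100 % and 12.83 somatic embryos per
   explant (NSE), and low-PGR media yield no response.
2. **train** — fit one first-order Sugeno neuro-fuzzy (ANFIS) model per
   response (CF, EF, NSE): Gaussian premises seeded by subtractive
   clustering, linear consequents solved by slope-penalized ridge least
   squares, premises refined by full-batch gradient descent, alternating for
   10 epochs with best-epoch retention.
3. **evaluate** — R², RMSE and mean bias error on the 810/270
   train/test split (the split re-draws until the training range covers the
   test range per feature).
4. **sensitivity** — leave-one-feature-out retraining per input (VSE), its
   ratio to the full-model error (VSR), and the resulting importance ranks.
5. **optimize** — NSGA-II (binary tournament, simulated binary crossover,
   polynomial mutation, elitist non-dominated sorting with crowding
   distance) maximizes the EF and NSE surrogates over the training-data box;
   the reported solution is the Pareto-front member closest to the pair of
   maxima observed in the data (ideal-point rule).
6. **validate** — the noise-free generator truth at the selected optimum is
   reported beside the model's prediction as an in-silico validation.

## Command line

```bash
embryopt simulate --seed 42 --out out/           # writes out/dataset.csv
embryopt train    --seed 42 --dataset out/dataset.csv --out out/
embryopt evaluate --seed 42 --dataset out/dataset.csv --models out/ --out out/
embryopt sensitivity --seed 42 --dataset out/dataset.csv --out out/
embryopt optimize --seed 42 --dataset out/dataset.csv --models out/ --out out/
embryopt run      --seed 42 --out out/           # full pipeline + report.json
```

All subcommands accept `--config PATH` (YAML or JSON pipeline configuration),
`--seed` (overrides every seed), `--out DIR` and `--log-level`.  A full run
writes `dataset.csv`, `model_{CF,EF,NSE}.json`, `fit_report.json`,
`sensitivity.csv`, `pareto_front.csv` and `report.json`.

## Library use

```python
from embryopt import (
    GeneratorConfig, generate, split, fit, NsgaConfig, evolve,
    select_ideal_point, sensitivity_report, run, PipelineConfig,
)

data = generate(GeneratorConfig(seed=42))
train, test = split(data, 0.75, seed=0)
report = run(PipelineConfig())   # the whole pipeline, deterministic
```

## Notes on design

- One independent ANFIS model per output; inputs are min–max scaled
  internally, all public I/O is in natural units; models serialize
  losslessly to JSON.
- Rule bases for the 8-input models use subtractive clustering on the
  distinct design points (a grid partition over 8 inputs would need 3⁸ =
  6561 rules).  Grid partition is retained for low-dimensional use and for
  oracle tests.
- Premise widths are proportional to each input's standard deviation so
  rules seeded in one factorial arm still respond weakly in the others;
  the consequent ridge penalizes slopes much harder than intercepts so the
  surrogates extrapolate conservatively — both choices exist to keep the
  downstream optimizer inside trustworthy regions of the surrogate.
- Predicted frequencies are clipped to [0, 100] (and NSE to ≥ 0) inside the
  optimization objective so the optimizer cannot chase extrapolation
  artifacts.
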
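# t1std — post-hoc standardisation of parametric cardiac T1 maps

Quantitative cardiac T1 mapping lacks universally valid reference values:
the apparent T1 of myocardium depends not only on tissue, but on
*confounding parameters* (CPs) — the subject's age and sex, the scanner,
and the mapping sequence variant. Every hardware or protocol change
therefore traditionally demands a fresh local healthy reference cohort.
`t1std` implements a post-hoc standardisation approach for researchers and
CMR imaging scientists: regression models learn, from pooled healthy
training data, the bias each CP induces relative to a chosen *reference CP
environment*, and subtract that bias from segmented pixel values so that
maps acquired anywhere become comparable.

## The model

For a segmented pixel with apparent value $v$ and CP vector $c$, the bias
regression estimates

$$\hat b(v, c) \approx v - \tau_{k(v)}$$

where $\tau_k$ is the *target* value of bin $k$ — the mean T1 of healthy
training pixels acquired in the reference environment — and $k(v)$ is the
pixel's bin in an optional partition of the T1 axis (1–10 bins via eight
clustering algorithms). The standardised value is $v - \hat b$. A pipeline
setting combines:

* **regression type**: `linear`, `lsvr` (linear support vector), `rfr`
  (random forest, 1000 trees), `etr` (extra trees, 1000 trees);
* **y type**: `absolute` (bias in ms, shifts all pixels equally) or
  `relative` (bias as a fraction of the apparent value);
* **mode**: `individual` (one regression per CP, all other CPs held at
  their reference values), `cascaded` (sequential per-CP fits on
  progressively standardised data; order-dependent), `ensemble` (one
  regression over the whole encoded CP vector);
* **bins** and **cluster type** for the T1-axis partition.

The best performing pipeline (BPSP) is selected by the coefficient of
variation $\mathrm{COV} = \sigma / \mu$ of per-map mean T1 across a
held-out healthy test set: first all 24 single-bin combinations of
regression type × y type × mode, then the top three across 2–10 bins ×
8 clustering algorithms (216 more; 240 settings in total). Diagnostic
separability of standardised cohorts is assessed by ROC analysis with the
Youden-optimal threshold and the evidence rule
sensitivity + specificity ≥ 150 %.

A synthetic generator produces ring-phantom cohorts (the annulus mimics a
full circular mid-ventricular myocardium segmentation) with exactly known
injected CP effects, so the whole toolchain runs and is tested without
clinical data.

## Worked example

```python
import t1std as t

cps = t.default_cp_definitions()          # age, sex, scanner, sequence
train, truth = t.generate_cohort(60, noise_pixel_sd=30.0, seed=7)
test, _ = t.generate_cohort(20, noise_pixel_sd=30.0, design="mixed", seed=8)

model = t.fit_pipeline(
    train, t.PipelineSetting("linear", "absolute", "cascaded"), cps)
print(model.summary())
print(f"baseline COV : {100 * t.baseline_cov(test):.2f}%")
print(f"standardised : {100 * t.evaluate_pipeline(model, test):.2f}%")

res = model.standardise_map(test[0])
print(f"map {res.map_id}: {res.mean_before:.1f} -> {res.mean_after:.1f} ms")
for name, comp in res.bias_components:
    print(f"  bias[{name:<8}] = {comp.mean():+8.2f} ms")
```

prints (abridged):

```
regression type : linear
y type          : absolute
mode            : cascaded
per-bin targets (ms): 1142.41
training maps   : 60 (12240 pixels, 60 subjects)
baseline COV : 9.01%
standardised : 4.21%
map healthy-000-00: mean 945.2 -> 1058.5 ms
  bias[age     ] =    +2.05 ms
  bias[sex     ] =    +0.00 ms
  bias[scanner ] =  -115.34 ms
  bias[sequence] =    +0.00 ms
```

The cascaded linear pipeline halves the inter-subject COV of the healthy
test set; the first map was acquired on the 1.5 T scanner category, and the
estimated −115 ms scanner bias (this subject's share of the injected field
strength effect) is removed, moving its mean toward the reference
environment around 1142 ms.

The same workflow is available from the shell:

```bash
t1std simulate --config cfg.json --out data/ --seed 5
t1std train --data data/ --cohort-filter healthy --out pipeline.t1pipe
t1std gridsearch --train data/ --test testdata/ --seed 5 --report grid.csv
t1std standardize --pipeline pipeline.t1pipe --data data/ --out results/
t1std evaluate --results results/ --report eval.json
```

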
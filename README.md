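# bnsens — noise sensitivity of Bayesian network diagnostic models

How much diagnostic accuracy does a discrete Bayesian network (BN) lose when
its conditional probability parameters are corrupted?  A widely repeated
belief holds that BN inference is barely sensitive to parameter precision.
`bnsens` puts that belief to the test for medical-style diagnostic models:
it injects controlled noise into CPT parameters — unbiased, or biased toward
the over-/underconfidence typical of elicited probabilities — and measures
the resulting loss of leave-one-out diagnostic accuracy.

Who it is for: knowledge engineers deciding how much effort to spend
refining elicited probabilities, and researchers studying the robustness of
probabilistic graphical models.

## The model

A diagnostic BN has one class (disease) node `D` and finding nodes tagged as
medical history (*h*), physical examination (*p*) or laboratory results
(*l*).  Noise is applied per CPT column (one conditional distribution
`Pr = (p_1, …, p_k)`) in base-10 log-odds space, `Lo(p) = log10(p/(1−p))`:

* **symmetric** — every entry independently becomes
  `p′ = Lo⁻¹[Lo(p) + Normal(0, σ)]`, and the column is renormalized;
* **overconfidence** — the smallest entry `p_S` is shrunk,
  `p_S′ = Lo⁻¹[Lo(p_S) − |Normal(0, σ)|]`, and the removed mass `p_S − p_S′`
  is added to the largest entry (entropy can only fall);
* **underconfidence** — the largest entry `p_L` is shrunk the same way and
  the removed mass is given to the smallest entry (the column flattens).

Evaluation is leave-one-out: for each of *n* records the CPTs are
re-estimated from the other *n* − 1 records, perturbed with fresh draws, and
the held-out record's class is predicted from its findings as
`argmax_d P(D = d | findings)` by exact inference.  Accuracy is the fraction
of correct argmax diagnoses; the mean posterior assigned to the true
diagnosis is tracked alongside, because a stable average posterior can hide
rank flips among competing diagnoses on individual cases.  Restricting the
noise targets to semantic node classes (*h*/*p*/*l*/*d*) or to the class
node's Markov blanket localizes where precision matters.

Real diagnostic models with matched patient datasets are essentially
unavailable, so the package ships a synthetic gold-standard generator:
class-rooted DAGs with Dirichlet-drawn CPT columns (concentration is a
difficulty dial; laboratory columns can be sharpened), forward-sampled
records, optional missingness imputed with per-variable normal/absent
states, and an exact Bayes-optimal accuracy ceiling for calibration.

## Worked example

```python
from bnsens import (GeneratorConfig, generate_network, make_benchmark,
                    bayes_optimal_accuracy, NoiseSensitivityStudy,
                    EvaluationConfig)

truth = generate_network(GeneratorConfig(seed=7))        # 13-node gold standard
print(bayes_optimal_accuracy(truth, method="exact"))
# BayesAccuracy(value=0.9908182063987627, se=0.0, method='exact')

data, normals = make_benchmark(truth, n=400, seed=7)     # 400 patient records
study = NoiseSensitivityStudy(
    truth.network, data, tags=truth.tags, normals=normals,
    config=EvaluationConfig(sigma_grid=(0.0, 0.5, 1.0, 2.0),
                            replicates=3, base_seed=7, keep_cases=False),
)
res = study.fit()          # sigma sweep over all three noise types
print(res.summary())
```

```
Leave-one-out diagnostic accuracy (mean over replicates)
================================================================
sigma               0.0     0.5     1.0     2.0
noise_type
overconfidence   0.9675  0.9617  0.9458  0.8942
symmetric        0.9675  0.9108  0.7633  0.5450
underconfidence  0.9675  0.7875  0.3542  0.1092
```

Reading the table: the unperturbed pipeline reaches 96.75% accuracy, close
to the 99.1% Bayes-optimal ceiling of this gold standard (the residual gap
is parameter-estimation error at n = 400).  Noise always degrades accuracy,
but overconfident noise is by far the least damaging (89.4% at σ = 2),
symmetric noise is intermediate, and underconfident noise — flattening the
most diagnostic columns — is catastrophic (10.9%, near the 1/4 chance level
of this four-disease model).  `study.fit("markov_blanket")`,
`study.fit("semantic")` and `study.fit("pradhan")` run the
blanket-restricted, node-class-restricted and average-posterior protocols;
every result object carries the sweep table (`res.table`), per-case detail
(`res.cases`), `summary()` and `plot()`.

The same pipeline is scriptable from the shell:

```sh
bnsens generate --seed 3 --records 500 --out-prefix demo
bnsens sweep --model demo.bif --data demo.csv --class-var disease \
       --normals demo.normals.csv --seed 5 --out-prefix results/sweep --plot
bnsens experiment mb --model demo.bif --data demo.csv --class-var disease \
       --normals demo.normals.csv --seed 5 --out-prefix results/mb
```

Models travel as BIF 0.15 text, datasets as CSV of state labels (empty cell
= missing), tag and normal-state maps as two-column CSVs.

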
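# pasvm

Cancer-classification pipeline for high-dimension / small-sample expression
matrices: **FCBF feature selection** followed by an **RBF soft-margin SVM**
whose hyperparameters are tuned by a **PSO→ABC hybrid swarm optimizer**
("PA-SVM").

Expression profiles — microarray mRNA panels, proteomic spectra — routinely
have 2,000–25,000 features for only tens of samples, most features being
irrelevant or redundant. `pasvm` addresses this in two stages:

1. **Fast Correlation-Based Filter (FCBF).** Features are discretized
   (Fayyad–Irani MDL) and scored against the class label by symmetrical
   uncertainty, `SU(X, Y) = 2·IG(X|Y) / (H(X) + H(Y)) ∈ [0, 1]`. Features
   with `SU > δ` are kept, ordered by decreasing SU, and any feature `j`
   *predominated* by a stronger feature `i` (`SU(i, j) ≥ SU(j, class)`) is
   removed as redundant. Reductions are typically drastic (thousands of
   features → tens).
2. **Swarm-tuned SVM.** The penalty factor `C` and RBF coefficient `γ`
   (kernel `K(x, y) = exp(−γ‖x−y‖²)`) are searched in
   `(log2 C, log2 γ) ∈ [−8, 8]²` against 10-fold cross-validated accuracy
   (`F = V_accuracy`). Particle swarm optimization
   (`v ← ωv + c1 r1 (p_i − x) + c2 r2 (p_g − x)`, `x ← x + v`) runs first;
   its best solution seeds the food sources of an artificial bee colony
   search (employed / onlooker / scout phases with neighborhood moves
   `x_i + r (x_i − x_j)` and fitness-proportional selection
   `P_i = fit_i / Σ fit`). The hybrid combines PSO's exploitation with
   ABC's scout-driven exploration and never returns less than the PSO
   stage's best.

Both optimizer stages default to population 30, 100 iterations, scout
limit 50, and 10-fold CV — the standard configuration for this method
family. See `docs/methods.md` for the full model description, design
choices, and limitations.

## Worked example

Generate a synthetic dataset shaped like a small expression study
(60 samples, 10 informative + 10 redundant + 480 irrelevant features),
select features, and fit the full pipeline:

```sh
pasvm synth --preset small --seed 1 --out toy.csv
pasvm select --input toy.csv --out selected.json
pasvm train --input toy.csv --seed 1 --out model.bin --report report.json
pasvm predict --model model.bin --input toy.csv --out labels.csv
```

The train step prints, for the run above:

```json
{"cv_accuracy": 1.0, "C": 37.876772579039184, "gamma": 0.36530823515699545}
```

meaning the tuned SVM classifies the 10-fold CV splits of the
FCBF-reduced matrix perfectly (`cv_accuracy` is the optimized fitness, in
[0, 1]) at penalty `C ≈ 37.9` and kernel coefficient `γ ≈ 0.365`.
`report.json` additionally records the selected feature indices (10 of
500 for this seed) and the evaluation count. Python equivalent:

```python
from pasvm.datasets import SyntheticSpec, generate_synthetic
from pasvm.svm_model import fit_pa_svm

data = generate_synthetic(SyntheticSpec(seed=1))
model = fit_pa_svm(data, seed=1)
print(model.cv_accuracy, model.params)      # 1.0 SVMParams(C=37.88.., gamma=0.365..)
print(model.predict(data.matrix)[:5])       # ['class0' 'class0' ...]
```

The repeated-runs comparison protocol (best of R runs per arm, like a
published method-comparison table) is available as:

```sh
pasvm compare --input toy.csv --runs 10 --out comparison.json
```

which reports best-of-R and median accuracy for a default-parameter SVM,
PSO-only tuning, ABC-only tuning, and the PA hybrid, all on the same
FCBF-reduced matrix. To apply the same protocol to a real downloaded
expression dataset, convert it to CSV with a `class` label column (or a
label row with `--orientation features-in-rows`) and point the same
commands at it.

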
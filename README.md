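# ictd — dual-view eye-movement emotion classification

Eye-tracking signals carry two complementary windows on affective state:
gaze dynamics (fixations, saccades) and pupillometry. `ictd` implements a
dual-branch CNN–transformer classifier for such data in which

* the transformer's feedforward sublayer is replaced by an **incremental
  feature feedforward network (IFFN)** — a partial-convolution projection,
  channel split and elementwise cross-channel gating that re-weights
  salient feature channels, and
* the two views are trained jointly with a **cosine-similarity deep CCA
  loss**: per-view projection networks `f₁, f₂` are optimised so that the
  centred projections maximise

  `J = tr(H₁ᶜᵀ H₂ᶜ) / (‖H₁ᶜ‖_F ‖H₂ᶜ‖_F)`,

  the cosine of the flattened matrices, combined with cross-entropy as
  `L = ω₁·L_CE + ω₂·(−J)` (defaults ω₁ = 0.1, ω₂ = 0.9).

The package is aimed at researchers studying emotion recognition from
eye movements who need a tested, self-contained reference implementation:
every stage — synthetic data with known ground truth, raw-stream
preprocessing and I-VT event detection, trial-level feature extraction
and ANOVA screening, the network, subject-independent cross-validation
and the component ablation — runs on CPU with no external datasets. The
neural network runs on a small numpy reverse-mode autodiff core shipped
in the package, with all gradients finite-difference-verified.

## Worked example

```python
import numpy as np
from ictd import (SyntheticSpec, generate_dual_modality,
                  subject_kfold_split, train_ictd, evaluate, TrainConfig)

ds = generate_dual_modality(SyntheticSpec(
    n_classes=4, n_subjects=10, trials_per_subject=100,
    class_separation=8.0, noise_sd=(0.5, 0.5), seed=0))

folds = subject_kfold_split(ds, folds=5, seed=0)
fold = (folds.train_subjects[0], folds.test_subjects[0])
trained = train_ictd(ds, train_cfg=TrainConfig(epochs=10, seed=0), fold=fold)

test = np.isin(ds.subject_ids, fold[1])
report = evaluate(trained, ds.gaze_view[test], ds.pupil_view[test],
                  ds.labels[test], n_classes=4)
print(report.accuracy, report.macro_f1)
```

Running `python examples/train_classifier.py` (the same computation with
logging) prints:

```
held-out subjects: [4 6]
epoch  0  loss +0.174  CE 1.761  align -0.002  val acc 0.250
epoch  3  loss +0.109  CE 1.276  align -0.021  val acc 0.945
epoch  6  loss +0.095  CE 1.046  align -0.011  val acc 0.995
epoch  9  loss +0.093  CE 1.003  align -0.008  val acc 1.000
held-out accuracy 1.000  macro-F1 1.000
```

Cross-entropy falls from chance (ln 4 ≈ 1.386) while the alignment term
(−J of the batch projections) trends negative; held-out accuracy is
measured on two subjects the model never saw, the subject-independent
protocol used throughout. The other scripts in `examples/` demonstrate
the generator, the raw-stream feature path, the alignment objective
against its closed-form linear-CCA oracle (both recover the designed
correlation 1/(1+σ²) = 0.50), and the ablation harness.

## Command line

A thin CLI wraps the library for shell pipelines:

```
ictd simulate --classes 4 --subjects 10 --seed 7 --out data/
ictd train    --data data/ --epochs 30 --seed 7 --out model/
ictd evaluate --model model/ --data data/ --out report/
ictd extract  --recording rec.csv --dialect eseed --out features.csv
ictd screen   --features features.csv --alpha 0.05 --out-dir screened/
ictd ablate   --data data/ --variants iffn,dcca,both --out ablation/
```

Every run writes a resolved-config echo next to its outputs; identical
config + seed reproduces identical artifacts.

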
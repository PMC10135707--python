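# pelvistrat

Preoperative stratification of laparoscopic rectal-surgery difficulty from
pelvis bone masks.

Total mesorectal excision in a *difficult pelvis* — narrow inlet, deep
curve — is harder, slower and riskier, and patients predicted to be
difficult may be better served by a transanal approach. `pelvistrat`
implements the full analysis pipeline for this problem for researchers in
surgical data science:

* **Stage I** — cohort-comparison statistics linking an intraoperative
  difficulty grading to perioperative outcomes (Pearson χ² without
  continuity correction, pooled two-sample *t*, Mann–Whitney).
* **Stage II** — a 3D residual network (ResNet-50 topology) over binary
  pelvis masks (bilateral ilium + sacrococcyx), with a CBAM attention block
  in every residual block, pooling replaced by even-kernel stride-2
  convolutions, a position-preserving shrink-convolution head, and
  multiplicative fusion of clinical covariates (BMI, sex, neoadjuvant
  therapy). The score is σ(logit) ∈ (0,1); training minimises
  −[y log f(x) + (1−y) log(1−f(x))] with AdamW, gradient clipping at 0.5
  and 4× per-epoch flip/rotation augmentation, under stratified 4-fold
  cross-validation; the merged model averages the four fold scores.
* **Attention maps** — 3D GradCAM++
  (α = g²/(2g² + Σ f·g³), heatmap = ReLU(Σ_c [Σ α·ReLU(g)]·f_c)),
  Demons non-rigid registration to a common space, cohort-average heatmaps,
  and top-0.5% highlighting.
* **Synthetic phantoms** — since patient MRI cannot be redistributed, a
  built-in generator produces binary pelvis phantoms whose *inlet width*
  drives the difficulty label through a logistic model with realistic
  clinical covariates, so every stage is testable end to end and the
  pipeline's ability to recover a known geometry→difficulty mechanism is a
  measurable property.

The network and its training loop run on a small NumPy reverse-mode
autodiff engine included in the package (`pelvistrat.nn`), whose operators
are validated by finite-difference tests; NIfTI I/O, resampling and Demons
registration use SimpleITK; metrics and statistics use scikit-learn and
SciPy behind the package's interfaces.

## Worked example

Train the desk-scale preset (32³ phantoms, 4 folds) and merge:

```bash
python examples/03_train_and_merge.py
```

```
per-fold held-out accuracy: [0.75, 0.75, 0.833, 0.833]
merged model: accuracy 0.833  precision 0.750  specificity 0.667  recall 1.000  F1 0.857
              AUC 0.944  AP 0.948
confusion: {'tp': 6, 'fp': 2, 'tn': 4, 'fn': 0}
```

The merged score of each held-out case is the mean of the four fold scores;
with the generator's strong narrowness signal the ensemble separates
difficult from non-difficult phantoms well above chance even in this
2-minute demonstration (12 test cases). Attention maps close the loop:

```bash
python examples/04_attention_maps.py
```

```
computed 12 per-case heatmaps at input resolution (32, 32, 32)
registration-averaged heatmap: 164 voxels highlighted (top 0.5%)
fraction of highlighted voxels inside the inlet band: 0.98
```

98% of the hottest voxels fall in the gap between the iliac wings — the
pelvic inlet whose width actually generated the labels.

The other examples cover cohort generation (`01`), preprocessing and
augmentation (`02`), and the stage-I statistics plus printed-table auditing
(`05`). A thin CLI wraps the same pipeline
(`pelvistrat simulate | stats | train | evaluate | run-all`).

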
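# nextvisit

Disease-onset prediction over coded patient visits, reformulated to match
masked-code pretraining.

Risk prediction from structured EHR data is usually cast as binary
classification: encode the patient's visit history, pool it, and train a
fresh linear head.  When a BERT-style encoder has been pretrained with a
masked-code objective, that head throws away the geometry pretraining built.
This package implements and benchmarks the alternative: score the patient by
the probability that one of the eight pancreatic-cancer ICD-10 codes
(C25.0–C25.4, C25.7–C25.9) fills the *next visit*, using the pretrained
token-embedding rows of those codes as the output layer.

Three heads share one encoder:

* **bc** — binary classification: `p = σ(w·c + b)` on the pooled patient
  context vector `c` (the masked sum of contextualized embeddings).
* **sum** — token prediction: `p_k = σ(L_k·c)` against the label tensor
  `L ∈ R^{8×d}` (the target codes' embedding rows); patient score
  `max_k p_k`.
* **mask** — next-visit masked-token prediction: a `[MASK]` token is
  appended at visit ordinal `i+1` and scored `p_k = σ(L_k·h_mask)`; with
  the tied MLM output projection these logits are *identical* to the
  pretraining scores restricted to the eight target ids.

Because real clinical encoders and cohorts are proprietary, the package
ships a synthetic cohort generator (precursor-code exposure → logistic onset
risk, censored at the index date), masked-code pretraining on a small
NumPy transformer with its own reverse-mode autograd, the five from-scratch
baselines (LR, GRU, BiGRU, LSTM, BiLSTM), and the few-shot learning-curve
protocol (7:1:2 splits, balanced sampling ladders, 3 runs per cell, AUROC
on the full test split).

## Worked example

```python
import nextvisit as nv

cohort = nv.generate_cohort(nv.GeneratorConfig(n_patients=2000, seed=11))
results = nv.MaskedLMModel(cohort).fit(epochs=6, seed=1)
print(results.summary())

train, val, test = nv.split_cohort(cohort, nv.SplitSpec(seed=0))
ftr, fva = nv.sample_fewshot(train, val, 100, nv.SamplingPolicy("balanced_both"), seed=0)
model = nv.OnsetModel(ftr, head="mask", pretrained=results,
                      finetune=nv.FinetuneConfig(max_epochs=20, patience=5))
fit = model.fit(valid_records=fva, seed=0)
print(fit.summary())
print(f"test AUROC: {fit.auroc(test):.3f}")
```

prints

```
Masked-code pretraining
  vocabulary size      : 210
  encoder parameters   : 24832
  epochs run           : 6
  held-out loss (init) : 5.3040
  held-out loss (final): 4.5913
Onset prediction head: mask
  encoder parameters : 24832
  epochs run         : 5 (best epoch 0)
  final train loss   : 0.3060
  best val AUROC     : 0.7464
test AUROC: 0.747
```

Pretraining cuts the held-out masked-code cross-entropy from 5.30 to 4.59
nats.  Fine-tuned on only 50 cases and 50 controls, the mask head scores
AUROC 0.747 on the 400-patient test split — and "best epoch 0" records that
validation selected the *un-fine-tuned* checkpoint: at this sample size the
pretrained next-visit geometry is already the best available model, which is
the point of the reformulation.  (The precursor-count oracle ceiling for
this generator is ≈ 0.82.)

The same pipeline is scriptable:

```
nextvisit simulate --out cohort.jsonl --seed 7
nextvisit pretrain --cohort cohort.jsonl --out ckpt --epochs 6 --seed 7
nextvisit learning-curve --cohort cohort.jsonl --ckpt ckpt \
    --models bc,sum,mask,lr,gru --sizes 10,100,500 --runs 3 --out results/
```

which writes per-cell AUROCs (`learning_curve.csv`), mean/std aggregates and
a log-scale AUC-vs-size plot.

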
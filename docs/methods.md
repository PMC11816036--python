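# Methods

## Problem and approach

`nextvisit` studies how the *form* of a disease-onset prediction head affects
few-shot fine-tuning of a BERT-style encoder over coded patient visits.  A
patient is an ordered sequence of visits, each a set of clinical codes; the
outcome is whether one of eight designated pancreatic-cancer ICD-10 codes
(C25.0–C25.4, C25.7–C25.9) appears in a future visit.  Three interchangeable
heads map the encoder output to a patient-level risk score:

* **bc** (binary classification): a fresh linear layer on the pooled patient
  context vector, `score = σ(w·c + b)`.
* **sum** (token prediction): dot products of the pooled context vector `c`
  with the *label tensor* `L ∈ R^{8×d}` — the token-embedding rows of the
  eight target codes — with `score = max_k σ(L_k·c)`.
* **mask** (next-visit masked-token prediction): a `[MASK]` token is appended
  at the position of the first future visit (ordinal `i+1`); the head scores
  `σ(L_k·h_mask)` from the contextual vector at that position and again takes
  the max.

Because the encoder is pretrained with a masked-code objective whose output
projection is the *tied* token-embedding table, the mask head is exactly the
restriction of the full-vocabulary pretraining scores to the eight target
ids.  That identity is enforced as a property test (no bias on sum/mask
logits by default, to keep it exact up to BLAS summation order), and is the
formal sense in which the downstream task is "aligned" with pretraining.

## Synthetic cohorts

Real pretrained clinical encoders and their cohorts are proprietary, so all
experiments run on a synthetic generator whose defaults define the study
conditions:

| parameter | default | meaning |
|---|---|---|
| `vocab_size` | 200 | ordinary codes, "D###/M###/P###" mix |
| `n_precursor_codes` | 10 | codes that raise onset risk |
| `visits_per_patient_range` | (2, 10) | uniform |
| `codes_per_visit_range` | (2, 8) | uniform |
| `zipf_exponent` | 0.8 | code frequency profile |
| `precursor_effect` | 0.5 | log-odds per precursor occurrence |
| `case_fraction_target` | 0.4 | calibrated prevalence |
| `n_patients` | 2000 | pretraining corpus size |

Code draws follow a Zipf-like frequency profile over a seeded permutation;
precursors are taken from moderately common frequency ranks so their counts
vary across patients.  A patient's latent risk is logistic in the precursor
occurrence count; the intercept is calibrated by root finding (`brentq`) so
the expected prevalence equals `case_fraction_target`, making the realized
case fraction a plain binomial around the target when the effect is zero.
Cases receive exactly one uniformly drawn target code in a dedicated final
onset visit; `index_visit` points at the preceding visit, so supervised
inputs are always censored at the index date.  Under the defaults the
precursor-count oracle reaches AUROC ≈ 0.82 and full-data logistic
regression ≈ 0.80 — the same order as published clinical benchmarks, which
is what makes head comparisons meaningful at this scale.

What the generator does *not* emulate: real ontologies, visit timestamps,
demographics, billing-lag and diagnostic-sensitivity artifacts, and any
signal that is not a monotone function of code counts.  Consequently a
bag-of-codes logistic regression is close to the Bayes rule here; passing
tests show the machinery behaves as designed, not that transformers beat
linear models on real EHR data.

## Pretraining

The corpus encodes *full* trajectories, onset visits included (no next-visit
mask): it plays the role of the large uncurated patient pool a foundation
model is pretrained on, so target codes occur in context and their embedding
rows are trained.  Censoring applies to every supervised input.  Corruption
selects 15% of real code positions (the classical recipe; the 80/10/10
treatment split of selected positions is protocol); random replacements draw
from ordinary code ids.  Loss is cross-entropy at selected positions only,
computed by gathering the selected contextual rows before the vocabulary
projection.  Optimization is Adam at 1e-3, batch 100, with a fixed held-out
split (10%) whose corruption is frozen once so its loss is comparable across
epochs.  Six epochs on 2,000 patients (d=32, 2 layers, 2 heads) take well
under a minute on one CPU and drop the held-out loss by ≈ 0.7 nats.

A finding worth recording: the naive geometric picture "target-code
embeddings move toward precursor-code embeddings" is false under softmax
weight tying.  Embedding rows of codes that are high-probability in a
context are pushed *away* from the context directions that rare codes are
pulled toward, so raw embedding-row cosines are dominated by frequency.  The
alignment that matters is functional — contextual vector at the appended
mask position versus label rows — and it is substantial: the *un-fine-tuned*
mask head reaches AUROC ≈ 0.66–0.75 on held-out patients depending on the
test partition.

## Fine-tuning and model selection

All heads fine-tune end to end (encoder + head, label tensor tied and
trainable by default) with Adam at 1e-3 and batch 100, per protocol.  The
sum/mask training objective is per-token binary cross-entropy against the
8-slot multi-hot onset target (all-zero for controls); a "max" policy (BCE
of the max probability against the binary label) is available.  The
per-token default uses the richer supervision the reformulation creates;
both are interpretations, as the original work does not state this loss.

Early stopping monitors validation AUROC, and model selection *includes the
initial, un-fine-tuned state*: with a pretrained encoder the mask head can
start better than any epoch of aggressive 1e-3 fine-tuning, and at this
scale fine-tuning visibly erodes its zero-shot geometry (the published
benchmark reports the same decline for its mask head at larger sample
sizes).  Letting the validation split decide whether zero updates is the
best checkpoint is the natural few-shot policy and applies identically to
every head.

Numerical choices: logistic losses are computed on logits through a stable
softplus; probability-space reference losses clip at 1e-12; AUROC uses the
Mann–Whitney tie convention (scikit-learn); all randomness flows from
explicit integer seeds through `numpy.random.Generator`, and per-cell seeds
in the learning-curve harness derive from `SeedSequence([seed, model, size,
run])`, so every table reruns exactly.

## Benchmark protocol

Cohorts split 7:1:2 with floored validation/test counts and the remainder to
train — the rule reproduces the published triples (31,243 → 21,871/3,124/
6,248 and 3,810 → 2,667/381/762) exactly.  Few-shot cells sample without
replacement under three policies: balanced fine-tuning and validation sets
(sizes ≤ 1000), balanced fine-tuning with the full validation split (sizes
≥ 2000), and the external-cohort ladder keyed on size (balanced both ≤ 30;
balanced train with all-positive validation 40–200; all positives plus
sampled negatives on both sides at 300; all-positive train with full
validation 400–1000).  Every cell is evaluated on the full test split; the
default is 3 runs per cell with mean/std aggregation.  The desk-scale size
ladder is [10, 20, 50, 100, 200, 500, 1000]; the full published ladder up to
10,000 is available by flag.

## Known limitations

* The recurrent baselines learn slowly from scratch: at the protocol's
  learning rates the unidirectional models need tens of epochs to clear
  chance, and the bidirectional variants (lr 1e-5) barely move at
  desk-scale epoch budgets.  This is the intended contrast with pretrained
  heads, but it means "baseline" numbers are schedule-sensitive.
* Because the synthetic risk is logistic in code counts, bag-of-codes LR is
  near-optimal and remains competitive with the heads at the very smallest
  sample sizes; the pretrained-vs-scratch comparison is therefore made at
  n = 100, mid few-shot range.
* The mask-vs-bc few-shot contrast is directional, not asserted: across five
  seeds the paired difference is ≈ +0.04 AUROC at n = 10 and ≈ −0.02 at
  n = 100, with a pooled bootstrap interval that crosses zero — the same
  qualitative shape (advantage at extreme few-shot, fading with n) as the
  published benchmark, at Monte-Carlo scale.
* Encoder capacity (d = 32, 2 layers) and cohort sizes are desk-scale
  choices; absolute AUROC values are not comparable to results obtained
  with large pretrained clinical encoders.
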
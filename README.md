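# stagescreen

Screening children for ADHD-related behaviour from skeleton motion
captured during a robot-led game.

A screening session has 11 ordered stages — one explanation segment, then
five rounds each split into a *waiting* stage (a robot demonstrates) and a
*game* stage (the child plays).  Depth sensors record, per stage, a
variable-length sequence of 18-joint 3D skeleton frames, and clinicians
assign each child one of three labels: **normal**, **ADHD-risk**, or
**ADHD**.  `stagescreen` implements the full analysis pipeline for such
data:

* session containers, a JSON-lines on-disk dialect, and the zero-padding
  preprocessing (per-stage reference lengths from the training set);
* a stage-attentive classifier: one bidirectional LSTM encoder per stage,
  a channel-attention-style gate over the 11 stage features,

  `score = σ( MLP(AvgPool(F)) + MLP(MaxPool(F)) )`,

  multiplicative stage weighting, and a softmax head, trained with
  inverse-frequency-weighted cross-entropy
  `L = −Σᵢ wᵢ tᵢ log pᵢ`, `wᵢ = N/nᵢ` (all in hand-written NumPy,
  gradients verified against finite differences);
* leave-one-person-out (LOPO) cross-validation with a 3×3 confusion
  matrix and the one-vs-rest metric suite (Acc, Se, Sp, F1, FPR, FDR,
  FNR);
* interpretability of the learned attention: per-stage mean scores and
  per-class top-3 distribution rates with a late-vs-early localization
  report;
* a synthetic class-conditional motion generator standing in for the
  (non-deposited) clinical cohort, so everything is testable end to end.

The library is the interface: `import stagescreen` and compose the pieces
(see `examples/`).  A thin CLI (`stagescreen simulate/train/lopo/metrics/
analyze-attention`) wraps the same functions for shell use.

## Worked example

Reproduce the published per-class metric table from its confusion counts
(`python examples/metrics_from_published_confusion.py`):

```
class          Acc%     Se%     Sp%     F1%     FPR     FDR     FNR
NORMAL        98.99  100.00   97.57   99.15   0.024   0.017   0.000
ADHD_RISK     98.15   93.92  100.00   96.87   0.000   0.000   0.061
ADHD          99.16  100.00   99.06   96.35   0.009   0.070   0.000

overall accuracy: 98.15%
(the 11 at-risk misses cap the at-risk sensitivity at 170/181)
```

Each row treats one class against the other two: of 181 at-risk children,
170 were recovered (sensitivity 93.92 %) and none of the other 415 were
mislabelled as at-risk (specificity 100 %); the overall accuracy is the
trace of the confusion matrix over 596.

Train on synthetic children and classify held-out ones
(`python examples/train_and_classify.py`) — the generator plants the
class structure (normal children barely move, ADHD children fidget in
every stage, at-risk children fidget only from the third wait/game pair
onward) and the classifier recovers it:

```
held-out predictions:
  true NORMAL     -> NORMAL     ok  probs=[0.55 0.36 0.1 ] top3=GAME1,GAME2,EXPLAIN
  true ADHD_RISK  -> ADHD_RISK  ok  probs=[0.31 0.64 0.05] top3=GAME1,GAME2,EXPLAIN
  true ADHD       -> ADHD       ok  probs=[0.02 0.07 0.91] top3=GAME1,GAME2,EXPLAIN
  true ADHD       -> ADHD       ok  probs=[0.03 0.09 0.88] top3=GAME1,GAME2,EXPLAIN
  true ADHD_RISK  -> ADHD_RISK  ok  probs=[0.27 0.66 0.07] top3=GAME1,GAME2,EXPLAIN
  true ADHD       -> ADHD       ok  probs=[0.02 0.19 0.79] top3=GAME1,GAME2,EXPLAIN

held-out accuracy: 6/6
```

The probabilities order the three classes (normal, at-risk, ADHD); the
`top3` column lists the stages the attention gate scored highest for that
child.

`examples/attention_localization.py` runs the full LOPO + attention
pipeline at a small size, and `examples/simulate_cohort.py` shows the
generator's class/stage motion structure.

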
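# cefhar — per-frame human activity recognition from wrist accelerometry

`cefhar` is a research library for *classification-every-frame* (CEF) human
activity recognition: instead of cutting a tri-axial accelerometer stream
into fixed windows and labelling each window, it assigns a class to **every
frame** of the sequence — the time-series analogue of semantic segmentation.
It targets short *transition* activities (get-up, laying, stand-up, picking,
sitting) plus walking and a no-movement background, recorded from a
wrist-worn sensor at 15 fps.

The package provides, as plain importable Python (numpy-based, no GPU or
deep-learning framework required):

- **the per-frame network** — three stacked structures of multi-kernel 1-D
  convolutions (kernel widths 5/10/20/50/100, 64 filters), CBAM-style channel
  attention, and dot-product temporal self-attention with sigmoid scores,
  topped by a per-frame softmax head.  The canonical configuration has
  exactly **3,416,583** learnable parameters;
- **the sliding-window baseline** it is compared against — same backbone,
  majority-labelled fixed windows (10/5, 20/10, 40/20 size/overlap),
  confidence-resolved overlap expansion back to frames;
- **frame-level evaluation** — per-class precision/recall/F1 from a pooled
  confusion matrix, macro averages, leave-one-subject-out (LOSO) folds;
- **a synthetic data generator** reproducing the collection protocol of the
  (private) study dataset — 8 subjects × 18 activity scripts × 10
  repetitions of 250-frame recordings — from a gravity-orientation signal
  model, so every experiment runs without any download;
- a thin `cefhar` command-line interface and narrative scripts under
  `examples/`.

The model is trained with the cross-entropy **summed over frames**,
`L = −Σ_j Σ_i y_ji log z_ji`, by Adam (lr 1e-3); full protocol 200 epochs at
batch 100, desk preset 30 epochs at batch 16.  See `docs/methods.md` for the
complete model and generator description.

## Worked example

Train the desk-scale preset (16 filters, one block) on one synthetic subject
and score every frame of a second, unseen subject:

```bash
python examples/02_train_and_evaluate.py
```

prints (about two minutes on one CPU):

```
epoch-mean loss: 489 317 194 116 76 58 45 36 30 22

held-out subject: macro-F1 0.931, frame accuracy 0.973
  background  P 0.982  R 0.992  F1 0.987
  get-up      P 0.902  R 0.954  F1 0.927
  laying      P 0.948  R 0.872  F1 0.909
  stand-up    P 0.976  R 0.820  F1 0.891
  picking     P 0.983  R 0.898  F1 0.938
  sitting     P 0.912  R 0.901  F1 0.906
  walking     P 0.947  R 0.964  F1 0.956
```

The falling loss is the summed per-frame cross-entropy averaged over
recordings; the table shows that frame-level segmentation transfers to an
unseen subject — every activity, including the sub-3-second transitions, is
recovered with F1 ≈ 0.9, and errors concentrate at segment boundaries.

Other examples: dataset generation and protocol structure (`01`), the
CEF-vs-sliding-window comparison (`03`), attention-map extraction (`04`),
and the canonical parameter ledger (`05`).

## Command-line interface

```bash
cefhar simulate --out data.h5 --seed 0          # protocol-replica dataset
cefhar train --data data.h5 --tiny --out m.npz  # train per-frame model
cefhar evaluate --model m.npz --data data.h5 --report report.json
cefhar compare-sw --data data.h5 --tiny --report sw.json
cefhar inspect-attn --model m.npz --sample rec.csv --out attn
```

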
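"""Train the per-frame model at desk scale and score it on a held-out subject.

Uses a 2-subject slice of the synthetic protocol: train on subject "a",
evaluate frame-by-frame on subject "b".  Prints the per-epoch loss trend and
the per-class precision/recall/F1 of the held-out subject.  Runs in a few
minutes on one CPU.
"""

import cefhar as ch
from cefhar.evaluation import evaluate
from cefhar.training import predict_dataset, train

dataset = ch.generate_dataset(ch.GeneratorConfig(n_subjects=2, reps=10, seed=0))
train_set = dataset.subset(["a"])
test_set = dataset.subset(["b"])

model = ch.CEFNet(ch.tiny_config(seq_len=250), seed=0)
model, history = train(model, train_set, ch.TrainConfig(epochs=30, seed=0))
print("epoch-mean loss:", " ".join(f"{h:.0f}" for h in history[::3]))

preds = predict_dataset(model, test_set)
report = evaluate(preds, [s.labels for s in test_set], dataset.catalog)
print(f"\nheld-out subject: macro-F1 {report.macro_f1:.3f}, "
      f"frame accuracy {report.accuracy:.3f}")
for c, name in enumerate(report.class_names):
    print(f"  {name:11s} P {report.precision[c]:.3f}  R {report.recall[c]:.3f}  "
          f"F1 {report.f1[c]:.3f}")

# The loss is the summed per-frame cross-entropy averaged over recordings; a
# falling trend plus high held-out macro-F1 shows the model recovers the
# frame-level segmentation, not just the dominant background class.
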
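"""Train a discriminant RBM and classify pain states.

Binary abnormality features plus the pain label form the visible layer;
after CD-1 training, a new feature vector is classified by comparing the
free energies of its two label completions (the partition function
cancels in the ratio).  Prints the posterior table head and test-set ROC
metrics at the minimum-distance operating point.
"""

import numpy as np

from painrbm import (
    TrainingConfig,
    confusion_metrics,
    linear_cohort_config,
    generate_patient,
    posterior_table,
    roc_curve,
    train_rbm,
)
from painrbm.discriminant import append_label
from painrbm.pipeline import train_test_split_indices

patient = generate_patient(linear_cohort_config(0), patient_seed=8)
X, y = patient.Z, patient.labels  # ground-truth abnormality bits as features

train_idx, test_idx = train_test_split_indices(y, test_fraction=0.2, seed=0)
V = append_label(X[train_idx].astype(float), 0)
V[:, -1] = y[train_idx]

params = train_rbm(V, TrainingConfig(n_hidden=20, seed=0))
table = posterior_table(X[test_idx], params)
print(table.head(5).to_string(index=False))

roc = roc_curve(table["p1"].to_numpy(), y[test_idx])
thr, fpr, tpr = roc.optimal
preds = (table["p1"].to_numpy() >= thr).astype(int)
cm = confusion_metrics(preds, y[test_idx])
print(f"\ntest AUC          : {roc.auc:.3f}")
print(f"optimal threshold : {thr:.3f} (FPR {fpr:.3f}, TPR {tpr:.3f})")
print(f"sensitivity {cm.sensitivity:.3f} | specificity {cm.specificity:.3f} "
      f"| accuracy {cm.accuracy:.3f}")
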
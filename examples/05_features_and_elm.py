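"""Random convolutional features + closed-form ELM on phantom tubes.

Feature extraction pushes each image through fixed random conv/pool blocks
and flattens the last maps; the ELM then needs only one linear solve to
train.
"""

import numpy as np

from hemolyzer import elm
from hemolyzer.features import default_backbone, extract_features
from hemolyzer.phantoms import sample_dataset
from hemolyzer.pipeline import SplitSpec, split_dataset

images = sample_dataset(100, seed=0)
train, test = split_dataset(images, SplitSpec(0.8, seed=1))

backbone = default_backbone(seed=4)
F_train = extract_features(train, backbone)
F_test = extract_features(test, backbone)
print(f"feature matrix: {F_train.shape[0]} x {F_train.shape[1]}")

y_train = np.array([it.label for it in train])
y_test = np.array([it.label for it in test])
model = elm.fit(F_train, y_train, hidden_nodes=200, alpha=100.0, seed=5)
acc = np.mean(elm.predict(F_test, model) == y_test)
print(f"held-out accuracy with 200 hidden nodes: {acc:.3f}")

table, best = elm.sweep_hidden_nodes(F_train, y_train, candidates=[10, 100, 200], k=4, seed=6, alpha=100.0)
for L_h, cv in table:
    print(f"  L_h={L_h:4d}: 4-fold CV accuracy {cv:.3f}")
print(f"selected hidden nodes: {best}")
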
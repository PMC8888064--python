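"""The full protocol: generate -> split -> equalize -> augment -> extract ->
ELM with CV-selected ridge -> evaluate.

Augmentation touches only the training split, so the reported accuracy is
measured on untouched phantoms.
"""

import json

from hemolyzer.geometric import AugmentConfig
from hemolyzer.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(n_per_class=100, augment=AugmentConfig())
manifest, metrics = run_pipeline(cfg)

for stage in manifest:
    print(stage)
print(f"\ntest accuracy: {metrics['accuracy']:.3f}")
print(f"per-class recall: {[round(r, 3) for r in metrics['per_class_recall']]}")
print("confusion matrix (rows = truth):")
print(json.dumps(metrics["confusion"]))
print(f"ridge level selected by 4-fold CV: {metrics['alpha_selected']}")
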
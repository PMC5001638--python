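"""End-to-end training and detection on synthetic scenes.

Trains the RUSBoost classifier on three phantoms, detects on two held-out
phantoms and prints the FROC summary metrics.  Runs in a couple of minutes.
"""

import madetect as md

train = [md.generate_phantom(seed=100 + i) for i in range(3)]
model = md.train_pipeline([s.image for s in train],
                          [s.annotations for s in train], seed=7, T=100)
print(f"trained {model.n_rounds} boosting rounds")

test = [md.generate_phantom(seed=300 + i) for i in range(2)]
findings = [md.detect(s.image, model) for s in test]
curve = md.froc(findings, [s.annotations for s in test])

for level, sens in zip(md.DEFAULT_CONFIG.fp_levels, curve.sensitivities()):
    print(f"sensitivity at {level:5.3f} FPs/image: {sens:.3f}")
print(f"CPM {md.cpm(curve):.3f}  partial AUC {md.partial_auc(curve):.3f}")
# CPM is the mean sensitivity over the seven standard FP levels; values near
# 1 mean true lesions are ranked above essentially all clutter candidates.
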
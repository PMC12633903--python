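"""The Cross-Modal Fusion rule on hand-made prediction triplets.

Each modality contributes a label rho, a positive-class probability eta,
and its held-out accuracy phi. The rule averages probabilities
(accuracy-weighted) when the modalities agree, and lets the more accurate
modality win — with a logistic adjustment of the probability gap — when
they disagree.
"""

from cmfp import FusionParams, cmf_fuse
from cmfp.fusion import ModalPrediction

params = FusionParams()  # alpha = 0.4, iota = 1, threshold 0.5

cases = [
    ("agreement", ModalPrediction(1, 0.8, 0.7), ModalPrediction(1, 0.6, 0.6)),
    ("disagreement, a more accurate", ModalPrediction(1, 0.9, 0.8), ModalPrediction(0, 0.3, 0.6)),
    ("disagreement, equal accuracy", ModalPrediction(1, 0.55, 0.7), ModalPrediction(0, 0.2, 0.7)),
]
for name, a, b in cases:
    f = cmf_fuse(a, b, params)
    print(f"{name:32s} -> rho={f.rho} eta={f.eta:.5f} branch={f.branch}")

# Expected: the agreement case averages 0.8 and 0.6 weighted by accuracy
# (0.70769); the second case follows modality a (more accurate) with a
# gently adjusted probability just above 0.5; the third follows modality b
# because |0.2 - 0.5| > |0.55 - 0.5| (it is the more confident voice).
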
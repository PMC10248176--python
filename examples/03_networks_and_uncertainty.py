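"""Build the three architectures and predict with Monte-Carlo dropout.

Prints the trainable-parameter counts of the seven reference
configurations and demonstrates the certainty gate on an untrained
network (whose predictions should mostly be rejected).
"""

import numpy as np

from gazeintent import evaluation, networks

print("reference configurations (built vs published parameter counts):")
for name, (kind, cfg) in networks.REFERENCE_CONFIGS.items():
    net = networks.build_network(kind, cfg, seed=0)
    P = networks.count_trainable_parameters(net)
    print(f"  {name:5s} {kind:8s} P={P}  (published {networks.REFERENCE_PARAM_COUNTS[name]})")

net = networks.build_network(*networks.REFERENCE_CONFIGS["Mix3"], seed=7)
window = np.random.default_rng(0).normal(size=(350, 6))
pred = evaluation.predict_with_ue(net, window, n_passes=30,
                                  rng=np.random.default_rng(1))
last = pred.mean[-1]  # the newest subwindow is the one a live system acts on
c = int(np.argmax(last))
margin = last[c] - 2 * pred.std[-1][c]
print(f"\nuntrained Mix3, newest subwindow: argmax class {c}, "
      f"mean {last[c]:.3f}, SD {pred.std[-1][c]:.3f}, margin {margin:.3f}")
print("accepted at Th_L=0.5?",
      evaluation.accept_prediction(
          evaluation.UEPrediction(pred.mean[-1], pred.std[-1],
                                  pred.bin_mean[-1], pred.bin_std[-1], 30), 0.5))
print("(an untrained net is uncertain: mean - 2 SD rarely clears the bar)")
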
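"""Train a small encoder and pick its operating threshold.

A deliberately small run (two short sessions, a sub-reference-size
encoder, few epochs) so it finishes in well under a minute while showing
the full train -> threshold-scan -> gated-evaluation loop.
"""

import numpy as np

from gazeintent import evaluation, networks, preprocess, simulate, training

cfg = simulate.SimulationConfig(n_movements=60, warmup_movements=2)
profile = simulate.ParticipantProfile()
logs = [simulate.simulate_session(cfg, profile, seed=s) for s in (3, 4)]
ds = preprocess.prepare_datasets(logs)

net = networks.build_network("encoder",
                             networks.EncoderConfig(C=8, H=2, ff=8, N_x=1), seed=0)
hist = training.train_network(net, ds.train, ds.val,
                              training.TrainConfig(max_epochs=8, patience=8, seed=0))
print(f"trained {len(hist.train_loss)} epochs; "
      f"loss {hist.train_loss[0]:.2f} -> {hist.train_loss[-1]:.2f}")

th, a_i, scan = evaluation.threshold_scan(net, ds.val_stream, n_passes=15, n_p=10,
                                          rng=np.random.default_rng(1))
print(f"validation scan: Th_L={th:.2f} at the A_P/A_M crossing (A_I={a_i:.1f}%)")

se = evaluation.continuous_stream_eval(net, ds.test_stream, th, n_passes=15,
                                       n_p=10, rng=np.random.default_rng(2))
m = evaluation.compute_metrics(se)
print(f"test stream: A_P={m.A_P:.1f}% over {m.n_accepted} accepted predictions, "
      f"A_M={m.A_M:.1f}% of {m.n_movements} movements, A_VP={m.A_VP:.1f}%")
print("(short training run: expect mediocre numbers; the full-size run in the "
      "README reaches A_P above 80%)")
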
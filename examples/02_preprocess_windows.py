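"""From raw session logs to labeled sliding windows.

Shows the length filter (mean + 3 SD), the 45/5/50 contiguous split, the
[-1, 1] normalization fit on the training split, and the window/subwindow
bookkeeping.
"""

from gazeintent import preprocess, simulate

cfg = simulate.SimulationConfig(n_movements=60, warmup_movements=2)
profile = simulate.ParticipantProfile()
logs = [simulate.simulate_session(cfg, profile, seed=s) for s in (1, 2)]

ds = preprocess.prepare_datasets(logs)

fs = ds.filter_stats
print(f"length filter: mean {fs.mean:.1f} + 3 x SD {fs.sd:.1f} "
      f"-> threshold {fs.threshold:.0f} samples; kept {fs.n_after}/{fs.n_before} movements")
print(f"streams (samples): train {len(ds.train_stream)}, val {len(ds.val_stream)}, "
      f"test {len(ds.test_stream)}  (45/5/50 in order of appearance)")
print(f"windows of {ds.spec.w} samples, step {ds.spec.N_s}, "
      f"{ds.spec.N_w} subwindow labels each")
print(f"window counts: train {len(ds.train)} (stream replicated x{ds.spec.N_T + 1}), "
      f"val {len(ds.val)}, test {len(ds.test)}")
print(f"one window's first five subwindow class labels: {ds.test.cls[0, :5]} "
      "(each = the label of the subwindow's last sample)")
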
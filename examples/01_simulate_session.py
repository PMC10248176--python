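"""Generate one synthetic reach-to-target session and look inside it.

Builds a session of 40 movements, prints the layout geometry, the
movement-length distribution and where the NaN (blink) runs sit.
"""

import numpy as np

from gazeintent import simulate

profile = simulate.ParticipantProfile()
cfg = simulate.SimulationConfig(n_movements=40, warmup_movements=3)
layout = simulate.make_layout(profile)
log = simulate.simulate_session(cfg, profile, seed=42)

print(f"box 0 (neutral) at height {layout.positions[0, 0]:.2f} m, "
      f"0.30 m in front; inner arc at h1={profile.h1} m / r1={profile.r1} m")
print(f"session: {len(log)} samples at 120 Hz "
      f"({len(log) / 120:.0f} s), {log.movement.max() + 1} movements "
      f"(first {cfg.warmup_movements} are warm-up)")

lengths = np.bincount(log.movement)
print(f"movement lengths: mean {lengths.mean():.0f}, min {lengths.min()}, "
      f"max {lengths.max()} samples (Beta-shaped, right-skewed)")

blink = np.isnan(log.eye_left[:, 0])
print(f"blink samples: {blink.sum()} ({100 * blink.mean():.1f}% of the session), "
      "confined to the eye channels")

simulate.write_session(log, "scratch_session.csv", profile, cfg, seed=42)
print("wrote scratch_session.csv (+ .yaml sidecar with profile/config/seed)")
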
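"""Task-performance metrics for a simulated alternation session.

The middle (New) epoch uses low proficiency, so reward rate drops,
pre-reward slowing weakens, and spurious licking rises relative to the
flanking familiar epochs.
"""

import numpy as np

from novelsupp import (
    SimConfig,
    correct_lick_fraction,
    detect_lick_bouts,
    endzone_entries,
    lick_rate,
    normalize_to_famave,
    occupancy_map,
    pre_reward_deceleration,
    rewards_per_min,
    simulate_behavior,
    trial_failure_location,
    unrewarded_endzone_lick_fraction,
)

cfg = SimConfig(seed=7, proficiency=(0.9, 0.3, 0.9))
b = simulate_behavior(cfg)

rates = {ep: rewards_per_min(b, ep) for ep in b.epoch_names}
print("rewards/min:", {k: round(v, 2) for k, v in rates.items()})
print(
    "New normalized to Fam_Ave:",
    round(normalize_to_famave(rates["New"], rates["Fam"], rates["FamPrime"]), 2),
)

for ep in b.epoch_names:
    t0, t1 = b.epoch_bounds(ep)
    rew = b.reward_times[(b.reward_times >= t0) & (b.reward_times < t1)]
    dec = pre_reward_deceleration(b.forward_speed, rew, b.rate)
    print(f"pre-reward deceleration in {ep}: {dec:+.2f} cm/s^2")

bouts = detect_lick_bouts(b.lick, b.rate)
print(f"lick bouts: {len(bouts)} ({lick_rate(bouts, b.duration):.1f}/min), "
      f"correct fraction {correct_lick_fraction(bouts, b.reward_times):.2f}")
times, rewarded = endzone_entries(b)
print("unrewarded end-zone entries licked:",
      round(unrewarded_endzone_lick_fraction(bouts, times, rewarded), 2))

occ = occupancy_map(b.position, b.rate)
print("occupancy (s) per 20 cm bin:", np.round(occ, 0))
fails = trial_failure_location(b)
print(f"trial failures: {len(fails)}, median turn-around distance "
      f"{np.median(fails) if len(fails) else float('nan'):.0f} cm from destination")
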
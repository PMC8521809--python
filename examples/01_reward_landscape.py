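"""Evaluate the therapeutic-band reward for a few clinical situations.

Builds no data: evaluates the MAP and SAS band rewards, deviations, window
errors and the gated reward on hand-picked scenarios and prints them.
"""

from sedrl.reward import RewardConfig, breakdown_window, compute_reward

scenarios = [
    ("calm, normotensive, moderate doses", 3.5, 75.0, 8.0, 4.0),
    ("agitated, hypertensive", 6.0, 95.0, 15.0, 6.0),
    ("oversedated, hypotensive", 2.0, 55.0, 20.0, 8.0),
    ("in band on zero doses", 4.0, 80.0, 0.0, 0.0),
]

config = RewardConfig()
print(f"{'scenario':38s} {'r_SAS':>8s} {'r_MAP':>8s} {'error':>7s} {'reward':>8s}")
previous_error = None
for name, sas, map_mmHg, prop, fent in scenarios:
    bd = breakdown_window(sas, map_mmHg, prop, fent, config)
    reward = compute_reward(bd, error_prev=previous_error, config=config)
    print(f"{name:38s} {bd.r_sas:8.4f} {bd.r_map:8.4f} {bd.error_t:7.2f} {reward:8.4f}")
    previous_error = bd.error_t

print()
print("The band rewards peak between the target boundaries (SAS 3-4, MAP")
print("65-85 mmHg) and fall toward -1 outside; the reward for a window is")
print("r_SAS + r_MAP - 0.02*(propofol+fentanyl) and is gated to 0 unless the")
print("combined band error strictly improved on the previous hour.")
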
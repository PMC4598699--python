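"""Simulate a herd and emit the three milk-recording observation schemes.

Builds a small synthetic population with full AM/PM ground truth, then
degrades it into (a) mixed 50/50 composite samples, (b) alternate
single-milking records, and (c) a fully observed validation table.
"""

from ampmyield import (SimulationConfig, make_s_dataset, make_t_dataset,
                       make_validation_dataset, simulate_herds)

cfg = SimulationConfig(n_herds=5, cows_per_herd=20, test_days_per_cow=6,
                       seed=42)
truth = simulate_herds(cfg)

print(f"simulated {len(truth)} cow test days "
      f"({cfg.n_herds} herds x {cfg.cows_per_herd} cows x "
      f"{cfg.test_days_per_cow} visits)")
print(f"mean daily milk: {(truth.milk_am + truth.milk_pm).mean():.2f} kg "
      f"(AM {truth.milk_am.mean():.2f} / PM {truth.milk_pm.mean():.2f})")
print(f"mean fat content: AM {truth.content_am_fat.mean():.2f}, "
      f"PM {truth.content_pm_fat.mean():.2f} g/dL")
print("-> the AM milking follows the shorter overnight interval here, so it")
print("   carries less milk and, through dilution, slightly richer milk.\n")

s = make_s_dataset(truth)
t = make_t_dataset(truth)
v = make_validation_dataset(truth)
print(f"mixed 50/50 scheme:   {len(s)} rows, e.g. composite fat "
      f"{s.content_5050_fat.iloc[0]:.2f} g/dL (average of both milkings)")
print(f"alternate scheme:     {len(t)} rows, first visit all "
      f"'{t.session.iloc[0]}' samples, next visit the other milking")
print(f"validation scheme:    {len(v)} rows with both milkings observed; "
      f"daily fat yield of cow 0: {v.yield_daily_fat.iloc[0]:.0f} g")
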
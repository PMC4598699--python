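"""How much milking-interval variation do production traits explain?

Regresses the interval preceding the morning milking on five nested sets
of production covariates.  A large jump when the session milk yield
enters is the empirical basis for dropping the interval from prediction
equations: the session yield already carries most of its signal.
"""

from ampmyield import SimulationConfig, mi_nested_regressions, simulate_herds

truth = simulate_herds(SimulationConfig(n_herds=20, cows_per_herd=25,
                                        test_days_per_cow=8, seed=51))
rep = mi_nested_regressions(truth, session="am")

print(f"nested regressions of the AM milking interval (n={rep.n}):")
for label, r2, sig in zip(rep.labels, rep.r2_percent, rep.significant):
    mark = "*" if sig else " "
    print(f"  {label:<50s} R2 = {r2:6.2f}% {mark}")
print("(* added block significant at 0.05 by partial F-test)")
print()
print("daily milk alone explains almost nothing: the interval shifts milk")
print("between the two milkings without changing the day's total. The")
print("session milk yield captures that shift, so R2 jumps when it enters;")
print("fat content, lactation stage and parity add little on top.")
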
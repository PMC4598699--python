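"""Run the complete workflow and inspect the written artifacts.

Simulation -> outlier filter -> decomposition -> preset fits ->
validation report, correlation table, milking-interval report, manifest.
"""

from pathlib import Path

from ampmyield import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(
    seed=99,
    calibration=SimulationConfig(n_herds=12, cows_per_herd=20,
                                 test_days_per_cow=8, seed=99),
    traits=("milk", "fat", "sfa", "ufa"),
)
out = Path("scratch/example_run")
res = run_pipeline(cfg, out)

print(f"artifacts in {out}:")
for name in sorted(res["manifest"]["files"]):
    print(f"  {name}")
print(f"\nrecords: {res['manifest']['rows']}")

rep = res["report"].dropna(subset=["r_y_yhat"])
print("\nobserved-predicted correlations (%) per dataset:")
print(rep.pivot_table(index=["trait", "session"], columns="dataset",
                      values="r_y_yhat").round(1))
print("\nre-running with the same seed reproduces every file hash in")
print("manifest.json byte for byte.")
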
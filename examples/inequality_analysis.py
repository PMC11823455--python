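"""Population-weighted exposure inequality on a designed synthetic scene.

Runs the full chain (simulate -> filter -> oversample -> background ->
enhancement -> block-group aggregation -> population weighting) and compares
the recovered relative inequalities with the scene's designed values.
"""

from nh3ineq import RunConfig, SceneConfig, run_all

config = RunConfig(
    scene=SceneConfig(seed=7, hot_source_multiplier=1.0, calm_decay_multiplier=1.0),
    n_days=60,
    pixels_per_day=120,
    noise_cv=0.15,
    stratify=False,
    seed=7,
)
report = run_all(config)

print(f"pixels used: {report.n_pixels_used} of {report.n_pixels_simulated} simulated")
print(f"10th-percentile background: {report.background_value:.3g} molecules/cm^2\n")
print(f"{'group':>16} {'recovered %':>12} {'designed %':>11} {'abs (cm^-2)':>12}")
for _, row in report.inequality.iterrows():
    designed = report.designed_inequality[row["group"]]["relative_pct"]
    print(
        f"{row['group']:>16} {row['relative']:>11.1f} {designed:>11.1f} "
        f"{row['absolute']:>12.3g}"
    )
print(
    "\nmeaning: positive values say the group's population-weighted mean "
    "enhancement exceeds the reference group's; recovery within the standard "
    "mean errors shows the estimator resolves the designed spatial structure."
)
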
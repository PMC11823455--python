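"""Meteorological stratification: calm/windy and cool/hot contrasts.

Days are split at the median morning wind speed and air temperature; each
stratum is re-oversampled and enhanced against the all-days background. In
the generator's truth, hot days carry 1.5x source strengths and calm days a
1.5x decay length, so the stratified analysis has a known direction to
recover: enhancements reach farther on calm days and are higher near the
source on hot days.
"""

from nh3ineq import RunConfig, SceneConfig, run_all

report = run_all(RunConfig(scene=SceneConfig(seed=11), seed=11, stratify=True))

print(f"{'stratum':>8} {'extent km':>10} {'near-source mean':>18} {'pixels':>8}")
for name in ("calm", "windy", "cool", "hot"):
    s = report.strata[name]
    print(
        f"{name:>8} {s['extent_km']:>10.1f} {s['near_source_mean']:>18.3g} "
        f"{s['n_pixels']:>8}"
    )
print(
    "\nmeaning: the SNR=2 extent (shared all-days noise level) is larger in "
    "the calm stratum, and the near-source bin mean is larger in the hot "
    "stratum — the signatures of slower dilution and temperature-driven "
    "volatilization."
)
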
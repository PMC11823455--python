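"""Enhancement decay with distance to the nearest facility.

Profiles block-group mean enhancements against the haversine distance from
each block-group centre to the nearest swine facility, derives the SNR=2
spatial extent, and reports population-weighted distances per group.
"""

from nh3ineq import RunConfig, SceneConfig, run_all

report = run_all(RunConfig(scene=SceneConfig(seed=3), seed=3, stratify=False))
prof = report.profile

print(f"{'bin km':>10} {'mean enhancement':>18} {'sem':>10} {'n':>4}")
for _, row in prof.to_dataframe().iterrows():
    print(
        f"{row['bin_lo']:>4.0f}-{row['bin_hi']:<4.0f} "
        f"{row['mean']:>17.3g} {row['sem']:>10.2g} {row['n']:>4.0f}"
    )
print(f"\nfar-field (15-20 km) 2-sigma noise: {prof.noise_2sigma:.3g}")
print(f"SNR=2 spatial extent: {prof.extent_km:.0f} km")
print("population-weighted distance to nearest facility (km):")
for group, d in report.pw_distances_km.items():
    print(f"  {group:>16}: {d:.1f}")
print(
    "\nmeaning: enhancements decay roughly exponentially with distance and "
    "stay detectable (twice the far-field noise) many km downfield; groups "
    "living closer to facilities carry correspondingly higher exposure."
)
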
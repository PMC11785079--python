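"""Extension across the visual hierarchy: V1, V2 and V3 bandwidths.

Simulates a three-ROI cohort with increasing tuning bandwidth (2.2, 3.8 and
4.5 octaves), refits each map, and reports within-subject ROI differences of
the bandwidth parameter with bootstrap CIs.
"""

import tempfile
from pathlib import Path

from sfmaps import (
    NSD_V1_PARAMS,
    NSD_V2_PARAMS,
    NSD_V3_PARAMS,
    RunConfig,
    SimulationConfig,
    fwhm_octaves,
    run_replication,
    simulate_cohort,
)
from sfmaps.synthetic import write_cohort

config = SimulationConfig(
    n_vertices=300, n_subjects=4, seed=0,
    true_params={"V1": NSD_V1_PARAMS, "V2": NSD_V2_PARAMS, "V3": NSD_V3_PARAMS},
)
with tempfile.TemporaryDirectory() as tmp:
    data_dir = Path(tmp) / "cohort"
    write_cohort(simulate_cohort(config), data_dir)
    run = RunConfig(rois=("V1", "V2", "V3"), n_boot=2000, seed=0,
                    out_dir=str(Path(tmp) / "out"))
    result = run_replication(run, data_dir)

cohort = result["cohort"].set_index(["roi", "parameter"])
print("fitted bandwidth (octaves) and FWHM per map:")
for roi in ("V1", "V2", "V3"):
    sigma = cohort.loc[(roi, "sigma"), "mean"]
    print(f"  {roi}: sigma = {sigma:.2f} oct  ->  FWHM = "
          f"{fwhm_octaves(sigma):.1f} oct")

diffs = result["roi_differences"].set_index(["contrast", "parameter"])
print("\nwithin-subject bandwidth differences (68% CI):")
for contrast in ("V2-V1", "V3-V2", "V3-V1"):
    row = diffs.loc[(contrast, "sigma")]
    print(f"  {contrast}: {row['mean']:+.2f} oct "
          f"[{row['ci_low']:+.2f}, {row['ci_high']:+.2f}]")

# Bandwidth increases along the hierarchy while the preferred-period line
# changes little — the same qualitative pattern the model framework is
# designed to quantify.
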
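"""Project the region ensembles under a +2 degC pseudo-GCM warming scenario.

Each pseudo-GCM's anomaly is added to the observed baseline (delta
correction); the accepted members are projected onto baseline and corrected
fields; cells are classified to the most probable region; the normalized
transition entropy index (TI) maps where both regions remain probable; and
equal-area gains/losses are tested per occurrence-probability class.
"""

import numpy as np

from bioregionet import pipeline, synthetic
from bioregionet.grid import make_grid

grid = make_grid(lon_min=-40, lon_max=40)
scene = pipeline.build_scene(seed=11, grid=grid, n_south=20, n_subtrop=20,
                             n_widespread=3, n_local=2)
reg = pipeline.regionalize(scene, n_runs=50)
models = pipeline.fit_models(scene, reg)
scenario = synthetic.ScenarioSpec(n_gcms=10, mean_warming=2.0, gcm_sd=0.3, seed=11)
proj = pipeline.project_warming(scene, models, scenario)

for r in proj.present:
    print(f"region {r} ({reg.labels[r]}): {proj.present[r].n_runs} baseline runs, "
          f"{proj.future[r].n_runs} future runs (members x pseudo-GCMs)")

cols = ["region", "class", "delta_area_km2", "test", "p_value", "significant"]
print("\nequal-area change per occurrence-probability class (future - present):")
print(proj.area_change[cols].round(3).to_string(index=False))

_, lat = scene.grid.cell_centers()
for name, ti in (("present", proj.ti_present), ("future", proj.ti_future)):
    zone = np.nan_to_num(ti) >= 0.9
    print(f"{name}: transition zone (TI >= 0.9) {zone.sum()} cells, "
          f"mean latitude {lat[proj.cells][zone].mean():.1f}")
# A positive very-high-class change for the warm region with a matching loss
# for the cold one, and a poleward transition-zone shift, are the expected
# signatures of uniform warming across a fixed thermal barrier.
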
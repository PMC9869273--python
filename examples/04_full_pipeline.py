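"""End-to-end effect-size recovery: simulate, invert, contrast.

Runs the complete analysis on the default synthetic scene — four runs at
64 channels / 500 Hz with the reported alpha modulations injected — and
prints the recovered ROI-level percent changes next to the injected truth.
"""

import numpy as np

from olfactomap import (
    NoiseSpec,
    build_schedule,
    default_modulation_spec,
    default_sensor_array,
    default_source_atlas,
    simulate_empty_room,
    simulate_recording,
)
from olfactomap.contrast import OLFACTORY_MEAN
from olfactomap.pipeline import PipelineConfig, run_pipeline

seed = 1
cfg = PipelineConfig.desk_scale(seed=seed)
schedule = build_schedule(n_runs=cfg.n_runs)
atlas = default_source_atlas(points_per_roi=cfg.points_per_roi)
array = default_sensor_array(cfg.n_channels, cfg.helmet_radius)
modulation = default_modulation_spec(atlas.labels)

recording, _ = simulate_recording(
    schedule, atlas, modulation, array, sampling_rate=cfg.sampling_rate, seed=seed
)
empty_room = simulate_empty_room(
    array, NoiseSpec(), 300.0, cfg.sampling_rate,
    seed=np.random.SeedSequence(seed).spawn(3)[2],
)
result = run_pipeline(
    cfg, recording=recording, schedule=schedule, atlas=atlas, empty_room=empty_room
)
print("epoch counts:", result.epoch_counts)

injected = {
    "olfactory_L": 40.0, "olfactory_R": 40.0,
    "somatosensory_L": -30.0, "somatosensory_R": -30.0,
    "orbitofrontal_L": 27.5, "medial_frontal_L": 7.5, "precentral_L": 27.5,
}
print(f"\n{'ROI':18s} {'condition':14s} {'injected':>9s} {'recovered':>10s}  sig")
for roi, truth in injected.items():
    condition = OLFACTORY_MEAN if "olfactory" in roi or "somato" in roi else "PEA"
    change, significant = result.roi_map.entry(roi, "alpha", condition)
    print(f"{roi:18s} {condition:14s} {truth:+9.1f} {change:+10.1f}  {'*' if significant else ''}")
print(
    "\nRecovered alpha changes track the injected modulations; entries with "
    "|change| >= 20%\nare flagged significant (*), reproducing the "
    "fixed-threshold decision rule."
)
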
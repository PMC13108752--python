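"""Stereo triangulation of a synthetic session.

Generates one short gesture session, triangulates the two diagonal
cameras' 2D detections, and compares the reconstruction against the
ground-truth motion.
"""

import numpy as np

from gesturecap import SimulationConfig, build_cameras, generate_bundle
from gesturecap.analysis import triangulate_streams

config = SimulationConfig(
    n_participants=1, n_sequences=1, duration_s=15.0, seed=1
)
cameras, scene_to_world = build_cameras(config)
bundle = generate_bundle(config, participant=0, sequence=0)

tri = triangulate_streams(bundle.cam_streams, cameras)["stereo_a"]
truth_world = scene_to_world.apply(bundle.ground_truth.xyz)

ok = ~tri.missing
err = np.linalg.norm(tri.xyz[ok] - truth_world[ok], axis=1)
print(f"frames: {tri.n_frames}, keypoints reconstructed: {ok.sum()}")
print(f"mean |triangulated - truth|: {err.mean():.2f} mm")
print(f"95th percentile error:       {np.percentile(err, 95):.2f} mm")
print(f"fused confidence below 0.3:  {np.mean(tri.confidence[ok] < 0.3):.1%}")
# With 1 px detection noise at ~3 m the stereo reconstruction sits a few
# millimetres from the truth; low fused confidence marks torso occlusions.
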
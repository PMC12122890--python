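"""Two-means fixation detection and dynamic-AOI assignment.

Synthesises one trial of gaze over a moving actor (head mostly attended),
detects fixations with the sliding-window two-means algorithm, assigns them
to frame-by-frame Face/Hand/Arm rectangles and prints the per-AOI tally.
"""

from reachgrasp import gaze as gz
from reachgrasp.synth import GazeConfig, gen_gaze_stream, make_aoi_timeline

timeline = make_aoi_timeline(180)  # 1.5 s reach-to-grasp epoch at 120 fps
cfg = GazeConfig(seed=9, aoi_allocation={"default": (0.6, 0.2, 0.1, 0.1)})
samples, truth = gen_gaze_stream(timeline, cfg)

fixations = gz.detect_fixations(samples)
aois = gz.build_aois(timeline)
assigned = gz.assign_fixations(fixations, aois)

print(f"Planted fixations: {len(truth)}, detected: {len(fixations)}")
print(assigned.round(0).to_string(index=False))
print("\nPer-AOI summary:")
print(gz.aoi_summary(assigned).to_string(index=False))
print("\nEach fixation is credited to the AOI containing its centroid in the"
      "\nmajority of the video frames it spans; the face dominating the tally"
      "\nmirrors head-directed gaze during action observation.")
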
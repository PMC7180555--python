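"""Generate a synthetic multi-subject sensor world and run the feature pipeline.

Builds raw inertial-style streams for 2 subjects x 2 body locations x 4
activities, smooths and segments them into 2-second windows with 50%
overlap, and extracts the 8-statistic-per-channel feature battery.
"""

from comeal import SegmentationConfig, WorldConfig, features_from_stream, generate_world

cfg = WorldConfig(n_subjects=2, n_locations=2, seconds_per_activity=10.0, seed=42)
streams = generate_world(cfg)
print(f"world: {len(streams)} streams "
      f"({cfg.n_subjects} subjects x {cfg.n_locations} locations), "
      f"{streams[0].samples.shape[0]} samples each at {cfg.sampling_hz:.0f} Hz")

seg = SegmentationConfig(window_seconds=2.0, overlap_fraction=0.5, smoothing_width=5)
pool = features_from_stream(streams[0], seg)
print(f"stream {streams[0].subject_id}/{streams[0].location_id}: "
      f"{len(pool)} windows -> {pool.X.shape[1]}-dimensional feature vectors")
print(f"labels present: {pool.labels_present()}")
# Each window is one classification instance; the per-channel statistics
# (mean, sd, min, max, median, RMS, IQR, zero crossings) summarize 2 s of
# motion and are what the learner and all simulated experts consume.
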
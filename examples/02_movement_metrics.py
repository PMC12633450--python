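"""Quantify movement from landmark series, with and without hyperactivity.

Simulates 30 Hz face/pose landmark trajectories for a hyperactive and a
non-hyperactive child of the same age, applies the quality-control masks
(missing-data and jitter rules), affine face alignment and inter-shoulder
normalization, and prints the log mean framewise displacement per region.
"""

from phenokit import movement, synth

cfg = synth.LandmarkSimConfig(duration_s=20.0)

for hyper in (0, 1):
    rec = {"participant_id": f"demo_hyper{hyper}", "age": 9.0, "adhd_hyper": hyper}
    series, truth = synth.simulate_landmarks(rec, cfg, seed=7)
    qc = movement.qc_mask(series)
    dropped = int((series.present & ~qc).sum())
    summary = movement.movement_pipeline(series)
    print(f"\n== participant with adhd_hyper={hyper} "
          f"({series.n_frames} frames, {dropped} QC-masked landmark-frames) ==")
    for region, s in summary.items():
        print(f"  {region:6s} log mean displacement = {s.log_mean_displacement:7.3f} "
              f"({s.n_valid_frame_pairs} valid frame pairs)")

print("\nHigher (less negative) log displacement in the hyperactive child is the")
print("generative hyperactivity increment (+0.35 on the log scale) that the")
print("movement regression model is designed to detect.")
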
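"""Generate a small synthetic oocyte cohort and write it to disk.

Each movie is a directory of grayscale PNG frames showing a circular
oocyte with a darker zona-pellucida ring; the cytoplasm speckle of the
two outcome classes differs by the cohort's class_effect. A manifest CSV
records the label and reference (puncture-confirmed) frame per oocyte.
"""

from pathlib import Path

from oolemma import CohortConfig, generate_cohort, write_cohort

cfg = CohortConfig(
    n_ruptured=3, n_nonruptured=4,
    frame_width=320, frame_height=240,   # reduced raster for a quick demo
    frames_per_movie=31,
    class_effect=2.0,
    master_seed=42,
)
cohort = generate_cohort(cfg)
out = Path("scratch/demo_cohort")
manifest = write_cohort(cohort, out)

for seq in cohort:
    print(f"{seq.oocyte_id}: label={seq.label:12s} frames={seq.n_frames} "
          f"reference_frame={seq.reference_frame}")
print(f"\nmanifest: {manifest}")
print("Each row is one oocyte movie; the reference frame is the last one,")
print("so up to 5 frames can be sampled before it at a stride of 6 frames.")
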
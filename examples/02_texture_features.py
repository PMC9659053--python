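"""From a rendered frame to a 256-bin LBP histogram and its PCA reduction.

Shows the three feature stages on a tiny cohort: crop the oocyte-sized
region of interest, code every interior pixel's 8-neighbor sign pattern
into [0, 255], and reduce the histogram matrix with PCA.
"""

import numpy as np

from oolemma import CohortConfig, generate_cohort
from oolemma.evaluation import PipelineConfig, extract_features
from oolemma.lbp import frame_features, lbp_code_map
from oolemma.frame_io import crop_roi
from oolemma.pca import fit_pca, project

cfg = CohortConfig(n_ruptured=3, n_nonruptured=3, frame_width=320,
                   frame_height=240, frames_per_movie=31,
                   class_effect=2.0, master_seed=1)
cohort = generate_cohort(cfg)

pipe = PipelineConfig()
roi = pipe.resolve_roi(cohort[0].frames[0].shape)
crop = crop_roi(cohort[0].frames[0], roi)
codes = lbp_code_map(crop)
hist = frame_features(crop)
print(f"ROI {crop.shape} -> code map {codes.shape} -> histogram {hist.bins.shape}")
print(f"histogram sums to {hist.bins.sum():.6f} (density mode) over "
      f"{hist.n_pixels} coded pixels")

X, y, groups = extract_features(cohort, n_samples=3)
model = fit_pca(X)
Z = project(model, X, 2)
var_kept = model.eigenvalues[:2].sum() / model.eigenvalues.sum()
print(f"\nfeature matrix {X.shape} -> projected {Z.shape}; the first two "
      f"components keep {100 * var_kept:.1f}% of the variance")
for label, val in (("ruptured", 1), ("nonruptured", -1)):
    pc1 = Z[y == val, 0]
    print(f"  PC1 mean for {label:12s}: {pc1.mean():+.4f}")
print("A separation of the two PC1 means reflects the texture difference")
print("between the classes that the SVM will exploit.")
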
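"""Floral limb shape from 15-landmark photographs.

Generalized Procrustes analysis removes position, size and orientation;
PCA of the aligned coordinates gives the PC1/PC2 shape scores. The
synthetic specimens vary along a round-to-stellate deformation axis, which
PC1 should recover.
"""

import numpy as np

import floralevo as fe
from floralevo.simulate import sim_landmarks

configs, s_true = sim_landmarks(n_specimens=50, s_sd=0.05, noise_sd=0.01, seed=9)
aligned = fe.gpa_align(configs)
scores, var_frac = fe.shape_pca(aligned)

print(f"aligned {len(configs)} configurations in {aligned.n_iterations} GPA iterations")
print("variance fractions:", ", ".join(f"{v:.1%}" for v in var_frac[:4]))
r = np.corrcoef(scores["pc1"], s_true)[0, 1]
print(f"correlation of PC1 with the planted stellation coefficient: |r| = {abs(r):.3f}")
print("\nPC1 recovers the planted round-to-stellate axis despite every photo"
      "\nhaving its own random rotation, scale and position.")
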
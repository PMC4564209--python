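# coralign

Intensity-based 3-D brain MRI registration built around two similarity
metrics: the **correlation ratio** (CR) inside a multistart multiresolution
affine search, and the **local windowed cross-correlation** (CC) driving a
simplified symmetric deformable refinement.  The package is aimed at
researchers who want a transparent, fully testable CPU implementation of
these metrics — every fast path is paired with a brute-force oracle — plus
seeded phantoms with known ground truth for validating registration
accuracy (MAD, Jaccard overlap).

## The metrics

**Correlation ratio.**  For a reference image I and a transformed moving
image J_T = J ∘ T, with Ω the overlap region and Ω_i the voxels of
histogram bin i of I,

    η(J_T | I) = 1 − (1 / (N σ²)) Σ_i N_i σ_i²

where σ², m are the variance/mean of J_T over Ω and σ_i², m_i over Ω_i.
η ∈ [0, 1]: 1 for purely deterministic dependence, 0 for none.  The affine
search minimizes 1 − η over an 8/4/2/1 mm pyramid with 256/n bins at the
n-mm stage, computing the per-bin statistics through a stably-sorted voxel
index built once per stage.

**Local cross-correlation.**  At each voxel x, over a cubic (2r+1)³ window,

    CC(x) = C(x)² / (A(x) · B(x))

with A = Σ I² − 2 m_I Σ I + n m_I², B likewise for J, and
C = Σ IJ − m_I Σ J − m_J Σ I + n m_I m_J, all assembled from five running
window sums.  The symmetric refinement warps both images toward a midpoint
with two half-way displacement fields, greedily increasing the mean local
CC; accepted iterations never decrease it.

## Worked example

Recover a known rigid motion on a synthetic T1-like phantom:

```python
import numpy as np
from coralign import (PhantomSpec, make_phantom, apply_known_affine,
                      register_affine, SearchConfig)

spec = PhantomSpec(size=(64, 64, 64), noise_sd=2.1, seed=7)
volume, labels = make_phantom(spec)

true = np.zeros(12); true[6:9] = 1.0
true[:3] = (5.0, -3.0, 2.0)        # mm
true[5] = np.deg2rad(7.0)          # about z
moved, moved_labels, t_gt = apply_known_affine(volume, labels, true)

recovered, trace = register_affine(volume, moved, SearchConfig(dof=6))
p = recovered.to_params(center=volume.center_world)
print(f"translation (mm): {np.round(p[:3], 3)}")
print(f"rotation (deg):   {np.round(np.rad2deg(p[3:6]), 3)}")
print(f"final cost 1-eta: {trace[-1]['best_cost']:.6f}")
```

prints

```
translation (mm): [ 5. -3.  2.]
rotation (deg):   [0.   0.   7.01]
final cost 1-eta: 0.000482
```

i.e. the (5, −3, 2) mm translation is recovered to the line-search floor,
the 7° rotation to 0.01°, and the residual cost 1 − η ≈ 5e-4 reflects only
the simulated noise and resampling blur.

The same pipelines are scriptable from the shell:

```bash
coralign make-phantom --size 64 --seed 7 --out ref.nii.gz --labels lab.nii.gz
coralign register-affine --ref ref.nii.gz --mov mov.nii.gz --dof 12 --out xfm.txt
coralign register-syn --ref ref.nii.gz --mov mov.nii.gz --radius 3 --out warped.nii.gz
coralign evaluate --a ref.nii.gz --b warped.nii.gz        # prints: mad<TAB>value
```

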
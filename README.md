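# slicemapper

Automatic z-localization and atlas segmentation of single 2D brain slices
within a 3D template.

## The problem

Histological studies routinely produce *single* coronal sections — one
slice, or a handful at known spacing — rather than a full series that could
be reconstructed in 3D. To run region-based quantitative analysis on such a
slice, it must first be located along the rostro-caudal axis of a digital
atlas (which template slice does it correspond to?) and then segmented by
propagating the atlas labels onto it. Neuroanatomists do this by flipping
atlas pages and matching shapes by eye; `slicemapper` automates that
exploratory process.

## The method

Given an experimental slice $I_r$ and a template stack
$\{T_a \in B,\ a = 1..N\}$ with voxel-aligned label slices
$\{L_a \in A\}$, every candidate template slice is scored in three steps:

1. **Rigid registration** of $T_a$ (test) onto $I_r$ (reference) by block
   matching (exhaustive local search of high-variance blocks under Pearson
   cross-correlation, robust least-trimmed-squares transform fit,
   coarse-to-fine pyramid), initialised by automated foreground centering,
   then $S_{\mathrm{RIG}} = \mathrm{NMI}(I_r, T_a \circ \hat\theta^{RIG})$.
2. **Affine registration** initialised by the rigid result, then
   $S_{\mathrm{AFF}} = \mathrm{NMI}(I_r, T_a \circ \hat\theta^{RIG}
   \circ \hat\theta^{AFF})$.
3. **Weighted blend** $S_w = (1-w)\,S_{\mathrm{RIG}} + w\,S_{\mathrm{AFF}}$
   with the rigid-affine weighting $w \in [0, 1]$.

The estimated position is $z = \arg\max_a S_w$, and the segmentation is
$\hat L = L_z \circ \hat\theta^{RIG} \circ \hat\theta^{AFF}$ with
nearest-neighbour interpolation so label values are preserved. NMI
($\mathrm{(H(A)+H(B))/H(A,B)}$) is evaluated *after* registration as an
independent, multimodality-robust criterion; it never drives the
registration itself.

For an ordered set of $n$ slices at physical spacing $d_r$ (µm), the joint
mode converts $d_r$ into a template-space step through the relative scaling
factor $\gamma$ (the size ratio between the experimental brain and the
template along the cutting axis): $d_t = d_r/\gamma$, step
$= \mathrm{round}(d_t/e_t)$. Each slice $s$ is scored only over the window
$[u_s, v_s]$, $u_s = 1 + \mathrm{step}\,(s-1)$,
$v_s = N - \mathrm{step}\,(n-s)$; the offset-aligned $S_w$ curves are pooled
with per-slice contribution weights $\pi_s$, the pooled argmax gives the
first-slice position $z_m$, and $z_s = z_m + \mathrm{step}\,(s-1)$. Setting
$\pi_s = 0$ excludes an artifact-laden slice from the estimate while still
segmenting it. $\gamma$ can be given, or estimated by regressing independent
per-slice estimates against the slice index.

## Worked example

```python
import numpy as np
import slicemapper as sm

# a synthetic atlas (60 coronal slices, 96x96 px at 25 um, 100 um thickness)
atlas = sm.make_phantom_atlas(sm.PhantomSpec(N=60, seed=1))

# an "experimental" slice: template slice 30 seen through a 4 deg rotation,
# a (300, -150) um translation, a cross-modal intensity remap and 3% noise
theta = sm.Transform2D.rigid(4.0, (300.0, -150.0))
img, truth = sm.make_experimental_slice(atlas, 30, theta, noise_sigma=0.03,
                                        modality_map="gamma", rng=0)

res = sm.locate_single(img, atlas, w=0.5)
print(res.z)                            # 30
print(round(res.theta_rig.rotation_deg(), 2))   # 3.44
scores = sm.dice_by_region(res.mapped_labels, truth.region_masks[0])
print({k: round(v, 3) for k, v in scores.items()})
# {1: 0.961, 2: 0.957, 3: 0.977, 4: 0.867}
```

The slice is localized at exactly the generating position, the recovered
rigid rotation sits roughly half a degree from the true 4° (under 3%
noise), and the propagated segmentation overlaps the ground-truth region
masks with Dice ≈ 0.96 for the large regions (the 4th,
substantia-nigra-scale region is ~20 px and scores lower, as expected for
very small structures).

The same workflow is available from the shell:

```sh
slicemapper phantom --out phantom/ --n-slices 60
slicemapper segment-single --template phantom/template.nii.gz \
    --labels phantom/labels.nii.gz --image slice.png --pixel-size 25 \
    --out run/
```

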
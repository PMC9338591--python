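# camangle

Automated **alpha-angle** measurement for cam-type femoroacetabular
impingement (FAI), from a 3D binary segmentation mask of the proximal femur
to per-radial-slice alpha angles — together with the classical manual
(Nötzli) 2D construction as an independent oracle, synthetic femur phantoms
with analytic ground truth, and the observer-agreement statistics (ICC,
Bland–Altman, paired *t*) used to compare raters and methods.

## The problem and who this is for

Cam-type FAI is an asphericity of the femoral head–neck junction that
predisposes the hip to early osteoarthritis. Its standard imaging metric is
the **alpha angle**: on a radial image through the femoral neck axis, the
angle at the head centre *hc* between the neck axis (*hc → nc*, the neck's
narrowest point) and the ray to point *A*, the first point — walking from
the head apex toward the neck — where the bone contour leaves the best-fit
head circle. Manual measurement is slow and reader-dependent; this package
implements a fully automated 3D pipeline for researchers working on hip
morphometry who have bone segmentations (e.g. from MRI) and want
observer-independent alpha profiles around the whole head–neck
circumference, plus the statistical machinery to compare automated and
manual readings.

## The method

Given a binary mask (NIfTI, anisotropic spacing supported):

1. **Surface** — Gaussian-regularized iso-surface of the mask at occupancy
   0.5 (marching cubes), largest connected component, in millimetres.
2. **Initial landmarks** — head centre/radius from the maximum of the
   Euclidean distance transform (the largest inscribed sphere sits in the
   head); an approximate neck direction from the bone mass in a spherical
   shell around the head.
3. **Head/neck partition** — vertices labeled by position relative to the
   landmarks.
4. **Refined geometry** — RANSAC sphere fit (exact 4-point circumspheres,
   inlier threshold max(0.75 mm, 2 % r), least-squares polish) on the head
   vertices; the neck axis from the minimal-circumference planar
   cross-section of the neck surface ("narrowest point"), iterated to a
   fixed point.
5. **Radial slice group** — up to 120 half-planes bounded by the refined
   axis, evenly spaced in azimuth (`φ = 0` anterior, 90 superior, ...).
6. **Roundness map** — ray casting from the fitted centre gives
   ρ(φ, θ) = surface radius / head radius in spherical coordinates about
   the neck axis.
7. **Optimal cut** — alpha per azimuth is the polar angle of the cut θc(φ)
   minimizing an asymmetric misclassification cost (asphericity left on the
   head side weighs 10×, sphericity left on the neck side 1×) plus an L1
   smoothness penalty λ Σ|Δθc|, solved *exactly* by dynamic programming on
   the circular azimuth domain, then refined to the ρ = 1 crossing.

Because θ is measured from the head-to-neck axis direction, the cut angle
**is** the alpha angle. The same head-apex-toward-neck traversal convention
is used by `notzli_alpha_2d`, the manual 2D construction, so the two routes
are directly comparable; seven named clinical planes
(anterior … posterior, 30° apart) are read off the profile.

## Worked example

Generate a phantom femur (head R = 24 mm, neck r = 16 mm, i.e. baseline
alpha = arcsin(16/24) = 41.8°) carrying a cam lesion of severity 70° over
the anterior–superior azimuth span [0°, 60°], then measure it:

```bash
camangle synth --out phantom.nii.gz --truth truth.csv --cam
camangle measure --mask phantom.nii.gz --out result.json --csv alphas.csv \
                 --n-slices 72 --seed 17
```

which prints

```
wrote phantom.nii.gz (98556 voxels)
alpha profile over 72 slices; head radius 24.01 mm; wrote result.json
```

`result.json` holds the fitted sphere (radius 24.01 mm vs 24 mm truth), the
refined neck axis, the per-azimuth profile and the seven named planes:

```
anterior            41.4°   (azimuth   0°, cam span edge — tapers to baseline)
anterior-superior   70.6°   (azimuth  30°, cam centre; truth 70°)
superior-anterior   40.8°   (azimuth  60°, cam span edge)
superior            42.6°   ...
posterior           41.9°   (baseline truth 41.8°)
```

An abnormal (> ~55°) reading on any plane flags cam morphology; here the
cam is fully expressed only at the anterior-superior plane, exactly as
constructed. Compare two raters (or rater vs software) from a long-format
CSV with `camangle compare --table t.csv --raters obs1,software --out
agreement.json` to get the absolute-agreement ICC with 95 % CI and
reliability band, Bland–Altman bias/limits and a paired *t*-test.

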
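# sarcoreg

Histology ↔ MRI co-registration toolkit for soft-tissue sarcoma (STS)
specimens.

Validating quantitative MRI biomarkers of radiation-therapy response
requires knowing, voxel by voxel, which tumor tissue a histology slide came
from. For sarcomas — large, irregular specimens that cannot be fixed in a
3D-printed mold the way a prostate can — this package implements the full
chain that links a whole-mount microtomy section back to the in vivo
multiparametric MRI (mpMRI) via an agarose-embedded specimen and two
intermediate ex vivo scans:

1. **Rigid ex vivo → in vivo registration** from paired landmarks: the
   closed-form least-squares fit (Kabsch/Procrustes via SVD,
   reflection-corrected), `R, t = argmin Σᵢ ‖R sᵢ + t − fᵢ‖²` with
   `det R = +1` — rotation and translation only, no scaling.
2. **Cutting-angle derivation**: the sectioning-plane normal `n = Rᵀ e_z`
   is obtained by Rodrigues back-rotation
   (`v cosθ + (k×v) sinθ + k (k·v)(1−cosθ)`) and expressed as angle-plate
   *elevation* and *azimuth* (plus the residual in-plane angle), so that
   horizontal cuts of the re-oriented agarose block reproduce the in vivo
   axial planes. An optional in vivo angulation correction is composed in.
3. **Slice planning and matching** on a 4 mm measuring-grid localizer:
   slice centers every 4 mm, histology section *k* ↔ MRI slice *k*.
4. **Nonrigid section ↔ slice registration** with thin-plate splines
   (kernel `U(r) = r² log r`): exactly landmark-interpolating at λ = 0,
   affine-reproducing, with image warping by inverse-mapped resampling.
5. **Target registration error (TRE) protocol**: the 30–40 landmarks of a
   section/slice pair are randomly split 50/50, the TPS is fitted on one
   half, and the Euclidean distances (mm) of the warped held-out landmarks
   to their targets are pooled over 100 random splits; reported as
   median/IQR, compared across groups with Kruskal–Wallis and
   Bonferroni-corrected Wilcoxon rank-sum tests, and normalized as
   TRE per tumor volume (mm/mL).
6. **Habitat clustering**: the eight co-registered quantitative maps
   (ADC; IVIM D*, f, fD*; DCE Kᵗʳᵃⁿˢ, k_ep, v_e and the fourth DCE
   channel) are z-scored per channel ("equal weighting") and partitioned
   by k-means (k = 4, k-means++, best of 10 restarts) inside the tumor
   ROI; labels are mapped back onto the anatomy grid and regions compared
   per channel with one-way ANOVA plus Holm–Bonferroni pairwise t-tests.

Because no imaging data of this kind are publicly deposited, the
`phantom_generator` module synthesizes every input with known ground truth
— in vivo volume, rigidly re-oriented ex vivo copy, smoothly deformed 2D
sections with noisy paired landmarks, and 4-habitat parametric map stacks
with published per-region mean ± SD values — so that every stage is
testable by parameter recovery. See `docs/methods.md` for the models,
defaults and limitations.

## Worked example

```python
import numpy as np
import sarcoreg as sr

# synthesize a specimen: in vivo scan + randomly oriented "agarose block" copy
invivo, roi, landmarks = sr.make_invivo_phantom(seed=1)
rng = np.random.default_rng(2)
truth = sr.random_rigid(rng)
exvivo, ex_lm = sr.make_exvivo_phantom(invivo, landmarks, truth)

# rigid back-registration (ex vivo -> in vivo) from the paired landmarks
fit = sr.estimate_rigid(sr.pair_landmarks(ex_lm, landmarks))
print(f"rigid rms residual: {fit.rms_residual:.2e} mm")

# angle-plate settings that re-orient the block to the in vivo orientation
angles = sr.compute_plate_angles(fit.transform)
print(f"elevation {angles.elevation:.2f} deg, azimuth {angles.azimuth:.2f} deg")

# deformed "histology" section with noisy landmarks; accuracy protocol
mid = invivo.shape[2] // 2
section = sr.make_section_phantom(
    invivo.data[:, :, mid], float(invivo.spacing[0]),
    deformation_amplitude_mm=3.0, landmark_noise_sigma=0.5, seed=3)
result = sr.run_tre_protocol(section.pairs, n_iter=100, seed=4)
s = sr.summarize(result)
print(f"median TRE {s.median_mm:.2f} mm (IQR {s.iqr_mm:.2f} mm) "
      f"over {len(result.distances)} held-out landmarks")

# 4-habitat k-means clustering of the 8 parametric maps inside the ROI
stack, habitat_truth, _ = sr.make_map_stack(roi, seed=5)
clusters = sr.cluster_stack(stack, k=4, seed=5)
print("habitat sizes:", [int((clusters.labels.data == k).sum()) for k in (1, 2, 3, 4)])
```

Output:

```
rigid rms residual: 1.45e-14 mm
elevation 26.08 deg, azimuth 29.79 deg
median TRE 1.06 mm (IQR 0.92 mm) over 1800 held-out landmarks
habitat sizes: [2342, 1279, 1244, 1033]
```

The rigid fit recovers the synthetic block pose to machine precision; the
plate must be tilted 26.1° toward azimuth 29.8° to restore the in vivo
orientation. With 0.5 mm annotation noise on the histology landmarks the
protocol's pooled median TRE is ≈1 mm — the noise floor, since the
deformation itself is recovered exactly — and the clustering splits the
tumor ROI into four habitats, label 1 being the largest.

The same workflow is scriptable from the shell:

```sh
sarcoreg simulate --seed 7 --out-dir case/
sarcoreg register-rigid --moving-landmarks case/landmarks_exvivo.csv \
    --fixed-landmarks case/landmarks_invivo.csv --out-dir case/out
sarcoreg plan-angles --rigid-json case/out/rigid_transform.json --out-dir case/out
sarcoreg evaluate-tre --source-landmarks case/landmarks_histology.csv \
    --target-landmarks case/landmarks_mri_slice.csv --out-dir case/out
sarcoreg cluster --case-dir case/ --out-dir case/out
```

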
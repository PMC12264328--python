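# radstab — radiomic feature stability under segmentation uncertainty

Radiomic analyses extract quantitative intensity, shape and texture
features from a region of interest in a medical image. Two nuisance
factors routinely undermine them: **segmentation variability** (different
delineations of the same scan yield different feature values) and
**scan–rescan variability** (repeat acquisitions of the same subject, with
repositioning, yield different values). Stochastic deep-learning
segmentation — Monte-Carlo dropout or test-time augmentation — produces
*T* probabilistic delineations per scan, and therefore a voxelwise measure
of segmentation confidence. `radstab` implements the full analysis that
asks whether restricting feature extraction to *confidently* segmented
regions improves feature stability, and whether the surviving features
still discriminate patient groups.

The pipeline, for each stochastic-model profile:

1. **Uncertainty core.** From the replicate probabilities
   `p_it` it computes the mean prediction `p̄_i = (1/T) Σ_t p_it`
   (binarized into the *MP mask*) and the decomposition

   `U_i^(pred) = U_i^(aleat) + U_i^(epist) = (1/T) Σ_t p_it(1−p_it) + (1/T) Σ_t (p_it − p̄_i)²`,

   together with the soft Dice loss `L_DSC = 1 − 2Σp_i y_i / (Σp_i + Σy_i)`
   and its calibration-oriented "Dice Plus" variant
   `L_DSC++ = 1 − 2Σp_i y_i / (2Σp_i y_i + Σ[p_i(1−y_i)]^γ + Σ[(1−p_i)y_i]^γ)`.
   Segmentation quality is summarized by the 3-D Dice coefficient of the
   MP mask against ground truth and by the KL divergence between the
   predictive-uncertainty histograms of misclassified vs correctly
   classified voxels (higher = uncertainty sits where the model errs).
2. **Confidence-level masks.** `CL_th` = voxels labelled foreground by at
   least `th`% of the T replicates, for `th = 10, 20, …, 100`
   (so `CL_100 ⊆ CL_90 ⊆ … ⊆ CL_10`).
3. **Radiomics.** Intensity windowing to `[μ−0.5σ, μ+4σ]` rescaled to
   `[0, 255]`, resampling to a common voxel size (default
   1.458 × 1.458 × 5.5 mm, B-spline), z-score standardization, 64-bin
   discretization, and a pinned roster of **105 features** (18 first-order,
   14 3-D shape, 22 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM);
   first-order and texture features are computed slice by slice and
   averaged.
4. **Stability.** Per feature, reproducibility w.r.t. segmentation is
   `ICC_S` = two-way mixed, consistency, average-measure ICC(3,k) between
   ground-truth-mask and confidence-mask features; repeatability w.r.t.
   scan–rescan is `ICC_A` = two-way random, absolute-agreement ICC(2,k)
   across the repeat acquisitions. With cutoff 0.8 each feature falls into
   class 1 (both), 2 (only ICC_S), 3 (only ICC_A) or 4 (neither); the
   optimal confidence level `th_opt` minimizes the class-4 count (ties:
   maximize class 1). Wilcoxon signed-rank tests compare ICC distributions
   against the uncertainty-blind baselines.
5. **Discrimination.** Repeatable features (classes 1∪3 at `th_opt`) are
   filtered (zero variance; |r| > 0.8 with `shape_MeshVolume`), reduced to
   five by bootstrapped MRMR (500 resamples), and fed to a logistic
   regression evaluated with leave-one-patient-out cross-validation;
   ROC/AUC differences between methods are tested with DeLong's test for
   correlated ROC curves.

Because real repeat-scan MRI cohorts and trained stochastic networks are
not shippable, the package includes a first-class synthetic cohort
generator: two subject groups with injected volume and texture effects,
rigid 3-D repositioning between repeats, and replicate probability maps
built from the signed distance to the true boundary with smooth
per-replicate perturbations and a tunable error/uncertainty calibration.

## Worked example

```python
from radstab import (CohortParams, ModelProfile, RunConfig, run_pipeline)

cfg = RunConfig(
    cohort=CohortParams(n_per_group=5, n_repeats=5, grid_shape=(10, 48, 48), seed=1),
    profiles={
        "calibrated":    ModelProfile(band_width=3.0, replicate_jitter=1.8, calibration=1.0),
        "miscalibrated": ModelProfile(band_width=3.0, replicate_jitter=1.8, calibration=0.2),
    },
    T=20,
    seed=1,
)
report = run_pipeline(cfg, stage="classify")
print(report.accuracy.groupby("profile")[["dsc_3d", "kl_divergence"]].mean().round(3))
print(report.scans_by_th["calibrated"].th_opt)
```

prints

```
               dsc_3d  kl_divergence
profile
calibrated      0.995          2.273
miscalibrated   0.997          1.795
{'CKD': 60.0, 'HC': 60.0}
```

Both emulated models segment accurately (mean 3-D Dice ≈ 0.995), but the
well-calibrated profile separates wrong from right voxels much better
(KL 2.27 vs 1.80). For this cohort the optimal confidence level is 60%
in both groups; at that threshold 53 of the 105 features are repeatable
under scan–rescan variability (classes 1∪3), versus 51 from the
deterministic-analog mean-prediction masks. The downstream classifier
separates the two synthetic groups perfectly (AUC = 1.0) for every mask
source, as the injected volume and texture effects are strong.

The same run is available from the shell:

```sh
radstab all --config examples/demo.yaml --seed 1 --out runs/demo
```

which writes `accuracy.csv`, `features.csv`, per-profile ICC and
class-count tables, `th_opt.json`, `wilcoxon.csv`,
`classification.json` and a `manifest.json` of settings and outputs.

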
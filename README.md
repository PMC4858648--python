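# fmritex

Texture radiomics for telling true fMRI activation from false positives.

Individually analysed fMRI language maps always contain a mixture of
activation clusters in anatomically plausible language areas ("Expected",
E) and clusters that are non-essential or false positive ("Non-Expected",
NE) — both surviving the same statistical threshold. `fmritex` implements a
post-processing pipeline that discriminates the two classes from the
*texture* of the mean EPI volume inside each ROI, on the premise that truly
active cortex shows more heterogeneous signal than non-essential activation:

1. **Texture extraction** — per ROI, intensities are quantized into 8
   equal-width gray levels; 2-D gray-level co-occurrence matrices (GLCMs)
   are built at unit offset along Θ ∈ {0°, 45°, 90°, 135°}, accumulated
   over the ROI's axial slices and normalized; 20 Haralick/Soh/Clausi
   features (energy, contrast, correlation, sum/difference statistics,
   information measures of correlation, …) are computed per direction and
   averaged into a rotation-invariant vector.
2. **Labeling** — activation clusters are assigned E/NE from an anatomical
   cluster report via configurable region vocabularies, a 5-voxel minimum
   cluster size, and a higher-max-Z rule for clusters straddling both
   vocabularies; two fixed-coordinate control ROIs per subject anchor the
   NE class.
3. **Statistics** — pooled Student t-tests per feature (raw samples or
   printed summary statistics), Pearson feature correlations, and
   noncentral-t power curves.
4. **Modeling** — forward stepwise logistic regression of
   logit P(E) = β₀ + βᵀx with p-to-enter 0.05, p-to-remove 0.15, and an
   AIC guard against overfitting.
5. **Evaluation** — patient-grouped repeated holdout (12 of 15 subjects
   train, 3 test, 100 repeats): accuracy at threshold 0.5, ROC AUC, and
   the Youden-optimal sensitivity/specificity, averaged over repeats.

Because the original 15-volunteer scans are not public, a first-class
synthetic module generates (a) mean-EPI-like volumes whose ROI textures
differ by class and (b) labeled 116×20 feature tables whose per-class
marginals match the published descriptive statistics — so every stage is
testable end to end.

## Worked example

Group comparison of the four discriminating features from summary
statistics only (43 E vs 73 NE ROIs), `examples/03_univariate_stats.py`:

```
feature                    mean_E  mean_NE       p
sum variance                 101.5    124.5  0.001
autocorrelation               27.5     33.4  0.002
sum average                   10.4     11.4  0.003
sum of squares variance       27.9     33.4  0.004
```

All four are brightness/spread measures and all are higher in NE ROIs —
non-expected activation sits in *more homogeneous* tissue, expected
activation in more heterogeneous tissue. Grouped cross-validation of the
stepwise model on a feature table matched to those published marginals
(`examples/05_grouped_cv.py`):

```
accuracy                71.64%
auc                     77.30%
optimal_sensitivity     79.50%
optimal_specificity     75.02%
```

Accuracy is the success rate at probability threshold 0.5;
sensitivity/specificity are at the per-repeat Youden-optimal operating
point. Values are means over 100 subject-level splits, so no subject ever
contributes ROIs to both sides of a split. The remaining examples cover
texture extraction (`01`), cluster labeling (`02`), stepwise selection with
odds ratios (`04`), and the full simulated-cohort pipeline (`06`). A thin
CLI mirrors the stages (`fmritex simulate|extract|label|stats|fit|evaluate|all`).

## Layout

- `src/fmritex/` — `volumes` (NIfTI I/O, patches, control ROIs), `texture`
  (GLCMs + 20 features), `labeling`, `univariate`, `stepwise`,
  `evaluation`, `synthetic`, `pipeline`, `cli`.
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — model assumptions, parameter choices, numerical
  conventions and limitations.
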
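# Methods

## Problem and model

The pipeline classifies fMRI activation ROIs as Expected (E, anatomically
plausible language activation) or Non-Expected (NE, non-essential or false
positive) from the spatial texture of the mean EPI volume inside each ROI.
The working assumption is physiological: BOLD fluctuation between task and
control blocks leaves truly active cortex with more heterogeneous mean-EPI
signal, while non-essential activation and quiescent tissue are smoother.
Texture is quantified by gray-level co-occurrence statistics and the two
classes are separated by a logistic model built with forward stepwise
selection, evaluated by patient-grouped repeated holdout.

## Texture features

**Quantization.** Per ROI, the pooled intensity range over all in-ROI
voxels (across the ROI's axial slices) is split into `n_levels = 8`
equal-width bins; levels are 1-based and the top edge belongs to the last
bin. Using the per-ROI min–max rather than a volume-wide range makes the
features invariant to affine intensity shifts — desirable because EPI
units are arbitrary. A constant ROI maps to level 1 everywhere and carries
a degeneracy flag.

**GLCMs.** Co-occurrences are counted between in-ROI pixel pairs at unit
offset (in index space; no anisotropic-spacing correction for the
diagonals) along 0°/45°/90°/135°, counted symmetrically (each ordered pair
increments both (i,j) and (j,i)), which is the standard convention and
makes every GLCM symmetric. Counting is 2-D within axial slices. Raw counts
are accumulated over all slices of an ROI per direction and normalized
once; this weights each slice by its number of pairs instead of giving a
two-pixel sliver the same influence as a full slice. A direction with no
valid pair is flagged and excluded from the rotation-invariant average; if
all four directions are empty (single-pixel ROI) the ROI's features are
undefined and reported as an error.

**Features.** Twenty features per direction — the Haralick set (energy,
contrast, correlation, sum-of-squares variance, sum average/variance/
entropy, entropy, difference variance/entropy, two information measures of
correlation), the Soh set (autocorrelation, cluster prominence/shade,
dissimilarity, homogeneity, maximum probability) and the Clausi pair
(inverse difference normalized, inverse difference moment normalized) —
averaged over the four directions into a rotation-invariant vector.
Entropies use the natural log with 0·log 0 := 0; the base only rescales
entropy-family features, and all downstream use is relative. "Sum of
squares: variance" is treated as Haralick's variance Σ(i−μ)²p; the feature
count only comes out at 20 under that identification. Degenerate
conventions: a diagonal point mass implies deterministic equality of the
pair, so correlation := 1 when σ_x·σ_y = 0; imc1 := 0 when max(HX,HY) = 0;
the imc2 square root clamps small negative arguments to 0.

## Cluster labeling

Region vocabulary matching is case-insensitive exact match against
configurable E/NE lists seeded with the language-mapping defaults
(Brodmann 44/45/22, inferior/middle frontal and superior temporal gyri vs
cerebellum, sub-gyral white matter, insula, post-central, supramarginal and
superior frontal gyri). The published anatomical lists are illustrative,
not exhaustive, hence the vocabulary is a config value. Clusters under 5
voxels are filtered out before feature extraction. A cluster overlapping
both vocabularies takes the class of the entry with the highest max Z; an
exact cross-class Z tie is refused as unlabelable (flag for manual review)
rather than broken arbitrarily. Regions in neither vocabulary are logged
and ignored; a cluster with only unknown regions is unlabelable.

## Univariate statistics and power

Group comparisons are two-sided pooled-variance Student t-tests
(df = n_a + n_b − 2), computable from raw samples or from printed summary
statistics; both routes agree to machine precision and the summary route
reproduces the published p-values (0.001–0.004) for the four
discriminating features from their printed means/SDs at n = 43/73. No
multiple-testing correction is applied across the 20 features — p-values
are reported raw, matching how the univariate screen is used (descriptive,
not confirmatory). Power curves use the noncentral-t formulation
(statsmodels `TTestIndPower`) with equal group split; for the sum-variance
effect (d ≈ 0.65) power is ≈ 0.90 at a total n of 100 and > 0.99 from
n ≈ 170 — "effectively 100%" shortly beyond 100.

## Stepwise logistic model

E is coded 1. Candidates enter on their raw scale (standardization is an
option, off by default, matching the heterogeneous coefficient magnitudes
a raw-scale fit produces). Each round fits every remaining candidate on top
of the current model and admits the one with the smallest entry p-value
below `p_enter = 0.05`; ties break lexicographically so the step log is
fully deterministic. An addition whose post-fit AIC exceeds the current
model's AIC is rejected and selection stops — the AIC overfitting guard.
After each accepted entry, included terms with Wald p above
`p_remove = 0.15` are removed, worst first. `p_enter ≤ p_remove` is
enforced to prevent enter/remove cycling.

Entry tests are Wald by default with a likelihood-ratio variant available
(`test="lr"`); which flavour the original MATLAB/SPSS implementations used
is not recoverable from their outputs. Under (quasi-)perfect separation the
Wald statistic collapses toward zero (the Hauck–Donner effect), which would
make a perfectly separating feature *unselectable*; the entry test
therefore falls back to the likelihood-ratio test whenever the candidate
fit flags separation, and the removal phase is skipped on a separated
model, whose Wald p-values are meaningless. Separation itself is flagged
with a warning and the interrupted-fit coefficients are reported. A
singular Hessian on very small training sets is handled the same way; a
constant or collinear feature raises a singular-design error and is skipped
as a candidate.

## Grouped evaluation

Splits are drawn at the subject level: `n_train = 12` of 15 subjects train
and the remaining 3 test, redrawn independently per repeat
(`n_repeats = 100`, with replacement across repeats — with C(15,3) = 455
possible partitions, repeats may recur). The stepwise model is refit from
scratch on each training split. "Success rate" is accuracy at probability
threshold 0.5 (the threshold is otherwise unspecified, and 0.5 is the
natural choice for a probability output); the "optimal" operating point
maximizes Youden's J = sensitivity + specificity − 1 per repeat. AUC is the
trapezoidal area under the ROC sweep, which equals the normalized
Mann–Whitney U statistic (ties counted ½) — asserted against brute-force
pair counting in the tests. A repeat whose test subjects carry a single
class has no defined ROC; it is recorded as NaN and excluded from the AUC
mean with a warning. Aggregates are arithmetic means over repeats.

## Synthetic data

**Volumes.** Each of 15 subjects gets a 64×64×30 volume (matching a 64×64
acquisition matrix at 24 cm FOV, 4 mm slices → 3.75×3.75×4 mm spacing) of
smoothed background noise. 86 activation ROIs (9×9×3 boxes; 43 E and 43 NE
across subjects) are filled with Gaussian random fields realized by
in-plane convolution of white noise with a Gaussian kernel: E uses a short
correlation length (σ = 0.7 px) plus a positive-skew transform
g → g + skew·(g²−1)/2 emulating focal bright activation foci; NE uses a
longer correlation length (σ = 2.0 px), symmetric. Two fixed-coordinate
5×5×1 control ROIs per subject (identical coordinates across subjects)
keep background texture and are labelled NE, bringing the cohort to
116 ROIs, 43 E / 73 NE. Smoothness concentrates co-occurrences near the
GLCM diagonal (raising autocorrelation) and the E-class skew drags the
quantized-level mean down (lowering sum average), so NE exceeds E on both —
the direction observed in vivo. The generators are pure functions of their
config, seed included; setting both class textures (nearly) equal removes
the contrast and drives cross-validated AUC to chance for the activation
ROIs. The control ROIs differ from activation ROIs in size and texture by
construction, so a fully null cohort is only defined over activation ROIs.

**Feature tables.** Rows are drawn from per-class multivariate Gaussians
whose marginal means/SDs default to the published per-class descriptive
statistics, with a 0.99-equicorrelated block tying autocorrelation,
sum-of-squares variance, sum average and sum variance (their published
pairwise correlation). The correlation matrix is shrunk toward the
identity if ever infeasible. Joint Gaussianity is an explicit
simplification: real radiomic features are bounded, skewed and dependent
beyond this block, which bounds how closely the published cross-validated
AUC (≈ 0.80) can be emulated — matched tables typically cross-validate in
the 0.65–0.78 range depending on seed. The two normalized
inverse-difference features are published with SD "0.0" (one-decimal
rounding); literal zeros would create constant columns no real data set
has, so the defaults use small sub-rounding SDs (0.004 / 0.002). The
degenerate zero-SD path remains available through the config.

## Problem sizes in tests

The test suite validates the GLCM counter against exhaustive pair
enumeration on 200 random masked patches (≤ 12×12, 2–8 levels), rotation
invariance on 100 patches at 1e-9, stepwise behaviour over 200 replicates
of 116×20 tables, and the evaluation stack over 100 grouped splits; the
end-to-end simulated cohort uses the full 15-subject / 116-ROI default.
These sizes keep every property estimate's Monte-Carlo error well inside
the asserted margins.

## Known limitations

- 2-D slice-wise GLCMs only; 3-D (13/26-neighbour) co-occurrence, other
  radiomics families and IBSI certification are out of scope.
- Whether the original analysis pooled GLCM counts across slices or used a
  representative slice is unknowable from its outputs; count accumulation
  is this package's choice, made for statistical stability of small slices.
- The labeling vocabulary cannot be complete; unknown regions are surfaced
  rather than guessed.
- Synthetic data reproduce the published marginal structure and direction
  of class contrast, not the unpublished joint feature distribution; exact
  reproduction of the published cross-validated metrics is not expected,
  and passing tests demonstrate correctness of the machinery, not clinical
  performance on real scans.
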
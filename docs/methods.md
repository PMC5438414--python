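# Methods

`multiroi` implements a classification analysis of ROI-level brain
morphometry: two complementary feature families are extracted per subject,
the discriminating features are selected by a hybrid filter/wrapper cascade,
and a weighted multi-kernel RBF SVM is evaluated under a repeated,
class-stratified nested cross-validation protocol. The package operates
entirely on ROI summaries; image processing (segmentation, registration,
surface reconstruction) is upstream of its scope.

## Data model

A subject is six per-ROI vectors over the 78 cortical regions of the AAL
parcellation (gray-matter, white-matter and CSF volume in mm³, mean
cortical thickness and its within-ROI standard deviation in mm, cortical
surface area in mm²), two whole-head totals (intracranial volume, total
surface area), and a binary group label (`high`/`low`). The built-in atlas
lists the 78 regions in AAL index order (odd = left, even = right) with a
lobe assignment per region following the original AAL grouping (central,
frontal, temporal, parietal, occipital, limbic, insula; the temporal poles
are grouped with the limbic lobe and the fusiform gyrus with the occipital
lobe). All vectors and matrix axes in the package follow this one canonical
index order; flat files use columns named `<ABBREV>_<L|R>_<measure>`.

## Feature engineering

**Normalization** is within-subject: tissue volumes are divided by total
intracranial volume, surface area by total surface area, and each ROI's mean
thickness by the standard deviation (ddof = 1) of that subject's 78 ROI
thickness means — the only subject-level thickness scale available at ROI
granularity. The within-ROI thickness SD is left untouched, as it supplies
the similarity kernel's length scale.

**Similarity features.** For ROIs *i*, *j* with mean thicknesses *t(i)*,
*t(j)* and within-ROI SDs σᵢ, σⱼ,

    s(i, j) = exp( −(t(i) − t(j))² / (2 σ²) ),   σ² = σᵢ² + σⱼ²

so s = 1 for equal thicknesses, s → 0 as they diverge on the scale of the
combined within-ROI spread, and s is invariant under a common rescaling of
all four inputs. The 78×78 symmetric map's strict upper triangle, row-major
((1,2), (1,3), …, (77,78)), gives 3003 features per subject. Similarity is
computed from **raw** thickness means by default: its length scale is the
within-ROI vertex spread, which a rescaling of the means would no longer
match. A switch (`similarity_from_normalized`) computes it from normalized
means instead.

**Feature types.** Five single-measure ROI matrices (78 columns each), the
volume union (gmv‖wmv‖csfv, 234 columns), and the similarity matrix (3003
columns). Labels are +1 (high) / −1 (low).

## Selection cascade

Per feature type, on training rows only:

1. **Welch t-test** per feature; keep p < α (default 0.05). Welch rather
   than pooled variance because the generator (and plausibly real cohorts)
   produce group variance differences; zero-variance features are dropped
   with a warning. If nothing passes, the single smallest-p feature is
   carried forward (recorded in the stage trace).
2. **mRMR** greedy forward selection, up to `mrmr_k` = 50 features.
   Features are discretized into 3 bins at mean ± SD (Ding–Peng scheme);
   relevance is mutual information with the label, redundancy the mean MI
   with already-selected features; the score is relevance − redundancy
   (difference scheme, default) or relevance/redundancy (quotient).
3. **SVM-RFE** with a linear soft-margin SVM (C = 1): repeatedly rank by
   squared weight and drop the lowest `rfe_drop_fraction` (default 10%, at
   least one; 0 forces strict one-at-a-time elimination). The final subset
   size is chosen from a candidate grid by stratified 2-fold CV accuracy on
   the training rows, **averaged over 5 repeated splits** — a single 2-fold
   estimate is too noisy to order subset sizes — with exact ties resolved
   toward the smaller subset. The parsimony tie-break means that when a few
   features already saturate inner-CV accuracy the kept set is deliberately
   small; recovery of a planted signal should therefore be read from
   selection frequencies across outer runs, not from any single run.

All rankings break ties by canonical feature order (ROI index, then second
index), making every stage deterministic given its seed.

## Classifier and evaluation protocol

Per outer training half: the five ROI feature types are each selected and
concatenated into one ROI block; the similarity features form a second
block. Each block is z-scored with training statistics and mapped to an RBF
kernel K(a,b) = exp(−γ‖xₐ−x_b‖²). The two kernels are fused entrywise as

    K = β·K_roi + (1 − β)·K_sim,   β ∈ [0, 1]   (default β = 0.65),

which preserves positive semidefiniteness. γ for each block and the SVM's C
are tuned by stratified 2-fold CV on the training half; the γ grid is
{2⁻⁵, 2⁻³, …, 2⁵} scaled by 1/median pairwise squared training distance,
the C grid {2⁻³, 2⁻¹, …, 2⁵}; ties go to the smallest C, then the smallest
γ. Single-family classifiers are the same machinery with β pinned to 1
(ROI) or 0 (similarity) and the unused block skipped, so the β endpoints
reproduce the single-kernel runs run-for-run at a fixed seed.

The outer loop draws a class-stratified random half-split, evaluates
train→test, swaps the halves and evaluates again; with an odd class count
the extra subject alternates sides across repeats. `n_repeats` repeats give
2·n_repeats runs. Per run we record the confusion matrix and ACC, SEN, SPE,
AUC (trapezoidal over decision-value thresholds, positive class = high),
F-score, Youden's index, and balanced accuracy — the identities
ACC = (TP+TN)/N, BAC = (SEN+SPE)/2, Y = SEN+SPE−1 hold exactly per run —
plus the set of selected features (counted once per run). Paired
comparisons between feature types use a two-sided one-sample t-test on
per-run accuracy differences over shared splits; all-zero differences
return p = 1 with an undefined-t flag, constant nonzero differences ±∞ with
p = 0.

Selection and tuning never see held-out rows: the evaluation routine takes
index sets, errors on any overlap, and the selection interface receives the
training submatrix only.

## Synthetic cohorts

The generator emulates the *statistical* structure the analysis assumes,
not anatomy. Baselines are fixed module constants: volumes and areas are
log-normal around per-ROI medians (gray 8000 mm³, white 6000 mm³, CSF
2000 mm³, area 2500 mm², log-SD 0.25–0.30) modulated by a fixed per-ROI
profile; thickness is N(2.5, 0.25²) mm around a fixed per-ROI offset
profile; within-ROI thickness SD is |N(0.5, 0.1²)| mm; intracranial volume
N(1.5·10⁶, (10⁵)²) mm³, total area N(2·10⁵, (1.5·10⁴)²) mm². Default group
sizes are 34/34. All draws flow from one seed.

Two planted-effect mechanisms:

* **ROI effects** add `cohen_d` × the baseline SD of that (ROI, measure) to
  the high group.
* **Connection effects** shift the high group's thickness at ROIs *i* and
  *j* by ±shift/2 in opposite directions, oriented along each subject's own
  thickness gap so |t(i)−t(j)| widens by the full shift for every high
  subject. This moves s(i,j) strongly while the ROI-level mean shift is
  only the (small) asymmetry of the per-subject gap signs — the minimal
  mechanism that creates similarity-feature signal without a matching
  single-ROI signal. A fixed-direction shift was rejected because it can
  cancel against the baseline gap and it leaks a d ≈ 0.8 single-ROI effect.

What the generator does **not** model: realistic inter-ROI covariance,
hemispheric symmetry, site/scanner effects, or any correlation between
measures within an ROI. Passing recovery and calibration tests therefore
demonstrates that the pipeline detects and localizes the kinds of effects
it is built for — not that it would achieve any particular accuracy on real
cohorts.

## Numerical and design choices

* Degenerate inputs error loudly: zero thickness-SD pairs in the similarity
  map, zero subject-level thickness spread in normalization, single-class
  halves, overlapping train/test indices.
* The similarity map is symmetrized explicitly ((S+Sᵀ)/2) against
  floating-point asymmetry and its diagonal forced to 1.
* CSV round-trips use pandas with `float_precision="round_trip"` so
  write→read is exact.
* Problem sizes in the test suite and acceptance script (10–20 outer
  repeats, 5–10 generator seeds) were chosen as the smallest sizes at which
  the calibration bands and recovery medians are stable; the evaluation
  protocol itself is unchanged at larger sizes.

## Known limitations

* mRMR's 3-bin mutual-information ranking is a coarse statistic at n = 34
  per group; moderately informative features can rank below lucky noise in
  a single run. The cross-run frequency ranking is the reliable readout.
* The weight sweep evaluates every β with the full protocol on shared
  splits; picking the best β from that table is itself a selection step and
  slightly optimistic, as flagged for the corresponding experiment design.
* A fixed finite cohort can carry learnable chance structure; calibration
  statements are about means over splits of effect-free cohorts at n =
  34/34, and get looser at much smaller n.
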
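# multiroi

Multilevel ROI-feature classification of brain morphometry.

Structural-MRI group studies usually compare isolated regional measures —
gray-matter volume here, cortical thickness there. This package implements
an analysis that combines two complementary feature families extracted from
ROI-level morphometry over the 78 cortical regions of the AAL parcellation:

* **ROI features** — per-region gray-matter, white-matter and CSF volume,
  mean cortical thickness and surface area, normalized within subject
  (volumes by total intracranial volume, area by total surface area,
  thickness by the spread of the subject's regional thickness means);
* **similarity features** — a Gaussian similarity of mean cortical
  thickness between every pair of regions,

  `s(i,j) = exp(−(t(i)−t(j))² / (2σ²))`, `σ² = σᵢ² + σⱼ²`,

  where σᵢ is the within-region thickness SD — a within-subject proxy for
  structural connectivity, giving 78·77/2 = 3003 features per subject.

Per feature type a hybrid cascade — Welch t-test filter (p < 0.05), mRMR
re-ranking, SVM-RFE with inner-CV subset sizing — selects the
discriminating features on training data only. An RBF kernel is built per
family and fused as `β·K_roi + (1−β)·K_sim` (default β = 0.65); the
multi-kernel SVM is evaluated by repeated class-stratified half-splits with
train/test swapping (2·n_repeats runs), reporting ACC, SEN, SPE, AUC,
F-score, Youden's index, balanced accuracy, per-feature selection
frequencies, and a connection edge list for the selected region pairs.

Because ROI-level MRI cohorts of this kind are rarely shareable, the
package ships a first-class synthetic-cohort generator that plants
ROI-level effects (by Cohen's d) and coupled-thickness connection effects
(which move s(i,j) without a matching single-region signal), so the whole
pipeline is testable end to end. See `docs/methods.md` for the model,
parameter and design details.

## Worked example

```python
import multiroi as mr
from multiroi.classify import ExperimentConfig

spec = mr.EffectSpec(
    roi_effects=[(5, "gmv", 1.2), (12, "wmv", 1.2), (23, "thk", 1.2)],
    connection_effects=[(31, 47, 0.4), (2, 11, 0.4)],
    seed=4,
)
cohort, truth = mr.generate_cohort(spec)          # 34 + 34 subjects
features = mr.extract_features(cohort)            # 5 ROI types + similarity
result = mr.repeated_nested_cv(features, ExperimentConfig(seed=0), n_repeats=5)
for metric, (mean, sd) in result.summary().items():
    print(f"{metric:8s} {mean:.3f} ({sd:.3f})")
print(mr.frequency_table(result, "roi", top_n=3).to_string(index=False))
```

prints (10 outer runs on the cohort above):

```
acc      0.665 (0.064)
sen      0.671 (0.145)
spe      0.659 (0.099)
auc      0.730 (0.106)
f_score  0.661 (0.087)
youden   0.329 (0.128)
bac      0.665 (0.064)
 rank                             feature feature_id  frequency
    1 Orbitofrontal cortex (superior)_L_G      5:gmv         10
    2 Superior frontal gyrus (medial)_L_T     23:thk         10
    3              Rolandic operculum_R_A    18:area          5
```

Mean accuracy 0.665 is well above the ~0.5 chance level of an effect-free
cohort, and the two most frequently selected ROI features are planted ones —
left superior orbitofrontal gray-matter volume and left medial superior
frontal thickness, each selected in all 10 outer runs (the third row is a
noise feature at half that frequency, the usual long-tail of
small-sample selection). `mr.connection_edges(result)` lists the
selected region pairs with intra/inter-hemisphere flags, and
`mr.weight_sweep(...)` tabulates accuracy across the kernel weight β.
The scripts in `examples/` walk through each capability; a thin CLI
(`multiroi simulate|features|select|evaluate|sweep|run|atlas`) wraps the
same functions for shell use.

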
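"""Simulate a two-group morphometry cohort and round-trip it through CSV.

Builds a cohort of 34 high- and 34 low-self-esteem subjects with two planted
group differences: a gray-matter volume shift in the left orbitofrontal
cortex (Cohen's d = 1.2) and a coupled-thickness shift between the left
anterior cingulate and left middle occipital gyrus (0.4 mm).
"""

from pathlib import Path

import multiroi as mr

spec = mr.EffectSpec(
    roi_effects=[(5, "gmv", 1.2)],
    connection_effects=[(31, 47, 0.4)],
    seed=1,
)
cohort, truth = mr.generate_cohort(spec)
print(f"cohort: {len(cohort)} subjects, groups {cohort.group_counts()}")
print(f"planted ROI features:        {sorted(truth.true_roi_features)}")
print(f"planted similarity features: {sorted(truth.true_similarity_features)}")

atlas = mr.builtin_atlas()
roi, measure = next(iter(truth.true_roi_features))
print(f"  -> {atlas[roi].name} ({atlas[roi].hemisphere}), measure {measure}")

out = Path("scratch_cohort.csv")
mr.write_cohort(cohort, out)
back = mr.read_cohort(out)
print(f"wrote and re-read {out}: {len(back)} subjects, "
      f"first id {back.subject_ids[0]}")
out.unlink()
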
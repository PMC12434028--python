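"""Simulate a small MDD/HC cohort and run the group-level analysis.

MDD subjects carry the default injected effects (putamen matrix-like volume
-8.2%, striosome-like +15%, plus a severity-graded caudate shift).  The
analysis adjusts for study, scanner and age, corrects within pre-declared
test families, and runs voxelwise Freedman-Lane permutation inference with
TFCE.
"""
from striocomp import TrackingParams
from striocomp.phantom import CohortSpec
from striocomp.pipeline import cohort_analysis
from striocomp.reporting import summary_text

# a deliberately small demo cohort; the acceptance suite uses n = 20 + 20
spec = CohortSpec(n_mdd=6, n_hc=6, rng_seed=9)
res = cohort_analysis(spec, TrackingParams(samples_per_seed_voxel=150, rng_seed=3),
                      n_perm=200, rng_seed=11)

print(summary_text(res))
# Expect: putamen matrix-like volume lower and striosome-like volume higher
# in MDD, and a significant striosome-shift cluster in the rostral putamen
# where the generator injected the effect.
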
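"""Why video/frame selection must never see the test participants.

On a pure-noise cohort (no group difference at all), a pipeline that
selects discriminative frames using the FULL cohort — test participants
included — and builds signed distance-divergence features from them
reaches spuriously high holdout accuracy: the test participants helped
choose the frames on which they differ by chance.  The identical
pipeline restricted to training-only selection stays at the 0.5 chance
level.  This is the leak the evaluation protocol's provenance guard
forbids.
"""

from gazediff import SimConfig
from gazediff.classify import leakage_demonstration
from gazediff.io_gaze import frame_matrices_from_table
from gazediff.questionnaire import split_from_responses
from gazediff.simulate import generate_null_cohort

cohort = generate_null_cohort(SimConfig(seed=5))
matrices = frame_matrices_from_table(cohort.gaze)
_, groups = split_from_responses(cohort.responses())

proper = leakage_demonstration(matrices, groups, n_repetitions=6, seed=5, leaky=False)
leaky = leakage_demonstration(matrices, groups, n_repetitions=6, seed=5, leaky=True)

print(f"holdout accuracy, training-only selection: {proper:.3f}")
print(f"holdout accuracy, full-cohort selection:   {leaky:.3f}")
print("\nBoth pipelines saw pure noise; the gap is entirely selection leakage.")
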
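"""Generate a synthetic early/late mIBG study and recover its ground truth.

Builds a half-ellipsoid LV shell phantom with a known tracer concentration
per AHA segment at 15 min and 4 h post injection, runs the full segmental
chain (wall labelling -> top-decile sampling -> normalisation -> washout),
and compares against the generator's noise-free truth.
"""

import numpy as np

from mibgtools import (
    PhantomSpec,
    make_phantom,
    profile_chain,
    segmental_washout,
)

# heterogeneous uptake: the inferolateral wall (segment 5) washes out fastest
early = np.full(17, 800.0)
late = 0.73 * early
late[4] = 0.35 * early[4]  # segment 5: severe late washout

spec = PhantomSpec(
    segment_activity_early=tuple(early),
    segment_activity_late=tuple(late),
    noise="poisson",
    seed=42,
)
study = make_phantom(spec)

prof_early = profile_chain(study.volume_early)
prof_late = profile_chain(study.volume_late, labels=study.segment_labels)
washout = segmental_washout(prof_early, prof_late)

print("segment  late uptake %  truth %  washout pp  truth pp")
for s in range(17):
    print(
        f"{s + 1:>7}  {prof_late.values[s]:>12.1f}  {study.truth_uptake_late.values[s]:>7.1f}"
        f"  {washout.values[s]:>10.1f}  {study.truth_washout.values[s]:>8.1f}"
    )
print()
print(
    "Max |uptake - truth| = "
    f"{np.abs(prof_late.values - study.truth_uptake_late.values).max():.2f} pp"
)
# Late uptake is percent of the hottest segment; washout is the early-late
# difference of those percentages.  With Poisson noise at several hundred
# counts/voxel the chain recovers the generating kinetics to ~1-2 pp, and
# segment 5 stands out with the large washout that was built in.
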
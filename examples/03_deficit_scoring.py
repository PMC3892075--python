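"""Five-point defect scoring and the innervation-deficit call.

A late uptake profile is discretised per segment (0 = normal ... 4 = absent
uptake), summed into the SDS, and the adjacency rule decides whether the
abnormality qualifies as a regional innervation deficit: severely reduced
segments (score 3-4) count on their own, mildly reduced ones (1-2) only
next to another abnormal segment.
"""

import numpy as np

from mibgtools import classify_deficit, score_segments, summed_defect_score
from mibgtools.polar import SEGMENT_NAMES, SegmentProfile

# late profile with a contiguous inferolateral abnormality (segments 5, 11)
# and one isolated mildly-reduced segment (2)
values = np.full(17, 95.0)
values[0] = 100.0
values[4] = 25.0   # basal inferolateral: severely reduced
values[10] = 55.0  # mid inferolateral: mildly reduced, adjacent to segment 5
values[1] = 60.0   # basal anteroseptal: mildly reduced, isolated

profile = SegmentProfile(values=values, timepoint="late_4h")
pattern = score_segments(profile)
call = classify_deficit(pattern)

for s in np.nonzero(pattern.scores)[0] + 1:
    mark = "qualifies" if s in call.qualifying_segments else "does not qualify"
    print(f"segment {s:>2} ({SEGMENT_NAMES[s]:<20}) score {pattern.scores[s - 1]}  -> {mark}")
print(f"SDS = {summed_defect_score(pattern)}")
print(f"qualifying score sum = {call.qualifying_score_sum}")
print(f"innervation deficit: {call.is_deficit}")
# The isolated score-1 segment 2 is excluded by the adjacency rule, but the
# severe segment 5 (score 3) plus its abnormal neighbour 11 (score 1) put
# the qualifying sum at 4 >= 3: a regional deficit is called.
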
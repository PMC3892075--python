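"""Reproduce the published cohort statistics from the packaged table.

Uses the 16-patient table (relapse status, left atrial volumes) plus the
published group-level deficit counts to rebuild the 2x2 deficit-vs-relapse
table, its diagnostic metrics, and the LA-volume comparison.
"""

import json

from mibgtools import paired_rank_test, reproduce_published_results, unpaired_rank_test

out = reproduce_published_results()
print(json.dumps(out, indent=2))
# sensitivity 80 / specificity 45 / PPV 40 / NPV 83 (percent, rounded):
# a post-PVI innervation deficit is a sensitive but unspecific marker of
# AF relapse within 6 months.  Relapse occurred in 40 % of deficit-positive
# vs 16.7 % of deficit-negative patients, and relapsing patients tended
# toward larger left atria (132 +/- 36 ml vs 95 +/- 23 ml, n = 4 vs 11).

# The exact nonparametric machinery used for pre/post and between-group
# comparisons:
res = paired_rank_test([0, 0, 1, 0, 2, 0, 0, 3, 0, 1, 0, 0, 0, 2, 0, 0],
                       [2, 0, 3, 4, 2, 0, 5, 3, 0, 3, 2, 0, 6, 2, 3, 0])
print(f"\npaired SDS-style comparison: W+ = {res.statistic:.0f}, "
      f"p = {res.p_value:.4f} ({res.method}, {res.n_zero_dropped} zero diffs dropped)")
res2 = unpaired_rank_test([95, 72, 118, 76, 82], [132, 99, 122, 183])
print(f"unpaired volume comparison: U = {res2.statistic:.0f}, "
      f"p = {res2.p_value:.4f} ({res2.method})")
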
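"""Semiquantitative defect scoring and the innervation-deficit call.

Late normalised segmental uptake is discretised on the conventional
five-point defect scale (0 normal, 1 mildly reduced, 2 moderately reduced,
3 severely reduced, 4 absent uptake) and summed over all 17 segments into
the summed defect score (SDS).  An innervation deficit is called when the
scores of *qualifying* segments total at least 3, where a segment scoring
3-4 always qualifies and a segment scoring 1-2 qualifies only if at least
one adjacent segment is also abnormal (score >= 1).  Adjacency is over a
fixed graph on the 17-segment model: the three sector rings, the apex hub,
and inter-ring edges wherever sector angular spans overlap with nonzero
measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .polar import SEGMENT_NAMES, SegmentProfile

__all__ = [
    "DEFAULT_SCORE_THRESHOLDS",
    "ScorePattern",
    "DeficitCall",
    "SegmentAdjacency",
    "score_segments",
    "summed_defect_score",
    "adjacency_graph",
    "classify_deficit",
]

#: Descending uptake cutoffs (% of maximal segment) between scores 0|1, 1|2,
#: 2|3, 3|4.  Follows the conventional defect scale; configurable because the
#: underlying visual-read calibration is not standardised.
DEFAULT_SCORE_THRESHOLDS = (70.0, 50.0, 30.0, 10.0)

#: Minimum qualifying summed score for an innervation deficit.
SDS_DEFICIT_THRESHOLD = 3


@dataclass
class ScorePattern:
    """17 integer defect scores in {0, 1, 2, 3, 4}."""

    scores: np.ndarray
    thresholds: tuple[float, ...] = DEFAULT_SCORE_THRESHOLDS

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.shape != (17,):
            raise ValueError("a score pattern has exactly 17 segments")
        if not np.issubdtype(self.scores.dtype, np.integer):
            if not np.all(self.scores == np.rint(self.scores)):
                raise ValueError("scores must be integers")
            self.scores = self.scores.astype(int)
        if self.scores.min() < 0 or self.scores.max() > 4:
            raise ValueError("scores must lie in 0..4")


@dataclass
class DeficitCall:
    """SDS, the deficit verdict, and which segments qualified toward it."""

    sds: int
    is_deficit: bool
    qualifying_segments: frozenset[int]
    qualifying_score_sum: int
    mode: str = "qualifying"


@dataclass(frozen=True)
class SegmentAdjacency:
    """Symmetric adjacency over segment ids 1..17."""

    edges: frozenset[frozenset[int]]
    _neighbors: dict = field(default_factory=dict, compare=False, repr=False)

    def neighbors(self, s: int) -> frozenset[int]:
        if not self._neighbors:
            nb: dict[int, set[int]] = {i: set() for i in range(1, 18)}
            for e in self.edges:
                a, b = tuple(e)
                nb[a].add(b)
                nb[b].add(a)
            self._neighbors.update({k: frozenset(v) for k, v in nb.items()})
        return self._neighbors[s]


def _ring_edges(ids: list[int]) -> list[tuple[int, int]]:
    return [(ids[i], ids[(i + 1) % len(ids)]) for i in range(len(ids))]


def adjacency_graph() -> SegmentAdjacency:
    """The fixed 17-segment adjacency graph.

    Rings: basal 1-6, mid 7-12, apical 13-16 (each cyclic); basal-mid spokes
    pair equal sectors (1-7 ... 6-12); mid-apical edges join sectors whose
    60-degree and 90-degree angular spans overlap with nonzero measure
    (touching at a single boundary point does not count); the apex (17)
    neighbours all four apical segments.
    """
    edges: list[tuple[int, int]] = []
    edges += _ring_edges([1, 2, 3, 4, 5, 6])
    edges += _ring_edges([7, 8, 9, 10, 11, 12])
    edges += _ring_edges([13, 14, 15, 16])
    edges += [(s, s + 6) for s in range(1, 7)]
    edges += [
        (13, 7), (13, 8), (13, 12),
        (14, 8), (14, 9),
        (15, 9), (15, 10), (15, 11),
        (16, 11), (16, 12),
    ]
    edges += [(17, s) for s in (13, 14, 15, 16)]
    return SegmentAdjacency(edges=frozenset(frozenset(e) for e in edges))


def score_segments(
    late: SegmentProfile,
    thresholds: tuple[float, ...] = DEFAULT_SCORE_THRESHOLDS,
) -> ScorePattern:
    """Discretise a late normalised uptake profile on the five-point scale.

    With the default cutoffs: score 0 for uptake >= 70 % of the hottest
    segment, 1 for 50-70, 2 for 30-50, 3 for 10-30, 4 below 10.
    """
    thr = tuple(float(x) for x in thresholds)
    if (
        len(thr) != 4
        or any(hi <= lo for hi, lo in zip(thr, thr[1:]))
        or not all(0.0 < x < 100.0 for x in thr)
    ):
        raise ValueError("thresholds must be 4 strictly descending values in (0, 100)")
    scores = np.digitize(late.values, sorted(thr), right=False)
    return ScorePattern(scores=(4 - scores).astype(int), thresholds=thr)


def summed_defect_score(pattern: ScorePattern) -> int:
    """Sum of all 17 segmental defect scores (range 0..68)."""
    return int(pattern.scores.sum())


def classify_deficit(
    pattern: ScorePattern,
    graph: SegmentAdjacency | None = None,
    mode: str = "qualifying",
) -> DeficitCall:
    """Apply the SDS >= 3 deficit rule with the adjacency condition.

    ``mode='qualifying'`` (default): a segment's score counts toward the
    deficit threshold when the score is >= 3 (no adjacency required) or when
    the score is 1-2 and at least one neighbour is abnormal (score >= 1); a
    deficit is called when the qualifying scores sum to >= 3.  The reported
    ``sds`` is always the plain sum over all segments.

    ``mode='global'`` (sensitivity analysis): deficit iff the plain SDS is
    >= 3 *and* either some segment scores >= 3 or some two abnormal segments
    are adjacent.
    """
    if graph is None:
        graph = adjacency_graph()
    scores = pattern.scores
    sds = int(scores.sum())
    abnormal = {s for s in range(1, 18) if scores[s - 1] >= 1}
    qualifying = set()
    for s in range(1, 18):
        sc = scores[s - 1]
        if sc >= 3:
            qualifying.add(s)
        elif sc >= 1 and graph.neighbors(s) & abnormal:
            qualifying.add(s)
    qsum = int(sum(scores[s - 1] for s in qualifying))
    if mode == "qualifying":
        is_deficit = qsum >= SDS_DEFICIT_THRESHOLD
    elif mode == "global":
        has_severe = any(scores[s - 1] >= 3 for s in range(1, 18))
        has_adjacent_pair = any(
            graph.neighbors(s) & (abnormal - {s}) for s in abnormal
        )
        is_deficit = sds >= SDS_DEFICIT_THRESHOLD and (has_severe or has_adjacent_pair)
    else:
        raise ValueError("mode must be 'qualifying' or 'global'")
    return DeficitCall(
        sds=sds,
        is_deficit=bool(is_deficit),
        qualifying_segments=frozenset(qualifying),
        qualifying_score_sum=qsum,
        mode=mode,
    )
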
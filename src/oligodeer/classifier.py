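"""Oligomeric-state assignment by matching DEER peaks to predicted chords.

Each candidate oligomer (monomer, trimer, pentamer, hexamer, ...) predicts
a set of inter-protomer label distances; the observed peak positions are
matched to the in-window predictions by an exact minimum-cost one-to-one
assignment, with a flat penalty per unmatched peak or unmatched in-window
prediction. The candidate with the lowest total cost wins; ties go to the
smaller oligomer (parsimony).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .oligomer_geometry import DistanceClassSet, build_ideal_ring, distance_classes

__all__ = [
    "CandidateModel",
    "MatchResult",
    "ClassificationReport",
    "ideal_ring_candidate",
    "default_candidates",
    "match_cost",
    "classify",
]

#: label-site ring radii (Å) whose ideal chords reproduce the distance sets
#: predicted for a G67 label from the BR trimer, KR2 pentamer and BPR
#: hexamer templates (~37; ~18 and ~29; ~16, ~28 and ~31 Å).
DEFAULT_RING_RADII = {"monomer": 0.0, "trimer": 21.36, "pentamer": 15.31, "hexamer": 16.0}


@dataclass
class CandidateModel:
    label: str
    n: int
    predicted: DistanceClassSet
    source: str = "ideal ring"

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.predicted.distances):
            raise ValueError("predicted distances must be positive")
        if len(self.predicted) > self.n // 2:
            raise ValueError("more distance classes than floor(n/2)")


@dataclass
class MatchResult:
    cost: float
    matched: list[tuple[float, float]]  # (observed, predicted) pairs
    unmatched_observed: list[float]
    unmatched_predicted: list[float]


@dataclass
class ClassificationReport:
    ranking: list[tuple[CandidateModel, MatchResult]]
    window: tuple[float, float]

    @property
    def winner(self) -> CandidateModel:
        return self.ranking[0][0]


def ideal_ring_candidate(label: str, n: int, radius: float) -> CandidateModel:
    """Candidate from an ideal Cn ring of the given label radius."""
    if n == 1:
        return CandidateModel(label, 1, DistanceClassSet([]))
    ring = build_ideal_ring(n, radius)
    return CandidateModel(label, n, distance_classes(ring))


def default_candidates() -> list[CandidateModel]:
    """Monomer / trimer / pentamer / hexamer candidates at the default radii."""
    ns = {"monomer": 1, "trimer": 3, "pentamer": 5, "hexamer": 6}
    return [
        ideal_ring_candidate(name, ns[name], radius or 1.0)
        for name, radius in DEFAULT_RING_RADII.items()
    ]


def match_cost(
    observed: list[float],
    predicted: DistanceClassSet | list[float],
    window: tuple[float, float] = (15.0, 60.0),
    unmatched_penalty: float = 10.0,
) -> MatchResult:
    """Exact minimum-cost assignment of observed peaks to predicted classes.

    Predictions outside the detection window are dropped before matching
    (the experiment could not have seen them). The assignment minimizes the
    summed |d_obs - d_pred| over matched pairs plus ``unmatched_penalty``
    per unmatched observed peak or unmatched in-window prediction; solved
    exactly via the rectangular linear sum assignment problem on a matrix
    padded with the penalty.
    """
    if unmatched_penalty <= 0:
        raise ValueError("unmatched_penalty must be positive")
    obs = sorted(float(o) for o in observed)
    preds = predicted.distances if isinstance(predicted, DistanceClassSet) else list(predicted)
    preds = sorted(float(p) for p in preds if window[0] <= p <= window[1])
    n_o, n_p = len(obs), len(preds)
    if n_o == 0 and n_p == 0:
        return MatchResult(0.0, [], [], [])
    # square matrix: real pairs in the top-left block, penalty rows/columns
    # for "stay unmatched"; dummy-dummy cells cost 0
    size = n_o + n_p
    cost = np.zeros((size, size))
    for i, o in enumerate(obs):
        for j, p in enumerate(preds):
            cost[i, j] = abs(o - p)
    cost[:n_o, n_p:] = unmatched_penalty
    cost[n_o:, :n_p] = unmatched_penalty
    rows, cols = linear_sum_assignment(cost)
    matched, un_obs, un_pred = [], [], []
    matched_pred = set()
    for i, j in zip(rows, cols):
        if i < n_o and j < n_p:
            matched.append((obs[i], preds[j]))
            matched_pred.add(j)
        elif i < n_o:
            un_obs.append(obs[i])
    un_pred = [p for j, p in enumerate(preds) if j not in matched_pred]
    return MatchResult(float(cost[rows, cols].sum()), matched, un_obs, un_pred)


def classify(
    observed: list[float],
    candidates: list[CandidateModel] | None = None,
    window: tuple[float, float] = (15.0, 60.0),
    unmatched_penalty: float = 10.0,
) -> ClassificationReport:
    """Rank candidate oligomers by match cost against the observed peaks.

    Observed peaks outside the detection window are discarded before
    matching: outside it the inversion is unreliable (short distances are
    broadened, long ones exceed what the trace length constrains), and a
    peak there is uninformative about every candidate alike.
    """
    if candidates is None:
        candidates = default_candidates()
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate models")
    observed = [o for o in observed if window[0] <= o <= window[1]]
    scored = [
        (c, match_cost(observed, c.predicted, window, unmatched_penalty))
        for c in candidates
    ]
    scored.sort(key=lambda cm: (cm[1].cost, cm[0].n))
    return ClassificationReport(scored, window)
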
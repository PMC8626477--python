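"""Inter-subunit anchor distances, proximity grouping and group comparison.

Each outer subunit is assigned the distance to its closest interior
partner (anchor-atom to anchor-atom). Distances are then binned into a
proximal group (55–70 Å by default), a distal group (> 75 Å), or left
unassigned in the gap the binning deliberately leaves open. Enclosure
probabilities of the two groups are compared with a two-sided Mann–Whitney
rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._tables import ATOMIC_MASSES
from .model import AtomModel

__all__ = [
    "DistanceAssignment",
    "GroupBounds",
    "GroupComparison",
    "center_of_mass",
    "nearest_partner_distances",
    "classify_groups",
    "compare_group_probabilities",
]

GROUP1 = "group1"
GROUP2 = "group2"
UNASSIGNED = "unassigned"


@dataclass
class DistanceAssignment:
    subunit_id: str
    anchor: np.ndarray
    nearest_partner: str
    distance: float
    group: str = UNASSIGNED


@dataclass
class GroupBounds:
    """Proximal interval [lo, hi] and the open distal threshold (Å)."""

    group1_lo: float = 55.0
    group1_hi: float = 70.0
    group2_threshold: float = 75.0

    def __post_init__(self) -> None:
        if not self.group1_lo < self.group1_hi <= self.group2_threshold:
            raise ValueError("need lo < hi <= distal threshold")


@dataclass
class GroupComparison:
    summaries: pd.DataFrame  # index group, columns n/median/q1/q3
    u_statistic: Optional[float]
    p_value: Optional[float]


def center_of_mass(model: AtomModel, weighting: str = "uniform") -> np.ndarray:
    """Weighted mean position; ``weighting`` is 'uniform' or 'atomic-mass'."""
    if len(model) == 0:
        raise ValueError("center of mass of an empty model")
    if weighting == "uniform":
        w = np.ones(len(model))
    elif weighting == "atomic-mass":
        try:
            w = np.array([ATOMIC_MASSES[str(e).upper()] for e in model.element])
        except KeyError as exc:
            raise ValueError(f"element {exc} not in the mass table") from exc
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return (model.coord * w[:, None]).sum(axis=0) / w.sum()


def nearest_partner_distances(
    query_anchors: Mapping[str, np.ndarray],
    partner_anchors: Mapping[str, np.ndarray],
) -> list[DistanceAssignment]:
    """Closest partner for every query anchor (ties → smallest partner id)."""
    if not query_anchors or not partner_anchors:
        raise ValueError("both anchor sets must be non-empty")
    pids = sorted(partner_anchors)  # lexicographic tie-break by construction
    P = np.array([partner_anchors[p] for p in pids], dtype=float)
    out = []
    for qid, q in query_anchors.items():
        q = np.asarray(q, dtype=float)
        d = np.linalg.norm(P - q, axis=1)
        best = int(np.argmin(d))  # argmin returns the first = smallest id
        out.append(DistanceAssignment(subunit_id=qid, anchor=q,
                                      nearest_partner=pids[best],
                                      distance=float(d[best])))
    return out


def classify_groups(assignments: Sequence[DistanceAssignment],
                    bounds: GroupBounds = GroupBounds()
                    ) -> list[DistanceAssignment]:
    """Label assignments in place; distances in the (hi, threshold] gap stay
    unassigned (the binning leaves that interval open on purpose)."""
    for a in assignments:
        if bounds.group1_lo <= a.distance <= bounds.group1_hi:
            a.group = GROUP1
        elif a.distance > bounds.group2_threshold:
            a.group = GROUP2
        else:
            a.group = UNASSIGNED
    return list(assignments)


def compare_group_probabilities(
    p_by_subunit: Mapping[str, float],
    labels: Mapping[str, str],
) -> GroupComparison:
    """Median/quartile summaries per group plus a two-sided Mann–Whitney U.

    The test (normal approximation with tie correction) needs ≥ 3 members
    per group; summaries only need ≥ 1. Unassigned subunits are summarized
    but excluded from the test.
    """
    groups: dict[str, list[float]] = {}
    for sid, p in p_by_subunit.items():
        groups.setdefault(labels.get(sid, UNASSIGNED), []).append(float(p))
    if not groups.get(GROUP1) or not groups.get(GROUP2):
        raise ValueError("both group1 and group2 need at least one member")
    rows = {}
    for g, vals in sorted(groups.items()):
        v = np.asarray(vals)
        rows[g] = dict(n=len(v), median=float(np.median(v)),
                       q1=float(np.percentile(v, 25)),
                       q3=float(np.percentile(v, 75)))
    summaries = pd.DataFrame(rows).T
    u = pv = None
    g1, g2 = groups[GROUP1], groups[GROUP2]
    if len(g1) >= 3 and len(g2) >= 3:
        pooled = np.concatenate([g1, g2])
        if np.ptp(pooled) == 0:  # all tied: no evidence of any difference
            u, pv = len(g1) * len(g2) / 2.0, 1.0
        else:
            res = stats.mannwhitneyu(g1, g2, alternative="two-sided",
                                     method="asymptotic")
            u, pv = float(res.statistic), float(res.pvalue)
    return GroupComparison(summaries=summaries, u_statistic=u, p_value=pv)
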
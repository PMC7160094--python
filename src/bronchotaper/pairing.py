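"""Match airway branches to accompanying artery branches.

Each candidate airway-artery pair gets a cost combining proximity
(mean closest-point centerline distance, mm), orientation (unsigned
angle between principal directions, radians) and size similarity
(relative difference between mean artery diameter and mean airway outer
diameter).  A one-to-one assignment minimizing total cost over
candidates under the acceptance threshold is found with the Hungarian
algorithm; ties are broken deterministically by lexicographic branch id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .biomarkers import branch_mean_diameter
from .tree_model import Branch, Tree

__all__ = ["AAPair", "pair_trees", "DEFAULT_WEIGHTS", "DEFAULT_MAX_COST"]

logger = logging.getLogger(__name__)

DEFAULT_WEIGHTS = (1.0, 1.0, 2.0)  # (w_dist, w_angle, w_size)
DEFAULT_MAX_COST = 6.0

_INF = 1e12


@dataclass(frozen=True)
class AAPair:
    """A matched airway/artery branch pair and its cost components."""

    airway_branch_id: str
    artery_branch_id: str
    cost: float
    mean_centerline_distance: float
    orientation_angle: float  # degrees
    diameter_similarity: float


def _pair_metrics(airway: Branch, artery: Branch,
                  artery_kd: cKDTree,
                  airway_kd: cKDTree | None = None) -> tuple[float, float, float]:
    # symmetrized mean closest-point distance between the centerlines
    d_fwd = float(np.mean(artery_kd.query(airway.points)[0]))
    if airway_kd is None:
        airway_kd = cKDTree(airway.points)
    d_rev = float(np.mean(airway_kd.query(artery.points)[0]))
    dist = 0.5 * (d_fwd + d_rev)
    cosang = abs(float(np.dot(airway.direction(), artery.direction())))
    angle = float(np.arccos(np.clip(cosang, -1.0, 1.0)))
    d_aw = branch_mean_diameter(airway, "outer")
    d_art = branch_mean_diameter(artery, "outer")
    if not (d_aw > 0) or not np.isfinite(d_art):
        size = np.nan
    else:
        size = abs(d_art - d_aw) / d_aw
    return dist, angle, size


def pair_trees(airway: Tree, artery: Tree,
               weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
               max_cost: float = DEFAULT_MAX_COST) -> list[AAPair]:
    """Optimal one-to-one airway-artery branch matching.

    Candidates with cost above ``max_cost`` (or with an undefined
    component) are excluded; an empty candidate set yields an empty
    list.  The count of unpaired airway branches is logged as a
    pipeline health metric.
    """
    w_dist, w_angle, w_size = weights
    aw_ids = sorted(airway.branches)
    art_ids = sorted(artery.branches)
    aw_branches = [airway.branches[i] for i in aw_ids]
    art_branches = [artery.branches[j] for j in art_ids]
    art_kd = [cKDTree(b.points) for b in art_branches]
    aw_kd = [cKDTree(b.points) for b in aw_branches]

    cost = np.full((len(aw_ids), len(art_ids)), _INF)
    metrics: dict[tuple[int, int], tuple[float, float, float]] = {}
    for i, aw in enumerate(aw_branches):
        for j, art in enumerate(art_branches):
            d, a, s = _pair_metrics(aw, art, art_kd[j], aw_kd[i])
            if np.isnan(s):
                continue
            c = w_dist * d + w_angle * a + w_size * s
            if c <= max_cost:
                # tiny deterministic perturbation -> lexicographic tie-break
                cost[i, j] = c + 1e-10 * (i * len(art_ids) + j)
                metrics[(i, j)] = (d, a, s)

    pairs: list[AAPair] = []
    if np.any(cost < _INF):
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if cost[i, j] >= _INF:
                continue
            d, a, s = metrics[(i, j)]
            pairs.append(
                AAPair(
                    airway_branch_id=aw_ids[i],
                    artery_branch_id=art_ids[j],
                    cost=w_dist * d + w_angle * a + w_size * s,
                    mean_centerline_distance=d,
                    orientation_angle=np.degrees(a),
                    diameter_similarity=s,
                )
            )
    pairs.sort(key=lambda p: p.airway_branch_id)
    n_unpaired = len(aw_ids) - len(pairs)
    logger.info("paired %d/%d airway branches (%d unpaired)",
                len(pairs), len(aw_ids), n_unpaired)
    return pairs
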
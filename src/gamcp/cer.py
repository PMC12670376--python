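"""Two-stage closed testing by the conditional error rate (CER/PCER) method.

For every intersection hypothesis a two-look group-sequential test is
prespecified: a stage-one constant ``c_{J,1}`` spending ``alpha_{J,1}`` and a
stage-two constant ``c_{J,2}`` exhausting ``alpha``, on the scale of the
weighted marginal p values (component ``j`` crosses a boundary when its
p value falls at or below ``w_{j,J} * c``).  At the interim, the conditional
probability that the preplanned test would still reject -- the conditional
error rate ``B_J`` (parametric regime) or the sum of partial conditional
error rates (nonparametric and mixed regimes) -- is computed given the
observed stage-one p values.  Whatever adaptation is then performed
(dropping hypotheses, reweighting, changing stage-two sample sizes), the
adapted stage-two test keeps the familywise error rate as long as its
conditional rejection probability does not exceed ``B_J``; the adapted
constant ``c~_{J,2}`` is the solution of that equality.

Cumulative p values combine the stages through the inverse-normal rule at
the (possibly adapted) per-hypothesis information fraction, so the
preplanned test is recovered exactly when nothing is adapted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .combo import (AdaptationPlan, DecisionReport, DesignSpec, InterimState,
                    _nonempty_subsets, partition_open)
from .graph import WeightTable
from .numerics import (CorrBlock, bvn_lower, one_factor_lower, p_to_z,
                       solve_monotone, two_look_lower, z_to_p)

__all__ = ["BoundaryTable", "BoundaryRow", "adapted_boundaries",
           "cumulative_p", "final_test", "interim_cer",
           "preplanned_boundaries"]

_C_BRACKET = (1e-12, 1.0 - 1e-12)


def cumulative_p(p1: float, p_incr: float, t: float) -> float:
    """Two-stage cumulative p value by the inverse-normal rule.

    ``1 - Phi(sqrt(t) z_{p1} + sqrt(1-t) z_{p_incr})`` with ``t`` the
    (possibly adapted) information fraction of stage one.
    """
    if not 0.0 < t < 1.0:
        raise ValueError("information fraction must lie in (0, 1)")
    return float(z_to_p(np.sqrt(t) * p_to_z(p1) + np.sqrt(1.0 - t) * p_to_z(p_incr)))


@dataclass(frozen=True)
class BoundaryRow:
    """Critical constants and interim conditional error for one subset."""

    subset: frozenset
    weights: dict
    regime: str
    c1: float
    c2: float
    B: float | None = None
    c2_adapted: float | None = None
    adapted_weights: dict | None = None
    effective: frozenset | None = None   # J intersect I2 for partially dropped J
    status: str = "open"                 # open | rejected1 | auto_reject | closed


@dataclass(frozen=True)
class BoundaryTable:
    labels: tuple
    alpha: float
    alpha1: float
    t_planned: float
    rows: dict  # frozenset -> BoundaryRow

    def row(self, subset) -> BoundaryRow:
        return self.rows[frozenset(subset)]


# -------------------------------------------------------------------------
# preplanned boundaries


def _per_component_two_look(w: float, c1: float, c2: float, t: float) -> float:
    """``P(P_1 <= w c1 or P_cum <= w c2)`` for one component, stage/cumulative
    z correlation ``sqrt(t)``."""
    x = p_to_z(min(w * c1, 1.0))
    y = p_to_z(min(w * c2, 1.0))
    upper = float(bvn_lower(-x, -y, np.sqrt(t)))
    return min(w * c1, 1.0) + float(z_to_p(y)) - upper


def _block_stage1_union(wvals: np.ndarray, c1: float, block: CorrBlock) -> float:
    th = p_to_z(np.minimum(wvals * c1, 1.0))
    return 1.0 - float(one_factor_lower(th, np.asarray(block.loadings1)))


def _block_two_look_union(wvals: np.ndarray, c1: float, c2: float, t: float,
                          block: CorrBlock) -> float:
    x = p_to_z(np.minimum(wvals * c1, 1.0))
    y = p_to_z(np.minimum(wvals * c2, 1.0))
    return 1.0 - two_look_lower(x, y, np.asarray(block.loadings1), t,
                                np.asarray(block.loadings2))


def _positive_weights(weights: dict) -> dict:
    pos = {l: w for l, w in weights.items() if w > 0.0}
    if not pos:
        raise ValueError("all weights are zero for an intersection hypothesis")
    return pos


def preplanned_boundaries(design: DesignSpec,
                          weight_table: WeightTable | None = None) -> BoundaryTable:
    """Solve the group-sequential equations for every intersection hypothesis.

    Nonparametric subsets use sums of marginal two-look probabilities (so
    ``c_{J,1} = alpha_{J,1}`` when the weights sum to one); parametric
    subsets use joint MVN probabilities of the stage-one and cumulative
    z statistics; mixed subsets sum block-wise parametric probabilities.
    """
    table = weight_table if weight_table is not None else design.weight_table()
    t, alpha, alpha1 = design.t_planned, design.alpha, design.alpha1
    corr = design.corr_model
    rows = {}
    cache: dict = {}
    for J in _nonempty_subsets(design.labels):
        weights = table.entry(J)
        pos = _positive_weights(weights)
        regime = corr.regime(list(pos))
        blocks = corr.partition(list(pos))
        key = (regime,
               tuple(sorted((round(pos[l], 12),
                             tuple(round(x, 12) for x in (b.loadings1 + b.loadings2)))
                            for b in blocks for l in b.labels)))
        if key in cache:
            c1, c2 = cache[key]
        else:
            c1, c2 = _solve_preplanned(pos, blocks, t, alpha, alpha1)
            cache[key] = (c1, c2)
        rows[J] = BoundaryRow(J, weights, regime, c1, c2)
    return BoundaryTable(design.labels, alpha, alpha1, t, rows)


def _solve_preplanned(pos: dict, blocks: list, t: float, alpha: float,
                      alpha1: float) -> tuple[float, float]:
    wsum = sum(pos.values())

    def stage1(c1: float) -> float:
        total = 0.0
        for b in blocks:
            wv = np.array([pos[l] for l in b.labels])
            if len(b.labels) == 1:
                total += min(float(wv[0]) * c1, 1.0)
            else:
                total += _block_stage1_union(wv, c1, b)
        return total

    if all(len(b.labels) == 1 for b in blocks):
        c1 = min(alpha1 / wsum, 1.0)      # sums of uniform tails are linear
    else:
        c1 = solve_monotone(stage1, _C_BRACKET, target=alpha1)

    def two_look(c2: float) -> float:
        total = 0.0
        for b in blocks:
            wv = np.array([pos[l] for l in b.labels])
            if len(b.labels) == 1:
                total += _per_component_two_look(float(wv[0]), c1, c2, t)
            else:
                total += _block_two_look_union(wv, c1, c2, t, b)
        return total

    c2 = solve_monotone(two_look, _C_BRACKET, target=alpha)
    return c1, c2


# -------------------------------------------------------------------------
# interim: stage-one decisions and conditional error rates


def conditional_threshold(w_c2, p1, t):
    """Incremental-z threshold: given stage one, the cumulative p value falls
    below ``w*c2`` iff the incremental z exceeds
    ``(z_{w c2} - sqrt(t) z_{p1}) / sqrt(1-t)``."""
    return (p_to_z(np.minimum(w_c2, 1.0)) - np.sqrt(t) * p_to_z(p1)) / np.sqrt(1.0 - t)


def _conditional_error(pos: dict, blocks: list, c2: float, p1: dict,
                       t: float) -> float:
    total = 0.0
    for b in blocks:
        wv = np.array([pos[l] for l in b.labels])
        d = conditional_threshold(wv * c2, np.array([p1[l] for l in b.labels]), t)
        if len(b.labels) == 1:
            total += float(z_to_p(d[0]))
        else:
            total += 1.0 - float(one_factor_lower(d, np.asarray(b.loadings2)))
    return total


def interim_cer(boundaries: BoundaryTable, p1: dict,
                design: DesignSpec) -> tuple[BoundaryTable, InterimState]:
    """Stage-one rejections and conditional error rates for the open subsets.

    A subset is rejected at stage one when any component p value crosses its
    weighted stage-one boundary.  For every open subset the conditional
    error ``B_J`` is the (sum of) conditional probabilities that the
    preplanned cumulative test would reject at stage two, given the observed
    stage-one p values.
    """
    missing = [l for l in boundaries.labels if l not in p1]
    if missing:
        raise KeyError(f"missing stage-one p values for {missing}")
    corr = design.corr_model
    t = boundaries.t_planned
    rows = {}
    rejected = set()
    adjusted = {}
    for J, row in boundaries.rows.items():
        pos = _positive_weights(row.weights)
        min_ratio = min(p1[l] / w for l, w in pos.items())
        adjusted[J] = (min_ratio, row.regime)
        if min_ratio <= row.c1:
            rows[J] = replace(row, status="rejected1")
            rejected.add(J)
        else:
            B = _conditional_error(pos, corr.partition(list(pos)), row.c2, p1, t)
            rows[J] = replace(row, B=B)
    early = frozenset(i for i in boundaries.labels
                      if all(J in rejected for J in rows if i in J))
    interim = InterimState(boundaries.labels, dict(p1), design.alpha1, adjusted,
                           frozenset(rejected), early,
                           frozenset(set(boundaries.labels) - early))
    return replace(boundaries, rows=rows), interim


# -------------------------------------------------------------------------
# adapted boundaries and final test


def adapted_boundaries(boundaries: BoundaryTable, plan: AdaptationPlan,
                       p1: dict, design: DesignSpec,
                       interim: InterimState) -> BoundaryTable:
    """Solve the CER/PCER equality for the adapted stage-two constants.

    For each open subset the adapted test uses the adapted weights, the
    adapted per-hypothesis information fractions and the adapted stage-two
    correlation structure; partially dropped subsets are tested through
    ``J intersect I2`` with weights renormalized on the surviving labels.
    Subsets with ``B_J >= 1`` (possible for the PCER sums) are auto-rejected;
    subsets with no surviving labels are closed without rejection.  If the
    equality is unreachable below one (the conditional error exceeds the
    rejection probability of the fully spent adapted test), the constant is
    capped at one, which keeps the conditional level below ``B_J``.
    """
    I2 = frozenset(plan.selected)
    if not I2 <= interim.continuing:
        raise ValueError("selected hypotheses must be a subset of the continuing set")
    corr2 = plan.corr_model if plan.corr_model is not None else design.corr_model
    tfrac = plan.info_fractions or {}
    preplanned = design.weight_table()
    rows = {}
    cache: dict = {}
    for J, row in boundaries.rows.items():
        if row.status == "rejected1":
            rows[J] = row
            continue
        eff = J & I2
        if not eff:
            rows[J] = replace(row, status="closed")
            continue
        weights = plan.stage2_weights(eff, preplanned)
        pos = _positive_weights(weights)
        if row.B is not None and row.B >= 1.0:
            rows[J] = replace(row, status="auto_reject", adapted_weights=weights,
                              effective=eff)
            continue
        blocks = corr2.partition(list(pos))
        tj = {l: float(tfrac.get(l, boundaries.t_planned)) for l in pos}
        key = (round(row.B, 15),
               tuple(sorted((l, round(pos[l], 12), round(tj[l], 12)) for l in pos)),
               tuple(tuple(b.labels) + b.loadings2 for b in blocks))
        if key in cache:
            c2a = cache[key]
        else:
            c2a = _solve_adapted(pos, blocks, tj, p1, row.B)
            cache[key] = c2a
        rows[J] = replace(row, c2_adapted=c2a, adapted_weights=weights,
                          effective=eff)
    return replace(boundaries, rows=rows)


def _adapted_conditional(pos: dict, blocks: list, tj: dict, p1: dict,
                         c: float) -> float:
    total = 0.0
    for b in blocks:
        d = np.array([float(conditional_threshold(pos[l] * c, p1[l], tj[l]))
                      for l in b.labels])
        if len(b.labels) == 1:
            total += float(z_to_p(d[0]))
        else:
            total += 1.0 - float(one_factor_lower(d, np.asarray(b.loadings2)))
    return total


def _solve_adapted(pos: dict, blocks: list, tj: dict, p1: dict,
                   B: float) -> float:
    g = lambda c: _adapted_conditional(pos, blocks, tj, p1, c)
    if g(_C_BRACKET[1]) <= B:
        return 1.0
    return solve_monotone(g, _C_BRACKET, target=B)


def final_test(boundaries: BoundaryTable, p2_incr: dict, plan: AdaptationPlan,
               design: DesignSpec, interim: InterimState) -> DecisionReport:
    """Cumulative stage-two p values against the adapted boundaries, then the
    closed-test decision for the elementary hypotheses."""
    I2 = frozenset(plan.selected)
    missing = [l for l in I2 if l not in p2_incr]
    if missing:
        raise KeyError(f"missing stage-two p values for selected hypotheses {missing}")
    tfrac = plan.info_fractions or {}
    p_cum = {l: cumulative_p(interim.p1[l], p2_incr[l],
                             float(tfrac.get(l, boundaries.t_planned)))
             for l in I2}
    rows = []
    reject = {}
    for J, row in boundaries.rows.items():
        if row.status == "rejected1":
            reject[J] = True
            rows.append({"subset": J, "stage": 1, "reject": True, "B": None})
            continue
        if row.status == "auto_reject":
            reject[J] = True
            rows.append({"subset": J, "stage": 2, "reject": True, "B": row.B,
                         "note": "PCER sum >= 1"})
            continue
        if row.status == "closed":
            reject[J] = False
            rows.append({"subset": J, "stage": None, "reject": False, "B": row.B})
            continue
        if row.c2_adapted is None:
            raise ValueError("adapted boundaries have not been computed")
        pos = _positive_weights(row.adapted_weights)
        rej = any(p_cum[l] <= w * row.c2_adapted for l, w in pos.items())
        reject[J] = rej
        rows.append({"subset": J, "stage": 2 if rej else None, "reject": rej,
                     "B": row.B, "c2_adapted": row.c2_adapted})
    elementary = {}
    for i in boundaries.labels:
        containing = [J for J in boundaries.rows if i in J]
        if all(reject[J] for J in containing):
            elementary[i] = "stage1" if i in interim.early_rejected else "stage2"
        else:
            elementary[i] = "retained"
    return DecisionReport(boundaries.labels, tuple(rows), elementary)
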
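"""Two-stage closed testing by the inverse-normal p-value combination method.

Workflow: ``plan`` (spending level at the interim plus the stage-two level
constant), ``interim_test`` (closed testing of every intersection hypothesis
on stage-one adjusted p values), an optional adaptation (hypothesis
selection, reweighting, sample-size change), and ``final_test`` (stage-two
adjusted p values combined with stage one through the prespecified
inverse-normal function, followed by the closed-test decisions).

The combination weights ``nu_1, nu_2`` are fixed at design time from the
planned information fraction and are never updated, which is what makes the
procedure valid under arbitrary data-dependent adaptations: under the null
the stage-wise adjusted p values are (super)uniform and independent, so the
combination statistic keeps its null distribution whatever happened at the
interim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations

import numpy as np
from scipy.stats import norm

from .adjusted import adjusted_p
from .graph import GraphSpec, WeightTable, closure_weights
from .numerics import (CorrelationModel, bvn_lower, p_to_z, solve_monotone,
                       z_to_p)

__all__ = ["AdaptationPlan", "DecisionReport", "DesignSpec", "InterimState",
           "combine", "final_test", "interim_test", "partition_open",
           "solve_alpha2", "spending_alpha1"]


def spending_alpha1(t: float, alpha: float) -> float:
    """Lan-DeMets O'Brien-Fleming-type error spending function.

    ``g(t, alpha) = 2 - 2 * Phi(z_{alpha/2} / sqrt(t))`` -- the type-1 error
    spent by information fraction ``t`` of a one-sided level-``alpha`` test.
    """
    if not 0.0 < t <= 1.0:
        raise ValueError("information fraction must lie in (0, 1]")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return float(2.0 * norm.sf(norm.isf(alpha / 2.0) / np.sqrt(t)))


def solve_alpha2(alpha1: float, alpha: float, combo_weights: tuple[float, float],
                 ) -> float:
    """Stage-two level satisfying the two-stage level condition.

    Solves ``P(P1 <= a1) + P(P1 > a1, C(P1, P2) <= a2) = alpha`` for ``a2``,
    with ``P1, P2`` independent uniforms and ``C`` the inverse-normal
    combination.  On the z scale the pair ``(Z1, nu1 Z1 + nu2 Z2)`` is
    bivariate normal with correlation ``nu1``, so the left side is a
    bivariate orthant expression.
    """
    nu1, nu2 = combo_weights
    if abs(nu1 * nu1 + nu2 * nu2 - 1.0) > 1e-9:
        raise ValueError("combination weights must satisfy nu1^2 + nu2^2 = 1")
    if not 0.0 <= alpha1 < alpha:
        raise ValueError("need 0 <= alpha1 < alpha")
    if alpha1 == 0.0:
        return alpha
    z1 = p_to_z(alpha1)

    def level(a2: float) -> float:
        z2 = p_to_z(a2)
        # P(Z1 >= z1) + P(Zc >= z2) - P(Z1 >= z1, Zc >= z2)
        return alpha1 + a2 - float(bvn_lower(-z1, -z2, nu1))

    return solve_monotone(level, (1e-12, alpha), target=alpha)


def combine(p1: float, p2_incr: float, combo_weights: tuple[float, float]) -> float:
    """Inverse-normal combination of independent stage-wise p values."""
    nu1, nu2 = combo_weights
    return float(z_to_p(nu1 * p_to_z(p1) + nu2 * p_to_z(p2_incr)))


# --------------------------------------------------------------------------


def _nonempty_subsets(labels):
    labels = tuple(labels)
    return [frozenset(c) for c in chain.from_iterable(
        combinations(labels, r) for r in range(1, len(labels) + 1))]


@dataclass(frozen=True)
class DesignSpec:
    """Preplanned design: graph, correlation knowledge, and spending.

    ``combo_weights`` defaults to ``(sqrt(t), sqrt(1-t))`` at the planned
    information fraction; ``alpha1`` defaults to the LDOF spend at ``t``.
    """

    graph: GraphSpec
    corr_model: CorrelationModel
    alpha: float = 0.025
    t_planned: float = 0.5
    combo_weights: tuple[float, float] | None = None
    alpha1: float | None = None

    def __post_init__(self):
        if not 0.0 < self.t_planned < 1.0:
            raise ValueError("planned information fraction must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.combo_weights is None:
            object.__setattr__(self, "combo_weights",
                               (float(np.sqrt(self.t_planned)),
                                float(np.sqrt(1.0 - self.t_planned))))
        nu1, nu2 = self.combo_weights
        if abs(nu1 * nu1 + nu2 * nu2 - 1.0) > 1e-9:
            raise ValueError("combination weights must satisfy nu1^2 + nu2^2 = 1")
        if self.alpha1 is None:
            object.__setattr__(self, "alpha1",
                               spending_alpha1(self.t_planned, self.alpha))

    @property
    def labels(self) -> tuple[str, ...]:
        return self.graph.labels

    def weight_table(self) -> WeightTable:
        return closure_weights(self.graph)

    def alpha2(self) -> float:
        return solve_alpha2(self.alpha1, self.alpha, self.combo_weights)


@dataclass(frozen=True)
class AdaptationPlan:
    """Stage-two adaptation: selected hypotheses, optional reweighting,
    optional per-hypothesis information fractions (used by the CER method),
    and an optional stage-two correlation model after reallocation."""

    selected: tuple[str, ...]
    weight_table: WeightTable | None = None
    info_fractions: dict | None = None
    corr_model: CorrelationModel | None = None

    def stage2_weights(self, subset: frozenset, preplanned: WeightTable) -> dict:
        table = self.weight_table if self.weight_table is not None else preplanned
        return table.entry(sorted(subset, key=preplanned.labels.index))


@dataclass(frozen=True)
class InterimState:
    """Everything the interim closed test determined from stage-one data."""

    labels: tuple[str, ...]
    p1: dict
    alpha1: float
    adjusted1: dict          # frozenset -> (p value, regime)
    rejected: frozenset      # J with p_{J,1} <= alpha_{J,1}
    early_rejected: frozenset  # elementary hypotheses rejected at stage one
    continuing: frozenset      # I1* = I1 minus early rejections

    @property
    def open_sets(self) -> list:
        return [J for J in _nonempty_subsets(self.labels) if J not in self.rejected]

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "p1": dict(self.p1),
            "alpha1": self.alpha1,
            "adjusted1": {",".join(sorted(J)): [p, r]
                          for J, (p, r) in self.adjusted1.items()},
            "rejected": sorted(",".join(sorted(J)) for J in self.rejected),
            "early_rejected": sorted(self.early_rejected),
            "continuing": sorted(self.continuing),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InterimState":
        return cls(
            labels=tuple(d["labels"]),
            p1={k: float(v) for k, v in d["p1"].items()},
            alpha1=float(d["alpha1"]),
            adjusted1={frozenset(k.split(",")): (float(v[0]), v[1])
                       for k, v in d["adjusted1"].items()},
            rejected=frozenset(frozenset(s.split(",")) for s in d["rejected"]),
            early_rejected=frozenset(d["early_rejected"]),
            continuing=frozenset(d["continuing"]),
        )


def interim_test(design: DesignSpec, weight_table: WeightTable | None,
                 p1: dict) -> InterimState:
    """Closed testing on stage-one adjusted p values.

    Rejects every intersection hypothesis whose adjusted stage-one p value
    is at or below the spent level; an elementary hypothesis is rejected at
    stage one when every intersection containing it is rejected.
    """
    table = weight_table if weight_table is not None else design.weight_table()
    missing = [l for l in design.labels if l not in p1]
    if missing:
        raise KeyError(f"missing stage-one p values for {missing}")
    adjusted: dict = {}
    rejected = set()
    for J in _nonempty_subsets(design.labels):
        w = table.entry(J)
        pj, regime = adjusted_p(p1, w, design.corr_model, stage=1)
        adjusted[J] = (pj, regime)
        if pj <= design.alpha1:
            rejected.add(J)
    early = frozenset(i for i in design.labels
                      if all(J in rejected for J in _nonempty_subsets(design.labels)
                             if i in J))
    return InterimState(design.labels, dict(p1), design.alpha1, adjusted,
                        frozenset(rejected), early,
                        frozenset(set(design.labels) - early))


def partition_open(interim: InterimState, plan: AdaptationPlan):
    """Split the open intersection hypotheses by stage-two data availability.

    ``JA`` have complete stage-two data (subsets of the selected set I2),
    ``JB`` none (subsets of the de-selected hypotheses), and ``JC`` partial
    data; their stage-two p values are inherited from ``J intersect I2``.
    """
    I2 = frozenset(plan.selected)
    if not I2 <= interim.continuing:
        raise ValueError("selected hypotheses must be a subset of the continuing set")
    JA, JB, JC = [], [], []
    for J in interim.open_sets:
        inter = J & I2
        if inter == J:
            JA.append(J)
        elif not inter:
            JB.append(J)
        else:
            JC.append(J)
    return JA, JB, JC


@dataclass(frozen=True)
class DecisionReport:
    """Per-intersection test results and closed-test elementary decisions."""

    labels: tuple[str, ...]
    rows: tuple          # per-subset dicts: subset, p1, p2, combined, ...
    elementary: dict     # label -> "stage1" | "stage2" | "retained"

    def rejected(self) -> frozenset:
        return frozenset(l for l, v in self.elementary.items() if v != "retained")


def final_test(design: DesignSpec, weight_table: WeightTable | None,
               interim: InterimState, plan: AdaptationPlan,
               p2_incr: dict) -> DecisionReport:
    """Stage-two combination tests and the closed-test decision.

    Stage-two adjusted p values use the (possibly adapted) weights for
    subsets of the selected set, are set to one where no stage-two data
    exist, and are inherited from ``J intersect I2`` otherwise.  An open
    ``J`` is rejected when the combined p value is at or below the
    stage-two level; elementary decisions follow the closed-test rule.
    """
    table = weight_table if weight_table is not None else design.weight_table()
    I2 = frozenset(plan.selected)
    missing = [l for l in I2 if l not in p2_incr]
    if missing:
        raise KeyError(f"missing stage-two p values for selected hypotheses {missing}")
    corr2 = plan.corr_model if plan.corr_model is not None else design.corr_model
    alpha2 = design.alpha2()
    JA, JB, JC = partition_open(interim, plan)

    stage2_adj: dict = {}
    for J in _nonempty_subsets(sorted(I2, key=design.labels.index)):
        w = plan.stage2_weights(J, table)
        stage2_adj[J] = adjusted_p(p2_incr, w, corr2, stage=2)

    rows = []
    reject: dict = {}
    for J in _nonempty_subsets(design.labels):
        p1j, regime1 = interim.adjusted1[J]
        if J in interim.rejected:
            rows.append({"subset": J, "p1": p1j, "p2": None, "combined": None,
                         "stage": 1, "reject": True})
            reject[J] = True
            continue
        if J in JB:
            p2j, regime2 = 1.0, "none"
        elif J in JC:
            p2j, regime2 = stage2_adj[J & I2]
        else:
            p2j, regime2 = stage2_adj[J]
        cj = combine(p1j, p2j, design.combo_weights)
        rej = cj <= alpha2
        reject[J] = rej
        rows.append({"subset": J, "p1": p1j, "p2": p2j, "combined": cj,
                     "stage": 2 if rej else None, "reject": rej})
    elementary = {}
    for i in design.labels:
        containing = [J for J in _nonempty_subsets(design.labels) if i in J]
        if all(reject[J] for J in containing):
            elementary[i] = "stage1" if i in interim.early_rejected else "stage2"
        else:
            elementary[i] = "retained"
    return DecisionReport(design.labels, tuple(rows), elementary)
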
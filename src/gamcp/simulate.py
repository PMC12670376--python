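"""Monte-Carlo engine for multiarm two-endpoint two-stage adaptive designs.

Emulates a trial with ``n_arms`` treatment arms compared pairwise to a
shared control on a primary and a secondary endpoint (one one-sided null
hypothesis per arm-endpoint pair, primaries first).  Subject-level outcomes
are bivariate normal with common standard deviation and endpoint
correlation ``rho``; marginal p values come from one-sided pooled-variance
t tests on each stage's subjects.  At the interim, treatment arms are
dropped by a threshold rule on the marginal primary p values, their planned
stage-two subjects are reallocated to the continuing arms, and the trial is
completed with either the p-value combination method or the conditional
error rate method.  Reported operating characteristics are disjunctive
power, conjunctive power and the familywise error rate, with Monte-Carlo
standard errors.

The testing machinery mirrors the object layer (``adjusted``, ``combo``,
``cer``) but is vectorized across replicates; agreement between the two
paths is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from . import cer
from .combo import DesignSpec, solve_alpha2, spending_alpha1
from .graph import GraphSpec, closure_weights
from .numerics import (AllocationSpec, CorrBlock, CorrelationModel,
                       one_factor_lower, p_to_z, solve_monotone, z_to_p)

__all__ = ["OperatingCharacteristics", "ScenarioSpec", "apply_dropping_rule",
           "dunnett_single_stage_power", "generate_stage_data",
           "multiarm_corr_model", "multiarm_graph", "simulate_oc"]

_RULES = {"conservative": 0.75, "normal": 0.5, "aggressive": 0.25}
_SIM_NODES = 32   # Gauss-Hermite grid inside the Monte-Carlo loops


# -------------------------------------------------------------------------
# design builders


def multiarm_graph(n_arms: int) -> GraphSpec:
    """Weighting strategy for ``n_arms`` primary + secondary hypothesis pairs.

    The initial weight is split equally among the primaries.  On rejection
    of a primary, 3/4 of its weight moves to the matching secondary and the
    rest is shared equally by the other primaries; a rejected secondary
    returns its weight equally to the other arms' primaries.
    """
    if n_arms < 2:
        raise ValueError("need at least two treatment arms")
    k = 2 * n_arms
    labels = tuple(f"H{i + 1}" for i in range(k))
    w = np.zeros(k)
    w[:n_arms] = 1.0 / n_arms
    g = np.zeros((k, k))
    for i in range(n_arms):
        g[i, n_arms + i] = 0.75
        for j in range(n_arms):
            if j != i:
                g[i, j] = 0.25 / (n_arms - 1)
                g[n_arms + i, j] = 1.0 / (n_arms - 1)
    return GraphSpec(labels, w, g)


def multiarm_corr_model(n_arms: int, alloc1: AllocationSpec,
                        alloc2: AllocationSpec | None = None) -> CorrelationModel:
    """Correlation knowledge: Dunnett blocks within each endpoint, unknown
    correlation across endpoints."""
    labels = [f"H{i + 1}" for i in range(2 * n_arms)]
    return CorrelationModel((
        CorrBlock.dunnett(labels[:n_arms], alloc1, alloc2),
        CorrBlock.dunnett(labels[n_arms:], alloc1, alloc2),
    ))


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation configuration.

    ``deltas`` are the primary-endpoint effect sizes per treatment arm; the
    secondary endpoint of each arm carries the same effect.  ``n_per_arm``
    is the per-stage planned size of every arm (interim at 50% of the
    planned total).  For the CER method the two-phase scheme draws ``m1``
    stage-one data sets and ``m2`` stage-two completions each.
    """

    deltas: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    sigma: float = 1.0
    rho: float = 0.5
    rule: str = "conservative"
    method: str = "combo"
    n_per_arm: int = 50
    alpha: float = 0.025
    t_planned: float = 0.5
    n_reps: int = 10_000
    m1: int = 10_000
    m2: int = 20

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("endpoint correlation must lie in (-1, 1)")
        if self.rule not in (*_RULES, "ultra"):
            raise ValueError(f"unknown dropping rule {self.rule!r}")
        if self.method not in ("combo", "cer"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_per_arm < 2:
            raise ValueError("need at least 2 subjects per arm per stage")

    @property
    def n_arms(self) -> int:
        return len(self.deltas)


@dataclass(frozen=True)
class OperatingCharacteristics:
    disjunctive: float
    conjunctive: float
    fwer: float
    se_disjunctive: float
    se_conjunctive: float
    se_fwer: float
    n_reps: int


# -------------------------------------------------------------------------
# data generation and interim selection


def generate_stage_data(scenario: ScenarioSpec, n_treat: Sequence[int],
                        n_control: int, rng: np.random.Generator,
                        n_reps: int, active: Sequence[int] | None = None,
                        ) -> np.ndarray:
    """One-sided pooled-variance t-test p values for one stage.

    Returns an array of shape ``(n_reps, n_arms, 2)`` (endpoints last,
    primary then secondary); columns of inactive arms are NaN.  Subject
    outcomes are bivariate normal with sd ``sigma`` and correlation ``rho``.
    """
    na = scenario.n_arms
    active = list(range(na)) if active is None else list(active)
    cov = scenario.sigma ** 2 * np.array([[1.0, scenario.rho],
                                          [scenario.rho, 1.0]])
    L = np.linalg.cholesky(cov)

    def arm_stats(n: int, delta: float):
        if n < 2:
            raise ValueError("sample size per arm must be >= 2")
        x = rng.standard_normal((n_reps, n, 2)) @ L.T + delta
        mean = x.mean(axis=1)
        ss = ((x - mean[:, None, :]) ** 2).sum(axis=1)
        return mean, ss

    m0, ss0 = arm_stats(n_control, 0.0)
    out = np.full((n_reps, na, 2), np.nan)
    for a in active:
        n_a = int(n_treat[a])
        m, ss = arm_stats(n_a, scenario.deltas[a])
        df = n_a + n_control - 2
        s2 = (ss + ss0) / df
        tstat = (m - m0) / np.sqrt(s2 * (1.0 / n_a + 1.0 / n_control))
        out[:, a, :] = stats.t.sf(tstat, df)
    return out


def apply_dropping_rule(p_primary: np.ndarray, rule: str) -> np.ndarray:
    """Boolean mask of continuing arms given stage-one primary p values.

    Threshold rules drop an arm when its p value is at or above the
    threshold; the ultra-aggressive rule keeps only the arm with the
    smallest p value (ties broken by the lowest arm index).
    """
    p = np.atleast_2d(np.asarray(p_primary, dtype=float))
    if rule in _RULES:
        keep = p < _RULES[rule]
    elif rule == "ultra":
        keep = np.zeros(p.shape, dtype=bool)
        keep[np.arange(p.shape[0]), np.argmin(p, axis=1)] = True
    else:
        raise ValueError(f"unknown dropping rule {rule!r}")
    return keep if p_primary.ndim > 1 else keep[0]


def _reallocate(n_per_arm: int, n_arms: int, cont: np.ndarray) -> tuple[int, int]:
    """Stage-two sizes after dropped-arm subjects are reassigned.

    The dropped arms' planned stage-two subjects are split equally over the
    continuing arms including control; the integer remainder goes to the
    control arm.  Returns ``(n_treat, n_control)`` for the continuing arms.
    """
    n_cont = int(cont.sum())
    if n_cont == 0:
        return 0, 0
    pool = n_per_arm * (n_arms - n_cont)
    share, rem = divmod(pool, n_cont + 1)
    return n_per_arm + share, n_per_arm + share + rem


# -------------------------------------------------------------------------
# vectorized closed testing over the subset lattice


class _SubsetInfo:
    """Static structure of one intersection hypothesis in the closure."""

    __slots__ = ("mask", "w", "pos", "groups", "wsums", "single")

    def __init__(self, mask: int, w: np.ndarray, n_arms: int):
        self.mask = mask
        self.w = w
        self.pos = np.array([j for j in range(2 * n_arms)
                             if mask >> j & 1 and w[j] > 0.0], dtype=int)
        prim = self.pos[self.pos < n_arms]
        sec = self.pos[self.pos >= n_arms]
        self.groups = [g for g in (prim, sec) if len(g)]
        self.wsums = [float(w[g].sum()) for g in self.groups]
        self.single = len(self.pos) == 1


def _build_infos(graph: GraphSpec, n_arms: int) -> list:
    table = closure_weights(graph)
    k = 2 * n_arms
    infos = [None] * (1 << k)
    for subset, wmap in table.subsets():
        mask = sum(1 << graph.labels.index(l) for l in subset)
        w = np.zeros(k)
        for l, v in wmap.items():
            w[graph.labels.index(l)] = v
        infos[mask] = _SubsetInfo(mask, w, n_arms)
    return infos


def _group_union(pm: np.ndarray, idx: np.ndarray, w: np.ndarray,
                 loading: float) -> np.ndarray:
    """Vectorized ``P(any P_j <= w_j q)`` with block-local observed ``q``."""
    wsub = w[idx]
    q = (pm[:, idx] / wsub).min(axis=1)
    th = p_to_z(np.minimum(q[:, None] * wsub, 1.0))
    a = np.full(len(idx), loading)
    return 1.0 - one_factor_lower(th, a, nodes=_SIM_NODES)


def _adjusted_batch(pm: np.ndarray, info: _SubsetInfo, loading: float) -> np.ndarray:
    """Stage-wise weighted-adjusted p values for one subset, all replicates."""
    if info.single:
        j = info.pos[0]
        return np.minimum(1.0, pm[:, j] / info.w[j])
    if len(info.groups) == 1:
        return _group_union(pm, info.groups[0], info.w, loading)
    terms = np.empty((pm.shape[0], len(info.groups)))
    for gi, (g, wsum) in enumerate(zip(info.groups, info.wsums)):
        if len(g) == 1:
            terms[:, gi] = pm[:, g[0]] / info.w[g[0]]
        else:
            terms[:, gi] = _group_union(pm, g, info.w, loading) / wsum
    return np.minimum(1.0, terms.min(axis=1))


def _elementary_all(R: np.ndarray, k: int) -> np.ndarray:
    """Closed-test decisions: hypothesis j rejected iff every subset
    containing j is rejected.  ``R`` is (reps, 2^k) over subset bitmasks."""
    phi = np.empty((R.shape[0], k), dtype=bool)
    masks = np.arange(1, 1 << k)
    for j in range(k):
        idx = masks[(masks >> j & 1).astype(bool)]
        phi[:, j] = R[:, idx].all(axis=1)
    return phi


def _oc_from_phi(phi: np.ndarray, false_null: np.ndarray, rule: str,
                 cluster: int = 1) -> OperatingCharacteristics:
    reps = phi.shape[0]
    any_true = (~false_null).any()
    any_false = false_null.any()
    fw = phi[:, ~false_null].any(axis=1) if any_true else None
    dis = phi[:, false_null].any(axis=1) if any_false else None
    con = phi[:, false_null].all(axis=1) if any_false else None
    if rule == "ultra":
        con = None   # at most one arm reaches stage two by construction

    def est(x):
        if x is None:
            return float("nan"), float("nan")
        p = float(x.mean())
        if cluster > 1:     # CER two-phase: stage-two draws share stage one
            means = x.reshape(-1, cluster).mean(axis=1)
            se = float(means.std(ddof=1) / np.sqrt(len(means)))
        else:
            se = float(np.sqrt(p * (1.0 - p) / reps))
        return p, se

    d, sd = est(dis)
    c, sc = est(con)
    f, sf = est(fw)
    return OperatingCharacteristics(d, c, f, sd, sc, sf, reps)


# -------------------------------------------------------------------------
# combo-method engine


def _simulate_combo(sc: ScenarioSpec, seed: int) -> OperatingCharacteristics:
    rng = np.random.default_rng(seed)
    na, k = sc.n_arms, 2 * sc.n_arms
    graph = multiarm_graph(na)
    infos = _build_infos(graph, na)
    alpha1 = spending_alpha1(sc.t_planned, sc.alpha)
    nu = (np.sqrt(sc.t_planned), np.sqrt(1.0 - sc.t_planned))
    alpha2 = solve_alpha2(alpha1, sc.alpha, nu)
    a1 = float(np.sqrt(sc.n_per_arm / (2.0 * sc.n_per_arm)))  # balanced stage one

    reps = sc.n_reps
    p1 = generate_stage_data(sc, [sc.n_per_arm] * na, sc.n_per_arm, rng, reps)
    pm1 = np.concatenate([p1[:, :, 0], p1[:, :, 1]], axis=1)  # primaries first
    nmask = 1 << k
    adj1 = np.ones((reps, nmask))
    for m in range(1, nmask):
        adj1[:, m] = _adjusted_batch(pm1, infos[m], a1)
    R1 = adj1 <= alpha1

    cont = apply_dropping_rule(p1[:, :, 0], sc.rule)
    Rfin = R1.copy()
    z1 = p_to_z(adj1)
    for pattern in np.unique(cont, axis=0):
        sel = np.nonzero((cont == pattern).all(axis=1))[0]
        if not pattern.any():
            continue    # everything dropped: no stage-two testing
        cm = sum(1 << j for j in range(k) if pattern[j % na])
        n2t, n2c = _reallocate(sc.n_per_arm, na, pattern)
        a2 = float(np.sqrt(n2t / (n2t + n2c)))
        rng_g = np.random.default_rng(rng.integers(2 ** 63))
        p2 = generate_stage_data(sc, [n2t] * na, n2c, rng_g, len(sel),
                                 active=np.nonzero(pattern)[0])
        pm2 = np.concatenate([p2[:, :, 0], p2[:, :, 1]], axis=1)
        adj2 = np.ones((len(sel), nmask))
        for m in range(1, nmask):
            if m & cm == m:
                adj2[:, m] = _adjusted_batch(pm2, infos[m], a2)
        z2 = p_to_z(adj2)
        for m in range(1, nmask):
            eff = m & cm
            if eff == 0:
                continue    # no stage-two data: combined test cannot reject
            comb = z_to_p(nu[0] * z1[sel, m] + nu[1] * z2[:, eff])
            Rfin[sel, m] |= comb <= alpha2
    phi = _elementary_all(Rfin, k)
    false_null = np.array([sc.deltas[j % na] != 0.0 for j in range(k)])
    return _oc_from_phi(phi, false_null, sc.rule)


# -------------------------------------------------------------------------
# CER-method engine (two-phase Monte Carlo)


def _bisect_increasing(f, target: np.ndarray, lo: float = 1e-12,
                       hi: float = 1.0, iters: int = 50) -> np.ndarray:
    """Vectorized bisection for an increasing function; problems whose
    target exceeds ``f(hi)`` resolve to ``hi`` (boundary capped at one)."""
    lo_v = np.full(target.shape, lo)
    hi_v = np.full(target.shape, hi)
    for _ in range(iters):
        mid = 0.5 * (lo_v + hi_v)
        below = f(mid) < target
        lo_v = np.where(below, mid, lo_v)
        hi_v = np.where(below, hi_v, mid)
    return 0.5 * (lo_v + hi_v)


def _cond_error_batch(z1: np.ndarray, info: _SubsetInfo, c2, t: float,
                      loading: float) -> np.ndarray:
    """Conditional error of a weighted two-look test given stage-one
    z scores ``z1`` (reps, k); ``c2`` scalar or per-rep vector."""
    st, s2 = np.sqrt(t), np.sqrt(1.0 - t)
    c2 = np.asarray(c2, dtype=float)
    total = np.zeros(z1.shape[0])
    for g in info.groups:
        wc = np.minimum(np.multiply.outer(c2, info.w[g]), 1.0)
        d = (p_to_z(wc) - st * z1[:, g]) / s2
        if len(g) == 1:
            total += z_to_p(d[:, 0])
        else:
            a = np.full(len(g), loading)
            total += 1.0 - one_factor_lower(d, a, nodes=_SIM_NODES)
    return total


def _simulate_cer(sc: ScenarioSpec, seed: int) -> OperatingCharacteristics:
    rng = np.random.default_rng(seed)
    na, k = sc.n_arms, 2 * sc.n_arms
    graph = multiarm_graph(na)
    infos = _build_infos(graph, na)
    nmask = 1 << k
    alloc1 = AllocationSpec(sc.n_per_arm, (sc.n_per_arm,) * na)
    design = DesignSpec(graph, multiarm_corr_model(na, alloc1),
                        alpha=sc.alpha, t_planned=sc.t_planned)
    btab = cer.preplanned_boundaries(design)
    c1 = np.zeros(nmask)
    c2 = np.zeros(nmask)
    for J, row in btab.rows.items():
        m = sum(1 << graph.labels.index(l) for l in J)
        c1[m], c2[m] = row.c1, row.c2
    a_pre = float(np.sqrt(0.5))

    m1, m2 = sc.m1, sc.m2
    p1 = generate_stage_data(sc, [sc.n_per_arm] * na, sc.n_per_arm, rng, m1)
    pm1 = np.concatenate([p1[:, :, 0], p1[:, :, 1]], axis=1)
    z1 = p_to_z(pm1)
    minratio = np.full((m1, nmask), np.inf)
    for m in range(1, nmask):
        info = infos[m]
        minratio[:, m] = (pm1[:, info.pos] / info.w[info.pos]).min(axis=1)
    R1 = minratio <= c1[None, :]
    R1[:, 0] = False

    B = np.zeros((m1, nmask))
    for m in range(1, nmask):
        B[:, m] = _cond_error_batch(z1, infos[m], c2[m], sc.t_planned, a_pre)

    cont = apply_dropping_rule(p1[:, :, 0], sc.rule)
    reject_any = np.zeros((m1, m2, k), dtype=bool)
    for pattern in np.unique(cont, axis=0):
        sel = np.nonzero((cont == pattern).all(axis=1))[0]
        Rsel = R1[sel]
        phi_stage2 = np.zeros((len(sel), m2, nmask), dtype=bool)
        if pattern.any():
            cm = sum(1 << j for j in range(k) if pattern[j % na])
            n2t, n2c = _reallocate(sc.n_per_arm, na, pattern)
            a2 = float(np.sqrt(n2t / (n2t + n2c)))
            tt = float((1.0 / (2.0 / sc.n_per_arm))
                       / (1.0 / (2.0 / sc.n_per_arm) + 1.0 / (1.0 / n2t + 1.0 / n2c)))
            no_adapt = (cm == nmask - 1) and abs(tt - sc.t_planned) < 1e-12
            # adapted constants per open subset
            cstar = np.zeros((len(sel), nmask))
            auto = np.zeros((len(sel), nmask), dtype=bool)
            for m in range(1, nmask):
                eff = m & cm
                open_rows = ~Rsel[:, m]
                if eff == 0 or not open_rows.any():
                    continue
                Bm = B[sel, m]
                auto[:, m] = open_rows & (Bm >= 1.0)
                todo = open_rows & ~auto[:, m]
                if not todo.any():
                    continue
                if no_adapt:
                    cstar[todo, m] = c2[m]
                    continue
                z1_sub = z1[sel][todo]
                info_eff = infos[eff]
                f = lambda c: _cond_error_batch(z1_sub, info_eff, c, tt, a2)
                cstar[todo, m] = _bisect_increasing(f, Bm[todo])
            # stage-two completions
            act = np.nonzero(pattern)[0]
            rng_g = np.random.default_rng(rng.integers(2 ** 63))
            p2 = generate_stage_data(sc, [n2t] * na, n2c, rng_g, len(sel) * m2,
                                     active=act)
            pm2 = np.concatenate([p2[:, :, 0], p2[:, :, 1]], axis=1)
            zc = np.sqrt(tt) * np.repeat(z1[sel], m2, axis=0) \
                + np.sqrt(1.0 - tt) * p_to_z(pm2)
            pcum = z_to_p(zc).reshape(len(sel), m2, k)
            for m in range(1, nmask):
                eff = m & cm
                if eff == 0:
                    continue
                info_eff = infos[eff]
                bound = cstar[:, m][:, None, None] * info_eff.w[info_eff.pos]
                hit = (pcum[:, :, info_eff.pos] <= bound).any(axis=2)
                phi_stage2[:, :, m] = hit | auto[:, m][:, None]
        Rfin = Rsel[:, None, :] | phi_stage2
        masks = np.arange(1, nmask)
        for j in range(k):
            idx = masks[(masks >> j & 1).astype(bool)]
            reject_any[sel, :, j] = Rfin[:, :, idx].all(axis=2)
    phi = reject_any.reshape(m1 * m2, k)
    false_null = np.array([sc.deltas[j % na] != 0.0 for j in range(k)])
    return _oc_from_phi(phi, false_null, sc.rule, cluster=m2)


def simulate_oc(scenario: ScenarioSpec, seed: int = 0) -> OperatingCharacteristics:
    """Estimate disjunctive power, conjunctive power and FWER by simulation."""
    if scenario.method == "combo":
        return _simulate_combo(scenario, seed)
    return _simulate_cer(scenario, seed)


# -------------------------------------------------------------------------


def dunnett_single_stage_power(n_per_arm: int, delta: float, sigma: float,
                               alpha: float = 0.025, n_treatments: int = 2,
                               ) -> float:
    """Disjunctive power of a one-look one-sided Dunnett test.

    Balanced arms: the z statistics are equicorrelated with 0.5; the
    critical value solves ``P0(max Z > c) = alpha`` and the power is the
    probability that any shifted statistic exceeds it, with noncentrality
    ``delta / (sigma * sqrt(2 / n))``.
    """
    a = np.full(n_treatments, np.sqrt(n_per_arm / (2.0 * n_per_arm)))
    crit = solve_monotone(
        lambda c: 1.0 - float(one_factor_lower(np.full(n_treatments, c), a)),
        (0.0, 10.0), target=alpha)
    shift = delta / (sigma * np.sqrt(2.0 / n_per_arm))
    return 1.0 - float(one_factor_lower(np.full(n_treatments, crit - shift), a))
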
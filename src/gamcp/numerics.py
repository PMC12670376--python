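"""Deterministic multivariate-normal numerics shared by all testing modules.

Every probability a boundary equation needs reduces to an orthant probability
of a multivariate normal whose correlation matrix has a *one-factor*
structure, ``corr(Z_i, Z_j) = a_i * a_j`` for loadings ``a``.  Z statistics
of treatment-versus-control comparisons that share the control arm are of
this form (loadings ``sqrt(n_i / (n_i + n_0))``), as are equicorrelated
blocks with nonnegative correlation (loadings ``sqrt(rho)``).  Conditioning
on the shared factor turns a d-dimensional integral into a one-dimensional
Gauss-Hermite quadrature, which is fast, vectorizes over many threshold
vectors at once, and is bit-reproducible -- properties the root-finding
layers above rely on.

General correlation matrices are handled through scipy's MVN integrator,
which is used here only as a fallback and in cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr
from scipy.stats import multivariate_normal, norm

__all__ = [
    "AllocationSpec",
    "BracketError",
    "CorrBlock",
    "CorrelationModel",
    "bvn_lower",
    "dunnett_correlation",
    "dunnett_loadings",
    "information_fraction",
    "mvn_lower_orthant",
    "mvn_upper_orthant",
    "one_factor_lower",
    "p_to_z",
    "solve_monotone",
    "two_look_lower",
    "z_to_p",
]

# marginal p values of exactly 0 or 1 are clamped before the normal inverse
P_CLAMP = 1e-15

_GH_NODES = 96


def _gauss_hermite(n: int = _GH_NODES) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights for E[f(U)], U ~ N(0,1)."""
    x, w = np.polynomial.hermite.hermgauss(n)
    return np.sqrt(2.0) * x, w / np.sqrt(np.pi)


_GH_U, _GH_W = _gauss_hermite()

_GL_NODES = 64
_GL_X, _GL_W = np.polynomial.legendre.leggauss(_GL_NODES)


def p_to_z(p):
    """Upper-tail z score ``Phi^{-1}(1 - p)`` with clamping at 0 and 1."""
    return norm.isf(np.clip(p, P_CLAMP, 1.0 - P_CLAMP))


def z_to_p(z):
    """Upper-tail p value ``1 - Phi(z)``."""
    return ndtr(-np.asarray(z, dtype=float))


def bvn_lower(h, k, rho):
    """Bivariate standard normal CDF ``P(X <= h, Y <= k)``, vectorized.

    Uses the correlation-integral representation
    ``Phi2(h,k,rho) = Phi(h)Phi(k) + (2*pi)^-1 int_0^rho phi2(h,k;r) dr``
    with fixed Gauss-Legendre quadrature; absolute accuracy is well below
    1e-12 for |rho| <= 0.95, which covers every correlation arising here.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    # nodes on [0, rho]: r = rho/2 * (x+1)
    r = 0.5 * rho[..., None] * (_GL_X + 1.0)
    om = 1.0 - r * r
    hh = h[..., None]
    kk = k[..., None]
    dens = np.exp(-(hh * hh - 2.0 * r * hh * kk + kk * kk) / (2.0 * om)) / np.sqrt(om)
    integral = 0.5 * rho * (dens @ _GL_W)
    out = ndtr(h) * ndtr(k) + integral / (2.0 * np.pi)
    return np.clip(out, 0.0, 1.0)


_GH_CACHE: dict = {_GH_NODES: (_GH_U, _GH_W)}


def one_factor_lower(thresholds, loadings, nodes: int | None = None):
    """``P(Z_1 <= t_1, ..., Z_d <= t_d)`` for one-factor correlation.

    ``corr(Z_i, Z_j) = loadings[i] * loadings[j]``.  ``thresholds`` may carry
    leading batch axes; the last axis matches ``loadings``.  ``nodes``
    selects the Gauss-Hermite grid size (default 96; simulation code passes
    a smaller grid where Monte-Carlo error dominates anyway).
    """
    t = np.asarray(thresholds, dtype=float)
    a = np.asarray(loadings, dtype=float)
    if np.any(a < 0.0) or np.any(a > 1.0):
        raise ValueError("one-factor loadings must lie in [0, 1]")
    b = np.sqrt(1.0 - a * a)
    if nodes is None:
        u, gw = _GH_U, _GH_W
    else:
        if nodes not in _GH_CACHE:
            _GH_CACHE[nodes] = _gauss_hermite(nodes)
        u, gw = _GH_CACHE[nodes]
    # arg shape (..., m, d)
    num = t[..., None, :] - a * u[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(b > 0.0, ndtr(num / np.where(b > 0.0, b, 1.0)),
                        (num >= 0.0).astype(float))
    prod = np.prod(cond, axis=-1)
    return prod @ gw


def mvn_lower_orthant(thresholds, corr) -> float:
    """``P(Z_1 <= t_1, ..., Z_d <= t_d)`` for a general correlation matrix.

    Dispatches to the closed one-dimensional form (d=1), the deterministic
    bivariate quadrature (d=2), a one-factor reduction when the matrix has
    one (including equicorrelated matrices), and scipy's MVN integrator
    otherwise.
    """
    t = np.asarray(thresholds, dtype=float)
    R = np.atleast_2d(np.asarray(corr, dtype=float))
    d = t.shape[-1]
    if R.shape != (d, d):
        raise ValueError(f"correlation matrix shape {R.shape} does not match {d} thresholds")
    if not np.allclose(R, R.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if d == 1:
        return float(ndtr(t[0]))
    if d == 2:
        return float(bvn_lower(t[0], t[1], R[0, 1]))
    a = _one_factor_loadings(R)
    if a is not None:
        return float(one_factor_lower(t, a))
    # eigenvalue check, then deterministic scipy integration
    w = np.linalg.eigvalsh(R)
    if w.min() < -1e-9:
        raise np.linalg.LinAlgError("correlation matrix is not positive semidefinite")
    return float(multivariate_normal.cdf(t, mean=np.zeros(d), cov=R,
                                         allow_singular=True, abseps=1e-10,
                                         maxpts=2_000_000))


def mvn_upper_orthant(thresholds, corr) -> float:
    """``P(Z_1 > t_1, ..., Z_d > t_d)`` for standard MVN with correlation ``corr``."""
    t = np.asarray(thresholds, dtype=float)
    return mvn_lower_orthant(-t, corr)


def _one_factor_loadings(R: np.ndarray) -> np.ndarray | None:
    """Recover nonnegative loadings with ``R_ij = a_i a_j`` if they exist."""
    d = R.shape[0]
    off = ~np.eye(d, dtype=bool)
    if np.any(R[off] < -1e-14):
        return None  # negative correlations have no nonnegative factorization
    a2 = np.full(d, np.nan)
    for i in range(d):
        others = [j for j in range(d) if j != i]
        if all(R[i, j] < 1e-14 for j in others):
            a2[i] = 0.0  # isolated component
            continue
        for j in others:
            for k in others:
                if k != j and R[j, k] > 1e-14 and R[i, j] > 1e-14 and R[i, k] > 1e-14:
                    a2[i] = R[i, j] * R[i, k] / R[j, k]
                    break
            else:
                continue
            break
    if np.any(np.isnan(a2)) or np.any(a2 > 1.0 + 1e-10):
        return None
    a = np.sqrt(np.clip(a2, 0.0, 1.0))
    guess = np.outer(a, a)
    np.fill_diagonal(guess, 1.0)
    return a if np.allclose(guess, R, atol=1e-10) else None


def two_look_lower(x, y, loadings, t, loadings2=None) -> float:
    """Joint lower-orthant probability for stage-one and cumulative z statistics.

    ``P(Z_{j,1} <= x_j and Z_{j,2} <= y_j for all j)`` where the stage-one
    statistics ``Z_{j,1}`` share a one-factor structure with ``loadings``,
    the incremental stage-two statistics share ``loadings2`` (defaults to
    ``loadings``), and the cumulative statistic is the preplanned inverse
    normal composite ``Z_{j,2} = sqrt(t) Z_{j,1} + sqrt(1-t) Z_{j,(2)}``.

    Conditioning on the two shared factors leaves a product of bivariate
    normal probabilities, integrated on a tensor Gauss-Hermite grid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a1 = np.asarray(loadings, dtype=float)
    a2 = a1 if loadings2 is None else np.asarray(loadings2, dtype=float)
    if not 0.0 < t < 1.0:
        raise ValueError("information fraction t must lie in (0, 1)")
    b1 = np.sqrt(1.0 - a1 * a1)
    b2 = np.sqrt(1.0 - a2 * a2)
    st, s2 = np.sqrt(t), np.sqrt(1.0 - t)
    sd2 = np.sqrt(t * b1 * b1 + (1.0 - t) * b2 * b2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(sd2 > 0, st * b1 * b1 / np.where(sd2 > 0, b1 * sd2, 1.0), 0.0)
    m = 40
    ug, wg = _gauss_hermite(m)
    U1 = ug[:, None]
    U2 = ug[None, :]
    prob = np.ones((m, m))
    for j in range(x.shape[0]):
        if b1[j] <= 0 or sd2[j] <= 0:
            raise ValueError("degenerate loading of 1.0 is not supported")
        h = (x[j] - a1[j] * U1) / b1[j] + 0.0 * U2
        k = (y[j] - st * a1[j] * U1 - s2 * a2[j] * U2) / sd2[j]
        prob *= bvn_lower(h, k, r[j])
    return float(wg @ prob @ wg)


class BracketError(ArithmeticError, ValueError):
    """A root-finding bracket does not straddle the target value."""


def solve_monotone(f, bracket, target=0.0, xtol=1e-12) -> float:
    """Root of a monotone scalar function; deterministic Brent bisection.

    Raises ``BracketError`` when the bracket does not straddle the target.
    """
    lo, hi = bracket
    flo, fhi = f(lo) - target, f(hi) - target
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if np.sign(flo) == np.sign(fhi):
        raise BracketError(
            f"no sign change in bracket [{lo}, {hi}]: f-target = ({flo:.3g}, {fhi:.3g})")
    return brentq(lambda v: f(v) - target, lo, hi, xtol=xtol)


# --------------------------------------------------------------------------
# allocation / correlation bookkeeping


@dataclass(frozen=True)
class AllocationSpec:
    """Per-arm sample sizes for one stage: a control arm plus treatment arms."""

    n_control: int
    n_treatments: tuple[int, ...]

    def __post_init__(self):
        sizes = (self.n_control, *self.n_treatments)
        if any(int(n) < 2 for n in sizes):
            raise ValueError("all per-arm sample sizes must be >= 2")

    @property
    def k(self) -> int:
        return len(self.n_treatments)


def dunnett_loadings(alloc: AllocationSpec) -> np.ndarray:
    """Loadings ``sqrt(n_i / (n_i + n_0))`` of the shared-control factor."""
    n = np.asarray(alloc.n_treatments, dtype=float)
    return np.sqrt(n / (n + alloc.n_control))


def dunnett_correlation(alloc: AllocationSpec) -> np.ndarray:
    """Correlation matrix of treatment-vs-control z statistics.

    ``corr(Z_i, Z_j) = sqrt(lambda_i * lambda_j)`` with
    ``lambda_i = n_i / (n_i + n_0)``; 0.5 everywhere under balanced
    randomization.
    """
    a = dunnett_loadings(alloc)
    R = np.outer(a, a)
    np.fill_diagonal(R, 1.0)
    return R


def information_fraction(alloc_stage1: AllocationSpec,
                         alloc_stage2_incr: AllocationSpec) -> np.ndarray:
    """Per-comparison interim information fraction.

    ``t_j = I_j1 / (I_j1 + I_j(2))`` where ``I = (1/n_T + 1/n_C)^{-1}`` is
    the information of a difference of means with unit variance.
    """
    if alloc_stage1.k != alloc_stage2_incr.k:
        raise ValueError("stage allocations must cover the same treatments")
    n1 = np.asarray(alloc_stage1.n_treatments, dtype=float)
    n2 = np.asarray(alloc_stage2_incr.n_treatments, dtype=float)
    i1 = 1.0 / (1.0 / n1 + 1.0 / alloc_stage1.n_control)
    i2 = 1.0 / (1.0 / n2 + 1.0 / alloc_stage2_incr.n_control)
    return i1 / (i1 + i2)


@dataclass(frozen=True)
class CorrBlock:
    """A set of hypotheses whose z-statistic correlations are known.

    ``loadings1``/``loadings2`` give the one-factor representation of the
    stage-one and incremental stage-two correlation matrices.  Distinct
    blocks are treated as having unknown cross-correlations; no numeric
    value is ever imputed for them.
    """

    labels: tuple[str, ...]
    loadings1: tuple[float, ...]
    loadings2: tuple[float, ...]

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in correlation block")
        for a in (*self.loadings1, *self.loadings2):
            if not 0.0 <= a <= 1.0:
                raise ValueError("loadings must lie in [0, 1]")
        if not len(self.labels) == len(self.loadings1) == len(self.loadings2):
            raise ValueError("loadings must match labels")

    @classmethod
    def equicorrelated(cls, labels, rho: float) -> "CorrBlock":
        if rho < 0.0:
            raise ValueError("equicorrelated blocks require rho >= 0")
        a = float(np.sqrt(rho))
        return cls(tuple(labels), (a,) * len(labels), (a,) * len(labels))

    @classmethod
    def dunnett(cls, labels, alloc1: AllocationSpec,
                alloc2: AllocationSpec | None = None) -> "CorrBlock":
        a1 = dunnett_loadings(alloc1)
        a2 = a1 if alloc2 is None else dunnett_loadings(alloc2)
        return cls(tuple(labels), tuple(a1), tuple(a2))

    def corr(self, stage: int = 1) -> np.ndarray:
        a = np.asarray(self.loadings1 if stage == 1 else self.loadings2)
        R = np.outer(a, a)
        np.fill_diagonal(R, 1.0)
        return R

    def sub(self, labels) -> "CorrBlock":
        idx = [self.labels.index(l) for l in labels]
        return CorrBlock(tuple(labels),
                         tuple(self.loadings1[i] for i in idx),
                         tuple(self.loadings2[i] for i in idx))


@dataclass(frozen=True)
class CorrelationModel:
    """Partition of the hypothesis labels into known-correlation blocks.

    Labels not listed in any block are treated as implicit singleton blocks
    (their correlations with everything else are unknown).
    """

    blocks: tuple[CorrBlock, ...]

    def __post_init__(self):
        seen: set[str] = set()
        for b in self.blocks:
            if seen & set(b.labels):
                raise ValueError("correlation blocks must be disjoint")
            seen |= set(b.labels)

    def partition(self, labels) -> list[CorrBlock]:
        """Restrict the block structure to ``labels`` (order preserved)."""
        labels = list(labels)
        out: list[CorrBlock] = []
        claimed: set[str] = set()
        for b in self.blocks:
            sub = [l for l in labels if l in b.labels]
            if sub:
                out.append(b.sub(sub))
                claimed |= set(sub)
        for l in labels:
            if l not in claimed:
                out.append(CorrBlock((l,), (0.0,), (0.0,)))
        return out

    def regime(self, labels) -> str:
        """Test regime for a set of (positive-weight) labels."""
        labels = list(labels)
        if len(labels) <= 1:
            return "single"
        groups = self.partition(labels)
        if len(groups) == 1:
            return "parametric"
        if all(len(g.labels) == 1 for g in groups):
            return "nonparametric"
        return "mixed"
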
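"""Weighted-adjusted p values for intersection hypotheses.

Three regimes, chosen by what is known about the correlations among the
z statistics of the component hypotheses (after dropping zero-weight
components):

* nonparametric -- weighted Bonferroni, ``min(1, min_j p_j / w_j)``;
* parametric -- the exceedance probability
  ``P(min_j P_j / w_j <= min_j p_j / w_j)`` under the joint normal null,
  which is a union probability on the z scale;
* mixed -- the component labels are partitioned into blocks of known
  correlation; each block contributes its parametric exceedance probability
  divided by the block's weight sum, and the minimum over blocks (capped at
  one) is the adjusted p value.

The same functions serve stage-one p values and incremental stage-two
p values; only the correlation loadings differ.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .numerics import CorrelationModel, one_factor_lower, p_to_z

__all__ = ["adjusted_p", "bonferroni_adjusted", "mixed_adjusted",
           "parametric_adjusted"]


def _positive(p: Mapping[str, float], weights: Mapping[str, float]):
    labels = [l for l, w in weights.items() if w > 0.0]
    if not labels:
        raise ValueError("all weights are zero: adjusted p value undefined")
    missing = [l for l in labels if l not in p]
    if missing:
        raise KeyError(f"no p value supplied for {missing}")
    for l in labels:
        if not 0.0 <= p[l] <= 1.0:
            raise ValueError(f"p value for {l!r} outside [0, 1]")
    return labels


def bonferroni_adjusted(p: Mapping[str, float], weights: Mapping[str, float]) -> float:
    """Weighted Bonferroni adjusted p value; zero-weight components dropped."""
    labels = _positive(p, weights)
    return min(1.0, min(p[l] / weights[l] for l in labels))


def _block_exceedance(p: Mapping[str, float], weights: Mapping[str, float],
                      labels, loadings) -> float:
    """``P(min_{j in block} P_j / w_j <= q)`` with ``q`` the observed block
    minimum, as a one-factor union probability on the z scale."""
    w = np.array([weights[l] for l in labels])
    q = min(p[l] / weights[l] for l in labels)
    thresholds = p_to_z(w * q)
    return float(1.0 - one_factor_lower(thresholds, np.asarray(loadings)))


def parametric_adjusted(p: Mapping[str, float], weights: Mapping[str, float],
                        corr_model: CorrelationModel, stage: int = 1) -> float:
    """Weighted parametric adjusted p value (all correlations known)."""
    labels = _positive(p, weights)
    if len(labels) == 1:
        return min(1.0, p[labels[0]] / weights[labels[0]])
    groups = corr_model.partition(labels)
    if len(groups) != 1:
        raise ValueError(
            f"correlations among {labels} are not fully known; use mixed_adjusted")
    block = groups[0]
    loadings = block.loadings1 if stage == 1 else block.loadings2
    return _block_exceedance(p, weights, block.labels, loadings)


def mixed_adjusted(p: Mapping[str, float], weights: Mapping[str, float],
                   corr_model: CorrelationModel, stage: int = 1) -> float:
    """Weighted mixed adjusted p value (correlations known within blocks)."""
    labels = _positive(p, weights)
    terms = []
    for block in corr_model.partition(labels):
        if len(block.labels) == 1:
            l = block.labels[0]
            terms.append(p[l] / weights[l])
        else:
            loadings = block.loadings1 if stage == 1 else block.loadings2
            prob = _block_exceedance(p, weights, block.labels, loadings)
            terms.append(prob / sum(weights[l] for l in block.labels))
    return min(1.0, min(terms))


def adjusted_p(p: Mapping[str, float], weights: Mapping[str, float],
               corr_model: CorrelationModel, stage: int = 1) -> tuple[float, str]:
    """Adjusted p value plus the regime used, dispatched on the positive-
    weight labels and the correlation-knowledge structure."""
    labels = _positive(p, weights)
    regime = corr_model.regime(labels)
    if regime == "single":
        return min(1.0, p[labels[0]] / weights[labels[0]]), regime
    if regime == "nonparametric":
        return bonferroni_adjusted(p, weights), regime
    if regime == "parametric":
        return parametric_adjusted(p, weights, corr_model, stage), regime
    return mixed_adjusted(p, weights, corr_model, stage), regime
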
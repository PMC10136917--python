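"""Node predictability: variance explained by network neighbours.

For each symptom the item is regressed (ordinary least squares, in-sample)
on the items it shares a nonzero edge with in the estimated network, and the
R-squared — clipped to [0, 1] — is reported.  Treating the 0-3 ordinal items
as continuous makes this the Gaussian special case of mixed-graphical-model
predictability, consistent with the Gaussian machinery used for estimation.
Isolated nodes get R² = 0 by convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .instruments import ItemResponseMatrix
from .network import EDGE_EPS, SymptomNetwork

logger = logging.getLogger(__name__)

__all__ = ["PredictabilityProfile", "node_predictability"]


@dataclass
class PredictabilityProfile:
    r2: pd.Series  # per-node R-squared in [0, 1]

    @property
    def mean(self) -> float:
        return float(self.r2.mean())


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    """In-sample R² of y ~ 1 + X via least squares (min-norm on singular designs)."""
    n = len(y)
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        logger.warning("collinear neighbour design; using minimum-norm solution")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum(resid**2) / ss_tot)


def node_predictability(
    responses: ItemResponseMatrix, net: SymptomNetwork
) -> PredictabilityProfile:
    """Per-node in-sample R² from nonzero-edge neighbours, and its mean.

    The neighbourhood is taken from the estimated network (not refitted),
    so the value answers: how much of this symptom's variance do its
    connected symptoms explain?
    """
    if list(net.labels) != list(responses.items):
        raise ValueError("network labels must match response items")
    X = responses.values.astype(float)
    r2 = {}
    for i, node in enumerate(net.labels):
        nb = [j for j in range(net.p) if j != i and abs(net.W[i, j]) > EDGE_EPS]
        if not nb:
            r2[node] = 0.0
            continue
        val = _ols_r2(X[:, i], X[:, nb])
        r2[node] = float(np.clip(val, 0.0, 1.0))
    return PredictabilityProfile(r2=pd.Series(r2, name="predictability"))
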
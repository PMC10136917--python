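"""Bootstrap accuracy and stability of the estimated network.

Three procedures, all nonparametric and all driven by one master seed:

* **Edge accuracy** — resample subjects with replacement, re-run the whole
  Spearman -> glasso -> EBIC pipeline per resample, and report percentile
  (2.5/97.5) confidence intervals for every edge weight.
* **Centrality stability** — the case-dropping bootstrap: re-estimate on
  subject subsets of decreasing size and report the correlation-stability
  (CS) coefficient, the largest drop proportion at which the centrality
  still correlates >= 0.7 with the full-sample values in >= 95% of
  resamples.  CS >= 0.5 is considered good, >= 0.25 minimally acceptable.
* **Difference tests** — percentile bootstrap CIs of pairwise differences
  between edge weights or node centralities; a pair differs significantly
  when the (alpha/2, 1-alpha/2) interval excludes zero.  No multiplicity
  correction is applied, matching standard practice for these descriptive
  tests.

Per-replicate seeds are derived from the master seed by replicate index, so
results are identical regardless of worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .association import nearest_positive_semidefinite, spearman_matrix
from .centrality import bridge_expected_influence, expected_influence
from .instruments import DegenerateDataError, ItemResponseMatrix
from .network import EstimationError, SymptomNetwork, estimate_network

logger = logging.getLogger(__name__)

__all__ = [
    "BootConfig",
    "EdgeCIReport",
    "CSReport",
    "DifferenceTestMatrix",
    "StabilityError",
    "estimate_from_responses",
    "bootstrap_edges",
    "cs_coefficient",
    "difference_tests",
    "DEFAULT_DROP_PROPORTIONS",
]

DEFAULT_DROP_PROPORTIONS = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))

METRICS = {
    "expected_influence": expected_influence,
    "bridge_expected_influence": bridge_expected_influence,
}


class StabilityError(RuntimeError):
    """Too many bootstrap resamples failed to produce an estimate."""


@dataclass
class BootConfig:
    """Settings shared by the resampling procedures.

    ``nboots`` applies to both the edge bootstrap and each case-dropping
    proportion.  ``n_lambdas``/``lambda_min_ratio``/``gamma`` configure the
    re-estimation inside every replicate.  ``n_jobs`` only distributes
    work; results are independent of it.
    """

    nboots: int = 2000
    seed: int = 0
    gamma: float = 0.5
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    alpha: float = 0.05
    drop_proportions: tuple[float, ...] = DEFAULT_DROP_PROPORTIONS
    cs_threshold: float = 0.7
    cs_confidence: float = 0.95
    max_failure_rate: float = 0.10
    n_jobs: int = 1


def estimate_from_responses(
    responses: ItemResponseMatrix, config: BootConfig
) -> SymptomNetwork:
    """Full pipeline on one response matrix: Spearman, PSD repair, EBIC-glasso."""
    corr = nearest_positive_semidefinite(spearman_matrix(responses))
    net, _ = estimate_network(
        corr,
        communities=responses.communities,
        gamma=config.gamma,
        n_lambdas=config.n_lambdas,
        lambda_min_ratio=config.lambda_min_ratio,
    )
    return net


def _subset(responses: ItemResponseMatrix, idx: np.ndarray) -> ItemResponseMatrix:
    return ItemResponseMatrix(
        subjects=[responses.subjects[i] for i in idx],
        items=list(responses.items),
        communities=dict(responses.communities),
        values=responses.values[idx],
        instruments=responses.instruments,
    )


def _replicate_seed(master: int, stage: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master, stage, index]))


@dataclass
class EdgeCIReport:
    """Percentile bootstrap CIs per edge, plus the raw replicate store."""

    pairs: list[tuple[str, str]]
    point: np.ndarray
    replicates: np.ndarray  # (n_successful, n_pairs) edge-weight draws
    nboots: int
    n_failed: int
    ci_level: float = 0.95
    method: str = "percentile"

    def to_frame(self) -> pd.DataFrame:
        lo_q = (1 - self.ci_level) / 2
        return pd.DataFrame(
            {
                "node_i": [a for a, _ in self.pairs],
                "node_j": [b for _, b in self.pairs],
                "weight": self.point,
                "boot_mean": self.replicates.mean(axis=0),
                "ci_lower": np.quantile(self.replicates, lo_q, axis=0),
                "ci_upper": np.quantile(self.replicates, 1 - lo_q, axis=0),
            }
        )


def _boot_edge_replicate(
    responses: ItemResponseMatrix, config: BootConfig, r: int
) -> np.ndarray | None:
    rng = _replicate_seed(config.seed, 2, r)
    idx = rng.integers(0, responses.n_subjects, responses.n_subjects)
    try:
        net = estimate_from_responses(_subset(responses, idx), config)
    except (DegenerateDataError, EstimationError) as exc:
        logger.debug("edge bootstrap replicate %d failed: %s", r, exc)
        return None
    iu = np.triu_indices(net.p, k=1)
    return net.W[iu]


def bootstrap_edges(
    responses: ItemResponseMatrix,
    config: BootConfig,
    net: SymptomNetwork | None = None,
) -> EdgeCIReport:
    """Nonparametric bootstrap of every edge weight.

    Each replicate resamples subjects with replacement (same n) and re-runs
    estimation from scratch.  Replicates that fail (e.g. a resample drew a
    constant item) are dropped and counted; more than
    ``config.max_failure_rate`` failures raises :class:`StabilityError`.
    """
    if net is None:
        net = estimate_from_responses(responses, config)
    iu, ju = np.triu_indices(net.p, k=1)
    pairs = [(net.labels[i], net.labels[j]) for i, j in zip(iu, ju)]

    rows = Parallel(n_jobs=config.n_jobs)(
        delayed(_boot_edge_replicate)(responses, config, r)
        for r in range(config.nboots)
    )
    ok = [w for w in rows if w is not None]
    n_failed = config.nboots - len(ok)
    if n_failed > config.max_failure_rate * config.nboots:
        raise StabilityError(
            f"{n_failed}/{config.nboots} bootstrap resamples failed"
        )
    return EdgeCIReport(
        pairs=pairs,
        point=net.W[iu, ju],
        replicates=np.vstack(ok),
        nboots=config.nboots,
        n_failed=n_failed,
        ci_level=1 - config.alpha,
    )


@dataclass
class CSReport:
    """Case-dropping bootstrap outcome for one centrality metric."""

    metric: str
    proportions: tuple[float, ...]
    correlations: dict[float, np.ndarray]
    cs: float
    threshold: float = 0.7
    confidence: float = 0.95

    def pass_rate(self, proportion: float) -> float:
        corr = self.correlations[proportion]
        return float(np.mean(corr >= self.threshold))

    def recompute_cs(
        self, threshold: float | None = None, confidence: float | None = None
    ) -> float:
        """CS under a different threshold/confidence, same replicate store."""
        thr = self.threshold if threshold is None else threshold
        conf = self.confidence if confidence is None else confidence
        cs = 0.0
        for prop in sorted(self.proportions):
            if np.mean(self.correlations[prop] >= thr) >= conf:
                cs = float(prop)
        return cs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "proportion": list(self.proportions),
                "mean_correlation": [
                    float(np.mean(self.correlations[p])) for p in self.proportions
                ],
                "pass_rate": [self.pass_rate(p) for p in self.proportions],
            }
        )


def _cs_replicate(
    responses: ItemResponseMatrix,
    config: BootConfig,
    metric_fn,
    full_values: np.ndarray,
    prop_index: int,
    n_keep: int,
    r: int,
) -> float | None:
    rng = _replicate_seed(config.seed, 31 + prop_index, r)
    idx = rng.choice(responses.n_subjects, size=n_keep, replace=False)
    try:
        net = estimate_from_responses(_subset(responses, np.sort(idx)), config)
    except (DegenerateDataError, EstimationError):
        return None
    vals = metric_fn(net).to_numpy()
    if np.std(vals) == 0 or np.std(full_values) == 0:
        return None
    return float(np.corrcoef(full_values, vals)[0, 1])


def cs_coefficient(
    responses: ItemResponseMatrix,
    metric: str,
    config: BootConfig,
    net: SymptomNetwork | None = None,
) -> CSReport:
    """Correlation-stability coefficient of a centrality metric.

    For each drop proportion pi, ``config.nboots`` subsets of
    ``n - floor(pi n)`` subjects are drawn without replacement, the network
    is re-estimated, and the metric's Pearson correlation with the
    full-sample metric is recorded.  CS is the largest pi whose correlations
    reach ``cs_threshold`` in at least ``cs_confidence`` of resamples
    (0 when no proportion qualifies).
    """
    if metric not in METRICS:
        raise KeyError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    metric_fn = METRICS[metric]
    if net is None:
        net = estimate_from_responses(responses, config)
    full_values = metric_fn(net).to_numpy()
    if np.std(full_values) == 0:
        raise DegenerateDataError(
            f"{metric} is constant on the full sample; correlation undefined"
        )
    n = responses.n_subjects
    correlations: dict[float, np.ndarray] = {}
    for k, prop in enumerate(config.drop_proportions):
        n_keep = n - int(np.floor(prop * n))
        if n_keep < responses.n_items + 2:
            correlations[prop] = np.array([-np.inf])
            continue
        vals = Parallel(n_jobs=config.n_jobs)(
            delayed(_cs_replicate)(
                responses, config, metric_fn, full_values, k, n_keep, r
            )
            for r in range(config.nboots)
        )
        ok = np.array([v for v in vals if v is not None], dtype=float)
        correlations[prop] = ok if ok.size else np.array([-np.inf])

    report = CSReport(
        metric=metric,
        proportions=tuple(config.drop_proportions),
        correlations=correlations,
        cs=0.0,
        threshold=config.cs_threshold,
        confidence=config.cs_confidence,
    )
    report.cs = report.recompute_cs()
    return report


@dataclass
class DifferenceTestMatrix:
    """Pairwise bootstrapped difference tests at level alpha."""

    labels: list[str]
    significant: np.ndarray  # boolean, symmetric, False diagonal
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    alpha: float

    @property
    def n_significant_pairs(self) -> int:
        iu = np.triu_indices(len(self.labels), k=1)
        return int(self.significant[iu].sum())

    def significant_fraction(self, index: int) -> float:
        """Share of the other targets this target differs from significantly."""
        m = len(self.labels)
        row = np.delete(self.significant[index], index)
        return float(row.mean()) if m > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.significant, index=self.labels, columns=self.labels
        )


def difference_tests(
    replicates: np.ndarray,
    point: np.ndarray,
    labels: list[str],
    alpha: float = 0.05,
) -> DifferenceTestMatrix:
    """Percentile-CI tests of all pairwise differences among bootstrap targets.

    ``replicates`` is (n_boots, n_targets); a pair is significant when the
    (alpha/2, 1-alpha/2) quantile interval of its bootstrapped difference
    excludes zero.  The diagonal is never significant; the matrix is
    symmetric by construction.
    """
    replicates = np.asarray(replicates, float)
    if replicates.ndim != 2 or replicates.shape[1] != len(labels):
        raise ValueError("replicates must be (n_boots, n_targets)")
    if replicates.shape[0] < 2:
        raise ValueError("difference tests need a bootstrap replicate store")
    m = len(labels)
    lo_q, hi_q = alpha / 2, 1 - alpha / 2
    ci_lower = np.zeros((m, m))
    ci_upper = np.zeros((m, m))
    for i in range(m):
        diff = replicates - replicates[:, [i]]  # (n_boots, m): target_j - target_i
        ci_lower[i] = np.quantile(diff, lo_q, axis=0)
        ci_upper[i] = np.quantile(diff, hi_q, axis=0)
    significant = (ci_lower > 0) | (ci_upper < 0)
    significant = significant | significant.T  # enforce exact symmetry
    np.fill_diagonal(significant, False)
    return DifferenceTestMatrix(
        labels=list(labels),
        significant=significant,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        alpha=alpha,
    )


def metric_replicates(
    report: EdgeCIReport, labels: list[str], metric: str
) -> np.ndarray:
    """Per-replicate node centralities recovered from the edge-weight store."""
    if metric not in METRICS:
        raise KeyError(f"unknown metric {metric!r}")
    p = len(labels)
    iu, ju = np.triu_indices(p, k=1)
    out = np.zeros((report.replicates.shape[0], p))
    if metric == "expected_influence":
        for col, (i, j) in enumerate(zip(iu, ju)):
            out[:, i] += report.replicates[:, col]
            out[:, j] += report.replicates[:, col]
        return out
    raise ValueError(
        "bridge replicates need community labels; use metric_replicates_bridge"
    )


def metric_replicates_bridge(
    report: EdgeCIReport, labels: list[str], communities: dict[str, str]
) -> np.ndarray:
    """Per-replicate bridge expected influence from the edge-weight store."""
    p = len(labels)
    comm = [communities[l] for l in labels]
    iu, ju = np.triu_indices(p, k=1)
    out = np.zeros((report.replicates.shape[0], p))
    for col, (i, j) in enumerate(zip(iu, ju)):
        if comm[i] != comm[j]:
            out[:, i] += report.replicates[:, col]
            out[:, j] += report.replicates[:, col]
    return out
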
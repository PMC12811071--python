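"""Frequency-proportional bootstrap replication of interaction networks.

Each replica redraws ``n_events`` interaction events with replacement, cell by
cell, with probability proportional to the recorded event counts w_ij / sum w
(a multinomial over cells, equivalent to resampling individual events).  By
default ``n_events`` equals the source network's total, so replica totals are
conserved exactly; passing another value reproduces the sampled-interaction
sensitivity sweep.

Replicas may lose nodes whose cells were never drawn; metrics therefore see
only realized nodes, matching the phase diagnostics.  A metric that raises on
a degenerate replica is recorded as missing (never silently dropped) with a
logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .net_io import BipartiteNetwork, ValidationError

__all__ = ["BootstrapResult", "resample_network", "bootstrap_metrics"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapResult:
    """Per-replica metric values plus mean/SD/percentile summaries."""

    replicas: pd.DataFrame  # columns: replica, metric, value
    summary: pd.DataFrame  # index metric; mean, sd, q025, q975, n_missing
    n_replicas: int
    n_events: int
    seed: int

    def mean(self, metric: str) -> float:
        return float(self.summary.loc[metric, "mean"])

    def sd(self, metric: str) -> float:
        return float(self.summary.loc[metric, "sd"])


def resample_network(
    net: BipartiteNetwork, n_events: int | None = None, rng: np.random.Generator | None = None
) -> BipartiteNetwork:
    """One bootstrap replica: multinomial redraw of cells proportional to w_ij."""
    if rng is None:
        rng = np.random.default_rng()
    total = net.total_events
    if total < 1:
        raise ValidationError("cannot resample a network without events")
    if n_events is None:
        n_events = total
    if n_events < 1:
        raise ValidationError("n_events must be >= 1")
    probs = net.weights.ravel() / total
    counts = rng.multinomial(n_events, probs).reshape(net.weights.shape)
    return BipartiteNetwork(net.plant_ids, net.herbivore_ids, counts, season=net.season)


def bootstrap_metrics(
    net: BipartiteNetwork,
    metrics: Mapping[str, Callable[[BipartiteNetwork], float]],
    n_replicas: int = 10_000,
    n_events: int | None = None,
    seed: int = 0,
) -> BootstrapResult:
    """Apply pure network metrics to bootstrap replicas and summarize.

    One master seed spawns an independent substream per replica, so replica r
    is reproducible regardless of execution order or how many replicas run.
    """
    if n_replicas < 1:
        raise ValidationError("n_replicas must be >= 1")
    if n_events is None:
        n_events = net.total_events
    streams = np.random.SeedSequence(seed).spawn(n_replicas)
    names = list(metrics)
    values = np.empty((n_replicas, len(names)))
    for r, ss in enumerate(streams):
        replica = resample_network(net, n_events=n_events, rng=np.random.default_rng(ss))
        for j, name in enumerate(names):
            try:
                values[r, j] = metrics[name](replica)
            except Exception as exc:  # degenerate replica for this metric
                logger.warning("replica %d: metric %s undefined (%s)", r, name, exc)
                values[r, j] = np.nan
    replicas = pd.DataFrame(values, columns=names)
    replicas.insert(0, "replica", np.arange(n_replicas))
    tidy = replicas.melt(id_vars="replica", var_name="metric", value_name="value")
    import warnings as _warnings

    with _warnings.catch_warnings():
        # all-missing metrics legitimately summarize to NaN
        _warnings.simplefilter("ignore", RuntimeWarning)
        summary = pd.DataFrame(
            {
                "mean": np.nanmean(values, axis=0),
                "sd": np.nanstd(values, axis=0, ddof=1) if n_replicas > 1 else 0.0,
                "q025": np.nanpercentile(values, 2.5, axis=0),
                "q975": np.nanpercentile(values, 97.5, axis=0),
                "n_missing": np.isnan(values).sum(axis=0),
            },
            index=pd.Index(names, name="metric"),
        )
    return BootstrapResult(
        replicas=tidy, summary=summary, n_replicas=n_replicas, n_events=n_events, seed=seed
    )
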
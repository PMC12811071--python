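"""Full-study orchestration: phase diagnostics, bootstrap CIs, pathways, SEM.

``run_study`` takes the per-season networks plus the plant covariate table and
produces a machine-readable report:

* per season — phase summary and indirect-pathway contribution U of the
  empirical network, plus bootstrap mean/SD/percentile summaries of
  {n_components, frac_largest, C, U} across replicas;
* cross-season — the fold change of mean U (dry / rainy);
* the fitted path model (standardized coefficients, d-separation claims,
  Fisher's C, pseudo-R^2);
* an optional sensitivity grid re-running the bootstrap at alternative
  sampled-event counts;
* provenance (seed, configuration, package version).

One master seed governs every stochastic stage, so a rerun with the same
inputs and seed yields a byte-identical JSON report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import BootstrapResult, bootstrap_metrics
from .net_io import BipartiteNetwork, ValidationError
from .pathways import total_effects_analysis
from .phase import (
    connectivity_parameter,
    components,
    degree_distributions,
    interaction_probabilities,
    phase_summary,
)
from .sem import default_path_model, fit_path_model

__all__ = [
    "StudyConfig",
    "StudyReport",
    "phase_metric_suite",
    "attach_interaction_stats",
    "run_study",
    "fold_change_U",
    "save_report",
]

logger = logging.getLogger(__name__)

BOOTSTRAP_METRICS = ("n_components", "frac_largest", "C", "U")


@dataclass(frozen=True)
class StudyConfig:
    """Knobs of the full pipeline (spec file keys match these fields)."""

    replicas: int = 10_000
    events: int | list[int] | None = None  # None = each network's own total
    alpha_rule: str = "inverse_shifted"
    include_isolated: bool = False
    r2: str = "nagelkerke"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class StudyReport:
    """Bundle of the report dict plus the tidy per-replica tables."""

    report: dict
    bootstrap_replicas: pd.DataFrame
    coefficients: pd.DataFrame
    claims: pd.DataFrame


def phase_metric_suite(alpha_rule: str = "inverse_shifted", include_isolated: bool = False):
    """The four bootstrap metrics as pure functions of a network."""
    return {
        "n_components": lambda net: components(net, include_isolated)[0],
        "frac_largest": lambda net: components(net, include_isolated)[2],
        "C": lambda net: connectivity_parameter(degree_distributions(net)),
        "U": lambda net: total_effects_analysis(
            net, alpha_rule=alpha_rule, include_isolated=include_isolated
        ).U,
    }


def attach_interaction_stats(
    covariates: pd.DataFrame, networks: dict[str, BipartiteNetwork]
) -> pd.DataFrame:
    """Merge per-plant p_i and event counts (successes/trials) into the covariates.

    Plants present in the covariates but absent from their season's network
    get zero events; trials is the season's grand total, matching the
    events/trials binomial parameterization of the p_i path.
    """
    out = covariates.copy()
    out["p_i"] = 0.0
    out["p_i_successes"] = 0
    out["p_i_trials"] = 0
    for season, net in networks.items():
        mask = out["season"] == season
        p = interaction_probabilities(net)
        events = pd.Series(net.weights.sum(axis=1), index=list(net.plant_ids))
        ids = out.loc[mask, "plant_id"]
        out.loc[mask, "p_i"] = p.reindex(ids).fillna(0.0).to_numpy()
        out.loc[mask, "p_i_successes"] = events.reindex(ids).fillna(0).to_numpy(dtype=int)
        out.loc[mask, "p_i_trials"] = net.total_events
    return out


def _season_order(seasons: list[str]) -> list[str]:
    if set(seasons) == {"rainy", "dry"}:
        return ["rainy", "dry"]
    return sorted(seasons)


def fold_change_U(report: dict) -> float:
    """Mean-U fold change between the two seasons (later / earlier, dry / rainy)."""
    seasons = _season_order(list(report["seasons"]))
    if len(seasons) != 2:
        raise ValidationError("fold change requires exactly two seasons")
    base = report["seasons"][seasons[0]]["bootstrap"]["U"]["mean"]
    top = report["seasons"][seasons[1]]["bootstrap"]["U"]["mean"]
    if base == 0:
        raise ValidationError("fold change undefined: baseline mean U is zero")
    return float(top / base)


def _bootstrap_block(result: BootstrapResult) -> dict:
    block = {}
    for metric in result.summary.index:
        row = result.summary.loc[metric]
        block[metric] = {
            "mean": float(row["mean"]),
            "sd": float(row["sd"]),
            "q025": float(row["q025"]),
            "q975": float(row["q975"]),
            "n_missing": int(row["n_missing"]),
        }
    return block


def run_study(
    networks: dict[str, BipartiteNetwork],
    covariates: pd.DataFrame,
    config: StudyConfig | None = None,
    path_model=None,
) -> StudyReport:
    """Run the complete analysis; deterministic given ``config.seed``."""
    if config is None:
        config = StudyConfig()
    if not networks:
        raise ValidationError("no networks supplied")
    metrics = phase_metric_suite(config.alpha_rule, config.include_isolated)
    seasons = _season_order(list(networks))
    events_grid = config.events if isinstance(config.events, list) else None
    base_events = config.events if isinstance(config.events, int) else None

    # one deterministic sub-seed per (stage, season, events) slot
    seed_root = np.random.SeedSequence(config.seed)
    season_seeds = {s: int(ss.generate_state(1)[0] >> 1) for s, ss in zip(seasons, seed_root.spawn(len(seasons)))}

    report: dict = {
        "seasons": {},
        "provenance": {
            "seed": config.seed,
            "config": config.to_dict(),
            "herbnet_version": __version__,
        },
    }
    replica_tables = []
    for season in seasons:
        net = networks[season]
        logger.info("season %s: phase diagnostics on %d events", season, net.total_events)
        summary = phase_summary(net, include_isolated=config.include_isolated)
        te = total_effects_analysis(
            net, alpha_rule=config.alpha_rule, include_isolated=config.include_isolated
        )
        logger.info("season %s: bootstrap (%d replicas)", season, config.replicas)
        boot = bootstrap_metrics(
            net,
            metrics,
            n_replicas=config.replicas,
            n_events=base_events,
            seed=season_seeds[season],
        )
        tidy = boot.replicas.copy()
        tidy.insert(0, "season", season)
        replica_tables.append(tidy)
        report["seasons"][season] = {
            "empirical": {**summary.to_dict(), "U": te.U, "lambda": te.lam, "alpha": te.alpha,
                          "total_events": net.total_events},
            "bootstrap": _bootstrap_block(boot),
            "n_replicas": boot.n_replicas,
            "n_events": boot.n_events,
            "bootstrap_seed": boot.seed,
        }

    if len(seasons) == 2:
        report["fold_change_U"] = fold_change_U(report)

    # sensitivity sweep over the number of sampled interactions
    if events_grid:
        grid: dict = {}
        for n_events in events_grid:
            grid[str(n_events)] = {}
            for season in seasons:
                boot = bootstrap_metrics(
                    networks[season],
                    metrics,
                    n_replicas=config.replicas,
                    n_events=int(n_events),
                    seed=season_seeds[season] + int(n_events),
                )
                grid[str(n_events)][season] = _bootstrap_block(boot)
        report["sensitivity"] = grid

    # path model on covariates + interaction probabilities
    logger.info("fitting path model")
    data = attach_interaction_stats(covariates, networks)
    spec = path_model if path_model is not None else default_path_model()
    fit = fit_path_model(spec, data, r2=config.r2)
    report["path_model"] = {
        "fishers_C": fit.fishers_C,
        "df": fit.df,
        "p_value": fit.p_value,
        "pseudo_r2": fit.pseudo_r2,
        "coefficients": fit.coefficients.to_dict(orient="records"),
        "claims": fit.claims.to_dict(orient="records"),
    }

    replicas = pd.concat(replica_tables, ignore_index=True)
    return StudyReport(
        report=report,
        bootstrap_replicas=replicas,
        coefficients=fit.coefficients,
        claims=fit.claims,
    )


def save_report(study: StudyReport, out_dir) -> Path:
    """Write report.json plus tidy CSVs; returns the report path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    path.write_text(json.dumps(study.report, indent=2, sort_keys=True) + "\n")
    study.bootstrap_replicas.to_csv(out / "bootstrap_replicas.csv", index=False)
    study.coefficients.to_csv(out / "path_coefficients.csv", index=False)
    study.claims.to_csv(out / "dsep_claims.csv", index=False)
    return path
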
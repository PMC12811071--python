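"""Piecewise path model: per-path GLMs, standardized coefficients and d-separation.

A path model is a DAG over named plant-level variables.  Each endogenous
variable is fitted by its own regression on its parents — ordinary least
squares for Gaussian responses, a binomial GLM (events/trials) for interaction
probabilities.  Goodness of fit uses direct-separation tests: for every
non-adjacent variable pair the implied conditional independence is tested by
adding the partner to the appropriate regression, and the claim p-values are
aggregated into Fisher's

    C = -2 sum_k ln p_k        ~  chi-square with 2k df under the model.

Coefficients are reported as standardized estimates; binomial coefficients are
standardized on the latent (logit) scale using sd_y = sqrt(var(eta) + pi^2/3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .net_io import ValidationError

__all__ = [
    "PathModelSpec",
    "PathModelFit",
    "default_path_model",
    "encode_season",
    "fit_paths",
    "standardize",
    "indirect_effect",
    "dsep_test",
    "pseudo_r2",
    "fit_path_model",
]

_LATENT_LOGIT_VAR = math.pi**2 / 3.0


@dataclass(frozen=True)
class PathModelSpec:
    """DAG of directed paths plus the error family of each response.

    ``families`` maps a response variable to ``"gaussian"`` (default) or
    ``"binomial"``.  A binomial response ``v`` is fitted from companion
    columns ``{v}_successes`` and ``{v}_trials`` in the data; its plain column
    (the proportion) is used when it appears as a predictor.
    """

    edges: tuple[tuple[str, str], ...]
    families: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("path model must be acyclic")
        bad = {f for f in self.families.values()} - {"gaussian", "binomial"}
        if bad:
            raise ValidationError(f"unknown families: {sorted(bad)}")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(self.edges)
        return g

    @property
    def variables(self) -> tuple[str, ...]:
        seen: list[str] = []
        for a, b in self.edges:
            for v in (a, b):
                if v not in seen:
                    seen.append(v)
        return tuple(seen)

    def parents(self, v: str) -> tuple[str, ...]:
        return tuple(sorted(a for a, b in self.edges if b == v))

    @property
    def endogenous(self) -> tuple[str, ...]:
        return tuple(v for v in self.variables if self.parents(v))

    def family(self, v: str) -> str:
        return self.families.get(v, "gaussian")


def default_path_model() -> PathModelSpec:
    """The seasonality / phytochemical-diversity path model.

    Season shifts compositional PD; season and both PD dimensions drive the
    plants' interaction probabilities p_i (binomial); both PD dimensions drive
    herbivory.
    """
    return PathModelSpec(
        edges=(
            ("season", "compositional_pd"),
            ("season", "p_i"),
            ("compositional_pd", "p_i"),
            ("structural_pd", "p_i"),
            ("compositional_pd", "herbivory"),
            ("structural_pd", "herbivory"),
        ),
        families={"p_i": "binomial"},
    )


def encode_season(data: pd.DataFrame, column: str = "season") -> pd.DataFrame:
    """Return a copy with a two-level season column coded 0/1 (dry = 1).

    Non-{rainy, dry} labels are coded in sorted order (second level = 1);
    numeric columns pass through unchanged.
    """
    if column not in data.columns or pd.api.types.is_numeric_dtype(data[column]):
        return data
    out = data.copy()
    levels = sorted(out[column].astype(str).unique())
    if len(levels) > 2:
        raise ValidationError(f"{column} must have at most two levels, got {levels}")
    if set(levels) == {"rainy", "dry"}:
        one = "dry"
    else:
        one = levels[-1]
    out[column] = (out[column].astype(str) == one).astype(float)
    return out


def _design(data: pd.DataFrame, predictors: tuple[str, ...]) -> pd.DataFrame:
    X = data.loc[:, list(predictors)].astype(float)
    return sm.add_constant(X, has_constant="add")


def _fit_one(
    response: str, predictors: tuple[str, ...], family: str, data: pd.DataFrame
):
    X = _design(data, predictors)
    if np.any(X.iloc[:, 1:].std(axis=0) == 0):
        zero = [c for c in X.columns[1:] if X[c].std() == 0]
        raise ValidationError(f"singular design for {response}: constant predictor(s) {zero}")
    if family == "binomial":
        succ = data[f"{response}_successes"].to_numpy(dtype=float)
        trials = data[f"{response}_trials"].to_numpy(dtype=float)
        endog = np.column_stack([succ, trials - succ])
        return sm.GLM(endog, X, family=sm.families.Binomial()).fit()
    return sm.OLS(data[response].astype(float), X).fit()


def fit_paths(spec: PathModelSpec, data: pd.DataFrame) -> dict[str, object]:
    """One regression per endogenous variable on its DAG parents."""
    data = encode_season(data)
    fits = {}
    for resp in spec.endogenous:
        try:
            fits[resp] = _fit_one(resp, spec.parents(resp), spec.family(resp), data)
        except ValidationError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise ValidationError(f"fit failed for response {resp!r}: {exc}") from exc
    return fits


def standardize(spec: PathModelSpec, fits: Mapping[str, object], data: pd.DataFrame) -> pd.DataFrame:
    """Standardized coefficient table (response, predictor, estimate, std_estimate, p).

    Gaussian: beta_std = b * sd(x) / sd(y).  Binomial: latent-scale
    standardization with sd(y) = sqrt(var(linear predictor) + pi^2/3).
    Zero-variance predictors yield missing standardized estimates.
    """
    data = encode_season(data)
    rows = []
    for resp, res in fits.items():
        family = spec.family(resp)
        if family == "binomial":
            eta = np.asarray(res.predict(which="linear"))
            sd_y = math.sqrt(float(np.var(eta, ddof=1)) + _LATENT_LOGIT_VAR)
        else:
            sd_y = float(data[resp].astype(float).std(ddof=1))
        for pred in spec.parents(resp):
            b = float(res.params[pred])
            sd_x = float(data[pred].astype(float).std(ddof=1))
            std = b * sd_x / sd_y if sd_x > 0 and sd_y > 0 else np.nan
            rows.append(
                {
                    "response": resp,
                    "predictor": pred,
                    "estimate": b,
                    "se": float(res.bse[pred]),
                    "p_value": float(res.pvalues[pred]),
                    "std_estimate": std,
                }
            )
    return pd.DataFrame(rows)


def indirect_effect(coefficients: pd.DataFrame, path: list[tuple[str, str]]) -> float:
    """Product of standardized coefficients along a directed path."""
    if not path:
        raise ValidationError("empty path")
    for (a, b), (c, _) in zip(path, path[1:]):
        if b != c:
            raise ValidationError(f"edges do not chain: {a}->{b} then {c}->...")
    effect = 1.0
    for a, b in path:
        match = coefficients[
            (coefficients["response"] == b) & (coefficients["predictor"] == a)
        ]
        if match.empty:
            raise ValidationError(f"edge {a}->{b} not in the fitted model")
        effect *= float(match["std_estimate"].iloc[0])
    return effect


def _basis_set(spec: PathModelSpec) -> list[tuple[str, str, tuple[str, ...]]]:
    """Shipley basis set: (response, tested predictor, conditioning set) per claim.

    Claims are the non-adjacent unordered pairs with at least one endogenous
    member, conditioned on the union of both variables' parents.  The tested
    regression's response is the pair member later in topological order,
    except that a Gaussian response is preferred over a binomial one when the
    order does not force the choice (neither is an ancestor of the other).
    """
    g = spec.graph()
    order = {v: i for i, v in enumerate(nx.lexicographical_topological_sort(g))}
    adjacent = {frozenset(e) for e in spec.edges}
    exog = set(spec.variables) - set(spec.endogenous)
    claims = []
    variables = sorted(spec.variables, key=order.get)
    for i, u in enumerate(variables):
        for v in variables[i + 1 :]:
            if frozenset((u, v)) in adjacent:
                continue
            if u in exog and v in exog:
                continue
            first, second = u, v  # topological order
            if (
                not nx.has_path(g, first, second)
                and spec.family(second) == "binomial"
                and spec.family(first) == "gaussian"
                and first not in exog
            ):
                first, second = second, first
            cond = tuple(sorted((set(spec.parents(u)) | set(spec.parents(v))) - {u, v}))
            claims.append((second, first, cond))
    return claims


def dsep_test(spec: PathModelSpec, data: pd.DataFrame) -> dict:
    """Direct-separation goodness of fit: claim p-values and Fisher's C.

    Each claim of conditional independence is tested by regressing the claim's
    response on its conditioning set plus the partner variable (with the
    response's family) and reading the partner's Wald p-value.
    """
    data = encode_season(data)
    claims = _basis_set(spec)
    rows = []
    for resp, other, cond in claims:
        res = _fit_one(resp, tuple(cond) + (other,), spec.family(resp), data)
        p = float(res.pvalues[other])
        rows.append(
            {
                "response": resp,
                "predictor": other,
                "conditioning": ",".join(cond),
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    k = len(rows)
    if k == 0:
        return {"claims": table, "fishers_C": 0.0, "df": 0, "p_value": 1.0}
    pvals = np.clip(table["p_value"].to_numpy(), 1e-300, 1.0)
    C = float(-2.0 * np.log(pvals).sum())
    df = 2 * k
    return {"claims": table, "fishers_C": C, "df": df, "p_value": float(chi2.sf(C, df))}


def pseudo_r2(res, method: str = "nagelkerke") -> float:
    """Pseudo-R^2 of a fitted binomial GLM (Nagelkerke default, McFadden optional)."""
    llf = float(res.llf)
    llnull = float(res.llnull)
    n = float(res.nobs)
    if method == "mcfadden":
        return 1.0 - llf / llnull if llnull != 0 else 0.0
    if method == "nagelkerke":
        cox_snell = 1.0 - math.exp((llnull - llf) * 2.0 / n)
        denom = 1.0 - math.exp(llnull * 2.0 / n)
        return cox_snell / denom if denom > 0 else 0.0
    raise ValueError(f"unknown pseudo-R2 method {method!r}")


@dataclass(frozen=True)
class PathModelFit:
    """Fitted piecewise path model: coefficients, d-separation fit, pseudo-R^2."""

    spec: PathModelSpec
    coefficients: pd.DataFrame
    claims: pd.DataFrame
    fishers_C: float
    df: int
    p_value: float
    pseudo_r2: dict[str, float]
    models: dict[str, object]

    def std_estimate(self, source: str, target: str) -> float:
        match = self.coefficients[
            (self.coefficients["response"] == target)
            & (self.coefficients["predictor"] == source)
        ]
        if match.empty:
            raise KeyError(f"no fitted path {source}->{target}")
        return float(match["std_estimate"].iloc[0])

    def indirect_effect(self, path: list[tuple[str, str]]) -> float:
        return indirect_effect(self.coefficients, path)


def fit_path_model(
    spec: PathModelSpec | None = None, data: pd.DataFrame = None, r2: str = "nagelkerke"
) -> PathModelFit:
    """Fit paths, standardize, run d-separation and compute pseudo-R^2."""
    if spec is None:
        spec = default_path_model()
    data = encode_season(data)
    fits = fit_paths(spec, data)
    coefficients = standardize(spec, fits, data)
    dsep = dsep_test(spec, data)
    r2s = {
        resp: pseudo_r2(res, method=r2)
        for resp, res in fits.items()
        if spec.family(resp) == "binomial"
    }
    return PathModelFit(
        spec=spec,
        coefficients=coefficients,
        claims=dsep["claims"],
        fishers_C=dsep["fishers_C"],
        df=dsep["df"],
        p_value=dsep["p_value"],
        pseudo_r2=r2s,
        models=fits,
    )
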
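"""Two-season synthetic plant-herbivore datasets with known causal structure.

The generator emulates the study conditions the analysis assumes: two
independent samples of plant individuals (one per season) interacting with a
shared pool of herbivore species.  The rainy season has few events spread
evenly across herbivore species; the dry season has many events concentrated
on a couple of dominant species.  Per-plant phytochemical-diversity (PD)
covariates are tied to interaction probabilities and herbivory through a known
path model, so downstream inference can be validated against ground truth.

Generation for one season:

1. herbivore relative abundances ~ symmetric Dirichlet(skew); small skew
   concentrates events on a few dominant species,
2. per-plant compositional/structural PD ~ Gaussian; the compositional mean
   shifts with season via ``season->compositional_pd``,
3. each plant draws a herbivore-preference profile from a Dirichlet centred
   on the season's abundances (within-plant clustering: the events on one
   plant tend to be the same species, as caterpillar broods are), then each
   of the season's events lands independently in a (plant, herbivore) cell
   with probability softmax(attractiveness)_plant x preference_plant,herbivore,
   attractiveness being the linear predictor over standardized PD and season,
4. herbivory = linear function of structural PD plus noise, clipped to
   [0, 100].

Event totals are conserved exactly (multinomial allocation).  Note that an
additive season term in the attractiveness is absorbed by the within-season
softmax; see docs for what the fitted season->p_i path then measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .net_io import BipartiteNetwork, ValidationError

__all__ = ["SyntheticConfig", "StudyData", "generate_season", "generate_paired_study"]

#: ground-truth path coefficients, on the standardized (z / latent) scale
DEFAULT_PATH_COEFFICIENTS = {
    "season->compositional_pd": 1.2,
    "compositional_pd->attractiveness": 0.6,
    "structural_pd->attractiveness": -0.5,
    "season->attractiveness": -0.4,
    "structural_pd->herbivory": -0.6,
}

#: residual scale per response, on the same standardized scale
DEFAULT_NOISE_SD = {"compositional_pd": 1.0, "herbivory": 1.0}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the paired-season generator.

    Defaults mirror the field setting: 62 plants and 18 herbivore species per
    season; 29 rainy-season events spread evenly (`herbivore_skew` large) and
    244 dry-season events skewed onto two dominant species (`herbivore_skew`
    small).  ``path_coefficients`` are standardized-scale effects; PD means/
    scales place the entropies in a realistic range of nats.
    """

    n_plants: int = 62
    n_herbivores: int = 18
    rainy_total_events: int = 29
    dry_total_events: int = 244
    herbivore_skew: Mapping[str, float] = field(
        default_factory=lambda: {"rainy": 50.0, "dry": 0.12}
    )
    path_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATH_COEFFICIENTS)
    )
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    within_plant_clustering: float = 0.1
    comp_pd_mean: float = 2.0
    comp_pd_scale: float = 0.4
    struct_pd_mean: float = 2.5
    struct_pd_scale: float = 0.35
    herbivory_mean: float = 30.0
    herbivory_scale: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_plants, self.n_herbivores) < 1:
            raise ValidationError("node counts must be positive")
        if min(self.rainy_total_events, self.dry_total_events) < 1:
            raise ValidationError("season event totals must be positive")
        if any(s <= 0 for s in self.herbivore_skew.values()):
            raise ValidationError("herbivore_skew concentrations must be positive")
        if self.within_plant_clustering <= 0:
            raise ValidationError("within_plant_clustering must be positive")
        unknown = set(self.path_coefficients) - set(DEFAULT_PATH_COEFFICIENTS)
        if unknown:
            raise ValidationError(f"unknown path coefficients: {sorted(unknown)}")

    def total_events(self, season: str) -> int:
        return self.rainy_total_events if season == "rainy" else self.dry_total_events

    def to_dict(self) -> dict:
        d = asdict(self)
        d["herbivore_skew"] = dict(self.herbivore_skew)
        d["path_coefficients"] = dict(self.path_coefficients)
        d["noise_sd"] = dict(self.noise_sd)
        return d


@dataclass(frozen=True)
class StudyData:
    """A paired two-season synthetic dataset."""

    networks: dict[str, BipartiteNetwork]
    covariates: pd.DataFrame
    config: SyntheticConfig


def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - x.max())
    return z / z.sum()


def generate_season(
    config: SyntheticConfig, season: str, rng: np.random.Generator
) -> tuple[BipartiteNetwork, pd.DataFrame]:
    """Generate one season's network and covariate table.

    ``season`` should be ``"rainy"`` or ``"dry"`` (any tag present in
    ``config.herbivore_skew`` works; the dry indicator is ``season == "dry"``).
    """
    if season not in config.herbivore_skew:
        raise ValidationError(f"no herbivore_skew configured for season {season!r}")
    total = config.total_events(season)
    if total < 1:
        raise ValidationError("season event total must be >= 1")
    beta = {**DEFAULT_PATH_COEFFICIENTS, **config.path_coefficients}
    noise = {**DEFAULT_NOISE_SD, **config.noise_sd}
    dry = 1.0 if season == "dry" else 0.0
    n_p, n_h = config.n_plants, config.n_herbivores

    # (1) herbivore species relative abundances
    abundance = rng.dirichlet(np.full(n_h, config.herbivore_skew[season]))

    # (2) plant covariates on the standardized latent scale
    comp_z = beta["season->compositional_pd"] * dry + noise["compositional_pd"] * rng.standard_normal(n_p)
    struct_z = rng.standard_normal(n_p)
    compositional_pd = config.comp_pd_mean + config.comp_pd_scale * comp_z
    structural_pd = config.struct_pd_mean + config.struct_pd_scale * struct_z

    # (3) event allocation: softmax attractiveness x within-plant preferences.
    # Each plant's preference profile is Dirichlet-centred on the species
    # abundances (E[pref] = abundance), with a small concentration so the
    # events on one plant cluster on few species, as clutch-laying herbivores
    # do; the softmax fixes each plant's share of events.
    attractiveness = (
        beta["compositional_pd->attractiveness"] * comp_z
        + beta["structural_pd->attractiveness"] * struct_z
        + beta["season->attractiveness"] * dry
    )
    pref_alpha = np.maximum(config.within_plant_clustering * n_h * abundance, 1e-9)
    with np.errstate(invalid="ignore", divide="ignore"):
        preferences = rng.dirichlet(pref_alpha, size=n_p)
    bad = ~np.isfinite(preferences).all(axis=1)
    if bad.any():  # all-underflow row: fall back to the season's mean profile
        preferences[bad] = abundance
    cell_probs = _softmax(attractiveness)[:, None] * preferences
    counts = rng.multinomial(total, cell_probs.ravel()).reshape(n_p, n_h)

    # (4) herbivory from structural PD, clipped to the percentage scale
    herbivory = np.clip(
        config.herbivory_mean
        + config.herbivory_scale
        * (beta["structural_pd->herbivory"] * struct_z + noise["herbivory"] * rng.standard_normal(n_p)),
        0.0,
        100.0,
    )

    width = len(str(n_p))
    plant_ids = tuple(f"{season}_p{str(i + 1).zfill(width)}" for i in range(n_p))
    herb_ids = tuple(f"h{str(j + 1).zfill(2)}" for j in range(n_h))
    net = BipartiteNetwork(plant_ids, herb_ids, counts, season=season)
    covariates = pd.DataFrame(
        {
            "plant_id": plant_ids,
            "season": season,
            "compositional_pd": compositional_pd,
            "structural_pd": structural_pd,
            "herbivory": herbivory,
        }
    )
    return net, covariates


def generate_paired_study(config: SyntheticConfig | None = None) -> StudyData:
    """Generate the rainy + dry bundle with disjoint plant individuals.

    Seasons use independent plant samples (the field design resampled
    different individuals each season); herbivore species labels are shared.
    Fixing ``config.seed`` makes the output byte-identical across calls.
    """
    if config is None:
        config = SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    networks: dict[str, BipartiteNetwork] = {}
    tables = []
    for season in ("rainy", "dry"):
        net, cov = generate_season(config, season, rng)
        networks[season] = net
        tables.append(cov)
    covariates = pd.concat(tables, ignore_index=True)
    return StudyData(networks=networks, covariates=covariates, config=config)
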
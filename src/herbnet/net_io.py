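"""Data model and delimited-text I/O for weighted bipartite interaction networks.

The central object is :class:`BipartiteNetwork`: a plant-individual x
herbivore-species matrix of interaction *event counts* for one season.
Two text dialects are supported:

* ``long`` (canonical): CSV with columns ``plant_id,herbivore_id,count,season``.
  Zero-interaction nodes survive a round trip only if declared in an optional
  node-manifest file.
* ``wide``: a labelled incidence grid, first column ``plant_id``, remaining
  columns herbivore labels, one file per season.

Per-plant covariates (phytochemical diversity, herbivory, ...) travel in a
plain :class:`pandas.DataFrame` with a fixed column contract, see
:func:`read_covariates`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BipartiteNetwork",
    "FormatError",
    "ValidationError",
    "read_interactions",
    "write_interactions",
    "read_covariates",
    "write_covariates",
    "read_node_manifest",
]

LONG_COLUMNS = ("plant_id", "herbivore_id", "count", "season")
COVARIATE_COLUMNS = (
    "plant_id",
    "season",
    "compositional_pd",
    "structural_pd",
    "herbivory",
)


class FormatError(ValueError):
    """A file does not match the expected column layout."""


class ValidationError(ValueError):
    """Input values violate a domain invariant (negative counts, empty data...)."""


@dataclass(frozen=True)
class BipartiteNetwork:
    """Weighted bipartite plant x herbivore interaction network for one season.

    Parameters
    ----------
    plant_ids, herbivore_ids
        Unique node labels; stored sorted lexicographically so matrix indices
        are reproducible across runs.
    weights
        ``(n_plants, n_herbivores)`` matrix of nonnegative integer event
        counts, rows/columns aligned with the sorted labels.
    season
        Free-form season tag (e.g. ``"rainy"``, ``"dry"``).
    """

    plant_ids: tuple[str, ...]
    herbivore_ids: tuple[str, ...]
    weights: np.ndarray
    season: str = "all"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.ndim != 2 or w.shape != (len(self.plant_ids), len(self.herbivore_ids)):
            raise ValidationError(
                f"weights shape {w.shape} does not match "
                f"{len(self.plant_ids)} plants x {len(self.herbivore_ids)} herbivores"
            )
        if not np.issubdtype(w.dtype, np.integer):
            if not np.allclose(w, np.round(w)):
                raise ValidationError("interaction counts must be integer-valued")
            w = np.round(w).astype(np.int64)
        if (w < 0).any():
            raise ValidationError("interaction counts must be nonnegative")
        if w.sum() < 1:
            raise ValidationError("network must contain at least one interaction event")
        if len(set(self.plant_ids)) != len(self.plant_ids):
            raise ValidationError("duplicate plant labels")
        if len(set(self.herbivore_ids)) != len(self.herbivore_ids):
            raise ValidationError("duplicate herbivore labels")
        object.__setattr__(self, "weights", np.ascontiguousarray(w, dtype=np.int64))
        object.__setattr__(self, "plant_ids", tuple(self.plant_ids))
        object.__setattr__(self, "herbivore_ids", tuple(self.herbivore_ids))

    # -- basic shape -------------------------------------------------------
    @property
    def n_plants(self) -> int:
        return len(self.plant_ids)

    @property
    def n_herbivores(self) -> int:
        return len(self.herbivore_ids)

    @property
    def n_nodes(self) -> int:
        """Total node count N = N_plants + N_animals (including zero-degree nodes)."""
        return self.n_plants + self.n_herbivores

    @property
    def total_events(self) -> int:
        return int(self.weights.sum())

    def incidence(self) -> np.ndarray:
        """Binary incidence matrix B (1 where at least one event was recorded)."""
        return (self.weights > 0).astype(np.int64)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: "pd.DataFrame",
        season: str = "all",
        extra_plants: tuple[str, ...] = (),
        extra_herbivores: tuple[str, ...] = (),
    ) -> "BipartiteNetwork":
        """Build a network from a long table with plant_id/herbivore_id/count.

        Duplicate (plant, herbivore) rows are summed.  ``extra_*`` declare
        sampled-but-uninfested nodes (zero rows/columns).
        """
        plants = sorted(set(edges["plant_id"].astype(str)) | set(extra_plants))
        herbs = sorted(set(edges["herbivore_id"].astype(str)) | set(extra_herbivores))
        p_index = {p: i for i, p in enumerate(plants)}
        h_index = {h: j for j, h in enumerate(herbs)}
        w = np.zeros((len(plants), len(herbs)), dtype=np.int64)
        counts = pd.to_numeric(edges["count"])
        if (counts < 0).any():
            raise ValidationError("negative interaction counts")
        if not np.allclose(counts, np.round(counts)):
            raise ValidationError("non-integer interaction counts")
        for p, h, c in zip(edges["plant_id"].astype(str), edges["herbivore_id"].astype(str), counts):
            w[p_index[p], h_index[h]] += int(round(c))
        return cls(tuple(plants), tuple(herbs), w, season=season)

    def to_long(self) -> pd.DataFrame:
        """Long-format table of the nonzero cells (canonical dialect)."""
        rows, cols = np.nonzero(self.weights)
        return pd.DataFrame(
            {
                "plant_id": [self.plant_ids[i] for i in rows],
                "herbivore_id": [self.herbivore_ids[j] for j in cols],
                "count": self.weights[rows, cols],
                "season": self.season,
            }
        )

    def to_wide(self) -> pd.DataFrame:
        """Incidence-grid table: rows plants, columns herbivores, cells counts."""
        return pd.DataFrame(
            self.weights, index=list(self.plant_ids), columns=list(self.herbivore_ids)
        ).rename_axis("plant_id")


def read_node_manifest(path) -> pd.DataFrame:
    """Read a node manifest declaring sampled nodes (columns node_id, node_type[, season]).

    node_type is ``plant`` or ``herbivore``.  A ``season`` column restricts the
    declaration to one season; without it the node applies to every season.
    """
    man = pd.read_csv(path, dtype=str)
    required = {"node_id", "node_type"}
    if not required.issubset(man.columns):
        raise FormatError(f"node manifest must contain columns {sorted(required)}")
    bad = set(man["node_type"]) - {"plant", "herbivore"}
    if bad:
        raise ValidationError(f"unknown node_type values: {sorted(bad)}")
    return man


def _manifest_nodes(manifest: pd.DataFrame | None, season: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    if manifest is None:
        return (), ()
    m = manifest
    if "season" in m.columns:
        m = m[(m["season"].isna()) | (m["season"] == season)]
    plants = tuple(m.loc[m["node_type"] == "plant", "node_id"])
    herbs = tuple(m.loc[m["node_type"] == "herbivore", "node_id"])
    return plants, herbs


def read_interactions(
    path,
    dialect: str = "long",
    season: str | None = None,
    manifest=None,
) -> dict[str, BipartiteNetwork]:
    """Read interaction data, returning one network per season tag found.

    Parameters
    ----------
    dialect
        ``"long"`` (plant_id,herbivore_id,count,season CSV) or ``"wide"``
        (labelled incidence grid; the season comes from ``season``).
    season
        Season tag for the wide dialect (default ``"all"``).
    manifest
        Optional path to a node-manifest CSV declaring sampled nodes with
        zero interactions (see :func:`read_node_manifest`).
    """
    man = read_node_manifest(manifest) if manifest is not None else None
    if dialect == "long":
        df = pd.read_csv(path)
        missing = set(LONG_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"long-format file missing columns {sorted(missing)}")
        if df.empty:
            raise ValidationError("interaction file contains no data rows")
        out: dict[str, BipartiteNetwork] = {}
        for tag, group in df.groupby("season", sort=True):
            extra_p, extra_h = _manifest_nodes(man, str(tag))
            out[str(tag)] = BipartiteNetwork.from_edges(
                group, season=str(tag), extra_plants=extra_p, extra_herbivores=extra_h
            )
        return out
    if dialect == "wide":
        tag = season if season is not None else "all"
        df = pd.read_csv(path)
        if df.shape[1] < 2 or df.columns[0] != "plant_id":
            raise FormatError("wide-format file must start with a plant_id column")
        if df.empty:
            raise ValidationError("interaction file contains no data rows")
        df = df.set_index("plant_id")
        extra_p, extra_h = _manifest_nodes(man, tag)
        plants = sorted(set(df.index.astype(str)) | set(extra_p))
        herbs = sorted(set(df.columns.astype(str)) | set(extra_h))
        grid = df.reindex(index=plants, columns=herbs).fillna(0)
        values = grid.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValidationError("negative interaction counts")
        if not np.allclose(values, np.round(values)):
            raise ValidationError("non-integer interaction counts")
        return {tag: BipartiteNetwork(tuple(plants), tuple(herbs), values.astype(np.int64), season=tag)}
    raise ValueError(f"unknown dialect {dialect!r}")


def write_interactions(net: BipartiteNetwork, path, dialect: str = "long") -> None:
    """Write one network in the requested dialect.

    The long dialect lists only nonzero cells (zero-degree nodes need a node
    manifest to round-trip); the wide dialect preserves zero rows/columns.
    """
    if dialect == "long":
        net.to_long().to_csv(path, index=False)
    elif dialect == "wide":
        net.to_wide().to_csv(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_covariates(path) -> pd.DataFrame:
    """Read and validate the per-plant covariate table.

    Columns: plant_id, season, compositional_pd, structural_pd, herbivory.
    Entropies are in nats (>= 0); herbivory is percent leaf area lost in
    [0, 100].  plant_id must be unique within a season.
    """
    df = pd.read_csv(path)
    missing = set(COVARIATE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"covariate file missing columns {sorted(missing)}")
    return validate_covariates(df)


def validate_covariates(df: pd.DataFrame) -> pd.DataFrame:
    if df.duplicated(subset=["plant_id", "season"]).any():
        raise ValidationError("plant_id values must be unique within a season")
    herb = df["herbivory"].dropna()
    if ((herb < 0) | (herb > 100)).any():
        raise ValidationError("herbivory must lie in [0, 100]")
    for col in ("compositional_pd", "structural_pd"):
        vals = df[col].dropna()
        if (vals < 0).any():
            raise ValidationError(f"{col} entropies must be nonnegative")
    return df


def write_covariates(df: pd.DataFrame, path) -> None:
    validate_covariates(df)
    cols = [c for c in COVARIATE_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.loc[:, cols].to_csv(path, index=False)
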
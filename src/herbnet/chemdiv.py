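"""Phytochemical diversity (PD) as Shannon entropy of spectral intensity profiles.

Compositional PD is the entropy of a leaf's compound-level intensity profile
(e.g. processed LC-MS peak table); structural PD is the entropy of its
substructure-level profile (e.g. binned 1H-NMR spectrum).  Entropies are
reported in nats by default and aggregated from leaves to plants by the mean.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import entropy as _entropy

from .net_io import ValidationError

__all__ = ["shannon_entropy", "pd_profile", "CHANNELS"]

logger = logging.getLogger(__name__)

#: spectral channels mapped to covariate columns
CHANNELS = {"compositional": "compositional_pd", "structural": "structural_pd"}

_META_COLS = ("plant_id", "leaf_id", "channel")


def shannon_entropy(intensities, base: float | None = None) -> float:
    """Shannon entropy of a nonnegative intensity vector.

    Intensities are normalized to proportions; zero entries contribute
    nothing.  ``base=None`` gives nats; pass e.g. ``base=2`` for bits.
    Scaling all intensities by a constant leaves the result unchanged.
    """
    x = np.asarray(intensities, dtype=float)
    if x.ndim != 1:
        raise ValidationError("intensities must be a 1-D vector")
    if (x < 0).any():
        raise ValidationError("intensities must be nonnegative")
    if x.sum() <= 0:
        raise ValidationError("entropy undefined for an all-zero profile")
    return float(_entropy(x, base=base))


def pd_profile(
    table: pd.DataFrame, agg: str = "mean", base: float | None = None
) -> pd.DataFrame:
    """Per-plant compositional and structural PD from a leaf-level spectral table.

    ``table`` has one row per (plant_id, leaf_id, channel) sample and one
    column per spectral feature; ``channel`` is ``"compositional"`` or
    ``"structural"``.  Leaf entropies are aggregated to plant level by ``agg``
    (any named pandas aggregation; default mean).  A plant missing a channel
    yields a missing covariate with a logged warning.
    """
    missing = set(_META_COLS) - set(table.columns)
    if missing:
        raise ValidationError(f"spectral table missing columns {sorted(missing)}")
    bad = set(table["channel"]) - set(CHANNELS)
    if bad:
        raise ValidationError(f"unknown channels: {sorted(bad)}")
    feature_cols = [c for c in table.columns if c not in _META_COLS]
    if not feature_cols:
        raise ValidationError("spectral table has no feature columns")
    leaf_H = table[list(_META_COLS)].copy()
    leaf_H["H"] = [
        shannon_entropy(row, base=base) for row in table[feature_cols].to_numpy(dtype=float)
    ]
    per_plant = (
        leaf_H.groupby(["plant_id", "channel"])["H"].agg(agg).unstack("channel")
    )
    out = per_plant.rename(columns=CHANNELS).reindex(columns=list(CHANNELS.values()))
    for col in CHANNELS.values():
        n_missing = out[col].isna().sum()
        if n_missing:
            logger.warning("%d plant(s) missing the %s channel", n_missing, col)
    return out.reset_index()
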
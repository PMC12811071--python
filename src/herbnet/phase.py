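"""Structural-phase diagnostics for bipartite networks.

Random-graph theory predicts that a bipartite network with a fixed degree
sequence and otherwise random wiring contains a giant component exactly when
the connectivity parameter

    C = sum_{m=1}^{D_plants} sum_{n=1}^{D_animals} m n (m n - m - n) p_m p_n

is positive, where ``p_m`` (``p_n``) is the relative frequency of plant
(animal) nodes with binary degree m (n) and D_* the largest observed degree on
each side.  This module computes C together with the two companion phase
diagnostics — number of connected components and the fraction of nodes in the
largest component — plus the per-plant interaction probabilities

    p_i = sum_j w_ij / sum_ik w_ik

that link network structure to plant-level covariates.

Degree here is *binary* (number of distinct partners); event counts enter only
``p_i`` and the bootstrap.  Nodes with zero realized interactions are excluded
from the degree distributions and, by default, from the component census —
pass ``include_isolated=True`` to keep manifest-declared uninfested plants in
the component/denominator bookkeeping as a sensitivity check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .net_io import BipartiteNetwork, ValidationError

__all__ = [
    "DegreeDistribution",
    "PhaseSummary",
    "degree_distributions",
    "connectivity_parameter",
    "components",
    "interaction_probabilities",
    "phase_summary",
]


@dataclass(frozen=True)
class DegreeDistribution:
    """Binary degree distributions of the two node sets.

    ``p_m[d]`` / ``p_n[d]`` give the relative frequency of degree ``d`` for
    d = 0..D (index 0 always holds probability 0: zero-degree nodes are
    excluded).
    """

    plant_degrees: np.ndarray
    animal_degrees: np.ndarray
    p_m: np.ndarray
    p_n: np.ndarray
    D_plants: int
    D_animals: int


@dataclass(frozen=True)
class PhaseSummary:
    """The three phase diagnostics for one network."""

    n_components: int
    frac_largest: float
    C: float
    n_nodes: int

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "frac_largest": self.frac_largest,
            "C": self.C,
            "n_nodes": self.n_nodes,
        }


def degree_distributions(net: BipartiteNetwork) -> DegreeDistribution:
    """Binary degree distributions over nodes with at least one interaction."""
    B = net.incidence()
    plant_deg = B.sum(axis=1)
    animal_deg = B.sum(axis=0)
    plant_deg = plant_deg[plant_deg > 0]
    animal_deg = animal_deg[animal_deg > 0]
    if plant_deg.size == 0 or animal_deg.size == 0:
        raise ValidationError("degree distribution undefined for an all-zero network")
    D_p = int(plant_deg.max())
    D_a = int(animal_deg.max())
    p_m = np.bincount(plant_deg, minlength=D_p + 1) / plant_deg.size
    p_n = np.bincount(animal_deg, minlength=D_a + 1) / animal_deg.size
    return DegreeDistribution(plant_deg, animal_deg, p_m, p_n, D_p, D_a)


def connectivity_parameter(dd: DegreeDistribution) -> float:
    """Giant-component criterion: C > 0 predicts the connected phase."""
    if dd.plant_degrees.size == 0 or dd.animal_degrees.size == 0:
        raise ValidationError("empty degree distribution")
    m = np.arange(dd.p_m.size)
    n = np.arange(dd.p_n.size)
    mn = np.outer(m, n)
    kernel = mn * (mn - m[:, None] - n[None, :])
    return float(np.einsum("mn,m,n->", kernel, dd.p_m, dd.p_n))


def _active_adjacency(net: BipartiteNetwork, include_isolated: bool):
    """Sparse symmetric adjacency over the retained nodes, plus their labels."""
    B = net.incidence()
    if include_isolated:
        keep_p = np.ones(net.n_plants, dtype=bool)
        keep_h = np.ones(net.n_herbivores, dtype=bool)
    else:
        keep_p = B.sum(axis=1) > 0
        keep_h = B.sum(axis=0) > 0
    Bk = B[np.ix_(keep_p, keep_h)]
    np_, nh = Bk.shape
    n = np_ + nh
    rows, cols = np.nonzero(Bk)
    r = np.concatenate([rows, cols + np_])
    c = np.concatenate([cols + np_, rows])
    A = csr_matrix((np.ones(r.size), (r, c)), shape=(n, n))
    labels = [p for p, k in zip(net.plant_ids, keep_p) if k] + [
        h for h, k in zip(net.herbivore_ids, keep_h) if k
    ]
    return A, labels


def components(
    net: BipartiteNetwork, include_isolated: bool = False
) -> tuple[int, dict[str, int], float]:
    """Connected components of the undirected bipartite graph.

    Returns ``(n_components, membership, frac_largest)`` where membership maps
    node label -> component index and ``frac_largest`` is the share of the
    retained nodes lying in the largest component (ties report the tied
    maximum size).
    """
    A, labels = _active_adjacency(net, include_isolated)
    if not labels:
        raise ValidationError("no nodes with interactions")
    n_comp, member = _cc(A, directed=False)
    sizes = np.bincount(member)
    frac = float(sizes.max() / len(labels))
    return int(n_comp), dict(zip(labels, member.tolist())), frac


def interaction_probabilities(net: BipartiteNetwork) -> pd.Series:
    """Per-plant share of all recorded interaction events (sums to 1)."""
    total = net.weights.sum()
    if total < 1:
        raise ValidationError("interaction probabilities undefined without events")
    p = net.weights.sum(axis=1) / total
    return pd.Series(p, index=list(net.plant_ids), name="p_i")


def phase_summary(net: BipartiteNetwork, include_isolated: bool = False) -> PhaseSummary:
    """Compose the three phase diagnostics for one network."""
    dd = degree_distributions(net)
    C = connectivity_parameter(dd)
    n_comp, _, frac = components(net, include_isolated=include_isolated)
    n_nodes = int(dd.plant_degrees.size + dd.animal_degrees.size)
    if include_isolated:
        n_nodes = net.n_nodes
    return PhaseSummary(n_components=n_comp, frac_largest=frac, C=C, n_nodes=n_nodes)
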
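"""Screening steps between network estimation and differential testing.

Variance-based gene filtering, definition of the extreme (most sensitive /
most resistant) cell lines, extraction of the strongest edges from a network
collection, decomposition of those edges into connected subnetworks, and
median summarisation of edge strengths.  Every step is deterministic: all
ties are broken by documented id order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SensitivityProfile
from .network_estimation import VaryingCoefficientNetwork

__all__ = [
    "Subnetwork",
    "select_top_variance_genes",
    "define_extreme_cell_lines",
    "extract_top_edges",
    "connected_components",
    "median_edge_summary",
    "subnetworks_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class Subnetwork:
    """A connected set of genes with its induced directed edges."""

    gene_ids: list[str]
    edges: list[tuple[str, str]]  # (regulator, target)
    subnetwork_id: str = ""
    summary_weights: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        members = set(self.gene_ids)
        for r, t in self.edges:
            if r not in members or t not in members:
                raise ValueError(f"edge ({r}, {t}) has an endpoint outside the subnetwork")
        g = nx.Graph()
        g.add_nodes_from(self.gene_ids)
        g.add_edges_from(self.edges)
        if len(self.gene_ids) > 1 and not nx.is_connected(g):
            raise ValueError("subnetwork is not connected as an undirected graph")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def select_top_variance_genes(expr: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """Keep the ``k`` genes with the largest sample variance.

    Ties are broken lexicographically by gene id; the surviving genes keep
    their original column order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > expr.n_genes:
        raise ValueError(f"k={k} exceeds the {expr.n_genes} available genes")
    var = expr.values.var(axis=0, ddof=1)
    ranked = sorted(range(expr.n_genes), key=lambda i: (-var[i], expr.gene_ids[i]))
    keep = sorted(ranked[:k])  # original column order
    return expr.subset_genes([expr.gene_ids[i] for i in keep])


def define_extreme_cell_lines(
    profile: SensitivityProfile, k: int
) -> tuple[list[str], list[str]]:
    """The ``k`` most sensitive (largest value) and ``k`` most resistant
    (smallest value) cell lines, as disjoint id lists.

    Boundary ties are broken by cell-line id order (ascending ids sort with
    ascending values), which keeps the two sets disjoint whenever ``2k <= n``.
    """
    n = profile.n_cell_lines
    if 2 * k > n:
        raise ValueError(f"2k={2 * k} exceeds the {n} available cell lines")
    if k <= 0:
        raise ValueError("k must be positive")
    order = sorted(range(n), key=lambda i: (profile.values[i], profile.cell_line_ids[i]))
    resistant = [profile.cell_line_ids[i] for i in order[:k]]
    sensitive = [profile.cell_line_ids[i] for i in order[n - k :]]
    boundary_ties = (
        profile.values[order[k - 1]] == profile.values[order[k]]
        or profile.values[order[n - k]] == profile.values[order[n - k - 1]]
    )
    if boundary_ties:
        logger.info("extreme-set boundary ties broken by cell-line id order")
    return sensitive, resistant


def _median_abs_strengths(
    networks: list[VaryingCoefficientNetwork],
) -> tuple[np.ndarray, list[str]]:
    if not networks:
        raise ValueError("need at least one network")
    gene_ids = networks[0].gene_ids
    for net in networks:
        if net.gene_ids != gene_ids:
            raise ValueError("networks are indexed over different gene sets")
    stack = np.stack([np.abs(net.coefficients) for net in networks])
    return np.median(stack, axis=0), gene_ids


def extract_top_edges(
    networks: list[VaryingCoefficientNetwork],
    fraction: float,
    per_network: bool = False,
) -> list[tuple[str, str]]:
    """Directed edges with the largest median absolute strength.

    Default reading: rank every edge by the median of ``|coefficient|``
    across the collection and keep the top ``ceil(fraction * E)``, where
    ``E`` counts edges with nonzero median (zero-median edges are treated as
    non-edges).  ``per_network=True`` instead takes the union of each
    network's own top ``fraction`` of nonzero edges.  Ties broken by
    (regulator, target) id order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    med, gene_ids = _median_abs_strengths(networks)

    if per_network:
        union: set[tuple[str, str]] = set()
        for net in networks:
            strengths = np.abs(net.coefficients)
            union.update(_top_of_matrix(strengths, gene_ids, fraction))
        return sorted(union)
    top = _top_of_matrix(med, gene_ids, fraction)
    if not top:
        import warnings

        warnings.warn("all median edge strengths are zero; no edges extracted", RuntimeWarning)
    return top


def _top_of_matrix(
    strengths: np.ndarray, gene_ids: list[str], fraction: float
) -> list[tuple[str, str]]:
    tgt, reg = np.nonzero(strengths)
    entries = [
        (-strengths[l, j], gene_ids[j], gene_ids[l]) for l, j in zip(tgt, reg) if l != j
    ]
    if not entries:
        return []
    entries.sort()
    n_keep = math.ceil(fraction * len(entries))
    return [(r, t) for _, r, t in entries[:n_keep]]


def connected_components(edges: list[tuple[str, str]]) -> list[Subnetwork]:
    """Undirected connected components of a directed edge set.

    Each component is returned with its induced directed edges, ordered by
    decreasing gene count then by lexicographically smallest member gene, and
    labelled ``S1, S2, ...`` in that order.
    """
    if not edges:
        raise ValueError("empty edge set")
    g = nx.Graph()
    g.add_edges_from(edges)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda genes: (-len(genes), genes[0]))
    out = []
    for i, genes in enumerate(comps):
        members = set(genes)
        induced = sorted((r, t) for r, t in edges if r in members and t in members)
        out.append(Subnetwork(genes, induced, subnetwork_id=f"S{i + 1}"))
    return out


def median_edge_summary(
    networks: list[VaryingCoefficientNetwork], subnet: Subnetwork
) -> pd.DataFrame:
    """Median signed strength of each subnetwork edge across a collection.

    The median of an even number of values is the midpoint of the two central
    values.  Sign is reported separately from magnitude, matching the
    positive/negative edge-colour convention used for network display.
    """
    med_signed, gene_ids = _signed_medians(networks)
    index = {g: i for i, g in enumerate(gene_ids)}
    rows = []
    for r, t in subnet.edges:
        if r not in index or t not in index:
            raise KeyError(f"subnetwork gene pair ({r}, {t}) absent from network index")
        value = float(med_signed[index[t], index[r]])
        rows.append((subnet.subnetwork_id, r, t, value, int(np.sign(value))))
    frame = pd.DataFrame(
        rows, columns=["subnetwork_id", "regulator", "target", "median_weight", "sign"]
    )
    subnet.summary_weights = {
        (r, t): w for _, r, t, w, _ in frame.itertuples(index=False, name=None)
    }
    return frame


def _signed_medians(
    networks: list[VaryingCoefficientNetwork],
) -> tuple[np.ndarray, list[str]]:
    if not networks:
        raise ValueError("need at least one network")
    gene_ids = networks[0].gene_ids
    stack = np.stack([net.coefficients for net in networks])
    return np.median(stack, axis=0), gene_ids


def subnetworks_to_frame(
    subnets: list[Subnetwork], networks: list[VaryingCoefficientNetwork]
) -> pd.DataFrame:
    """Flat TSV-ready table over all subnetworks with median edge weights."""
    frames = [median_edge_summary(networks, s) for s in subnets]
    return pd.concat(frames, ignore_index=True)
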
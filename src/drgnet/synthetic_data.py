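"""Synthetic expression panels with planted, sensitivity-varying networks.

The generator emulates the data-generating process assumed by the
varying-coefficient network model: each cell line carries a continuous drug
sensitivity value ``m``, and the expression of every target gene is a linear
combination of its regulators' expression with coefficients that change
smoothly with ``m``, plus Gaussian noise.  Planted networks are DAGs so the
panel can be produced by forward simulation in topological order; root genes
(no regulators) are i.i.d. standard normal.

Every downstream stage (kernel estimation, edge screening, the differential
permutation test) is validated against the ground truth objects produced
here, so the module is first-class, tested code rather than a fixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SensitivityProfile

__all__ = [
    "EffectProfile",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_dataset",
    "null_dataset",
    "write_truth_edges",
]


@dataclass(frozen=True)
class EffectProfile:
    """Coefficient of one regulatory edge as a function of sensitivity ``m``.

    ``value_sensitive`` is the coefficient at the sensitive end (largest
    ``m``), ``value_resistant`` at the resistant end (smallest ``m``).  The
    ``logistic`` kind interpolates smoothly between the two ends with the
    given transition ``midpoint`` and ``steepness``; ``step`` switches at the
    midpoint; ``constant`` requires both end values to coincide.
    """

    kind: str = "logistic"
    value_sensitive: float = 1.5
    value_resistant: float = 0.5
    midpoint: float | None = None
    steepness: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "logistic", "step"):
            raise ValueError(f"unknown profile kind: {self.kind!r}")
        if self.kind == "constant" and self.value_sensitive != self.value_resistant:
            raise ValueError("constant profile requires equal end values")

    @classmethod
    def constant(cls, value: float) -> "EffectProfile":
        return cls("constant", value, value)

    @classmethod
    def logistic(
        cls,
        value_sensitive: float,
        value_resistant: float,
        midpoint: float | None = None,
        steepness: float | None = None,
    ) -> "EffectProfile":
        return cls("logistic", value_sensitive, value_resistant, midpoint, steepness)

    @classmethod
    def step(
        cls, value_sensitive: float, value_resistant: float, midpoint: float | None = None
    ) -> "EffectProfile":
        return cls("step", value_sensitive, value_resistant, midpoint)

    @property
    def is_differential(self) -> bool:
        return self.value_sensitive != self.value_resistant

    def evaluate(self, m: np.ndarray, midpoint: float, steepness: float) -> np.ndarray:
        """Coefficient value at each ``m``; falls back to the resolved
        ``midpoint``/``steepness`` when the profile leaves them unset."""
        m = np.asarray(m, dtype=float)
        mid = self.midpoint if self.midpoint is not None else midpoint
        if self.kind == "constant":
            return np.full(m.shape, self.value_resistant)
        if self.kind == "step":
            return np.where(m >= mid, self.value_sensitive, self.value_resistant)
        s = self.steepness if self.steepness is not None else steepness
        sig = 1.0 / (1.0 + np.exp(-s * (m - mid)))
        return self.value_resistant + (self.value_sensitive - self.value_resistant) * sig


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters for one synthetic panel.

    ``module_sizes`` optionally partitions the first ``sum(module_sizes)``
    genes into disjoint modules; planted edges then stay within modules and
    only modules listed in ``differential_modules`` receive the (differential)
    ``effect_profile`` — the rest receive ``null_profile``.  ``explicit_edges``
    overrides random edge placement entirely with ``(regulator_index,
    target_index, profile)`` triples.
    """

    n_cell_lines: int = 200
    n_genes: int = 20
    sensitivity_range: tuple[float, float] = (-2.0, 2.0)
    n_true_edges: int = 25
    effect_profile: EffectProfile = field(default_factory=EffectProfile)
    null_profile: EffectProfile = field(default_factory=lambda: EffectProfile.constant(1.0))
    noise_sd: float = 0.3
    seed: int = 0
    sensitivity_distribution: str = "uniform"  # or "bimodal"
    module_sizes: tuple[int, ...] | None = None
    differential_modules: tuple[int, ...] = ()
    explicit_edges: tuple[tuple[int, int, EffectProfile], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_cell_lines <= 0 or self.n_genes <= 0:
            raise ValueError("n_cell_lines and n_genes must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.sensitivity_range
        if not lo < hi:
            raise ValueError("sensitivity_range must be a nonempty interval")
        if self.explicit_edges is None:
            if not 0 <= self.n_true_edges <= self.n_genes * (self.n_genes - 1):
                raise ValueError("n_true_edges exceeds the number of ordered gene pairs")
        if self.sensitivity_distribution not in ("uniform", "bimodal"):
            raise ValueError(f"unknown distribution: {self.sensitivity_distribution!r}")
        if self.module_sizes is not None:
            if sum(self.module_sizes) > self.n_genes:
                raise ValueError("module sizes exceed n_genes")
            for mi in self.differential_modules:
                if not 0 <= mi < len(self.module_sizes):
                    raise ValueError(f"differential module index {mi} out of range")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying one generated panel."""

    coefficient_tensor: np.ndarray  # (n, p, p); [cell, target, regulator]
    differential_edge_set: set[tuple[str, str]]  # (regulator id, target id)
    sensitivity_vector: np.ndarray
    group_labels: list[str]  # sensitive / moderate / resistant per cell line
    edges: list[tuple[str, str, EffectProfile]]
    gene_ids: list[str]
    cell_line_ids: list[str]
    noise_sd: float
    module_of: dict[str, int] = field(default_factory=dict)

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return {(r, t) for r, t, _ in self.edges}

    def module_genes(self, module: int) -> list[str]:
        return [g for g in self.gene_ids if self.module_of.get(g) == module]


def _draw_sensitivity(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.sensitivity_range
    n = config.n_cell_lines
    if config.sensitivity_distribution == "uniform":
        return rng.uniform(lo, hi, n)
    # Bimodal: equal mixture concentrated in the outer quarters of the range,
    # mimicking a screen restricted to the most extreme responders.
    width = (hi - lo) / 4.0
    low = rng.uniform(lo, lo + width, n)
    high = rng.uniform(hi - width, hi, n)
    pick = rng.random(n) < 0.5
    return np.where(pick, low, high)


def _plant_edges(
    config: SyntheticConfig, order: np.ndarray, rng: np.random.Generator
) -> list[tuple[int, int, EffectProfile]]:
    """Sample a DAG edge set respecting the topological ``order``.

    Returns (regulator index, target index, profile) triples; the regulator
    always precedes the target in ``order``.
    """
    rank = np.empty(config.n_genes, dtype=int)
    rank[order] = np.arange(config.n_genes)

    def admissible(genes: np.ndarray) -> list[tuple[int, int]]:
        pairs = []
        for u in genes:
            for v in genes:
                if u != v and rank[u] < rank[v]:
                    pairs.append((int(u), int(v)))
        pairs.sort()
        return pairs

    edges: list[tuple[int, int, EffectProfile]] = []
    if config.module_sizes is None:
        pairs = admissible(np.arange(config.n_genes))
        idx = rng.choice(len(pairs), size=config.n_true_edges, replace=False)
        for i in sorted(int(j) for j in idx):
            u, v = pairs[i]
            edges.append((u, v, config.effect_profile))
        return edges

    # Distribute edges as evenly as possible across modules, remainders to
    # the earliest modules.
    n_mod = len(config.module_sizes)
    base, extra = divmod(config.n_true_edges, n_mod)
    counts = [base + (1 if i < extra else 0) for i in range(n_mod)]
    start = 0
    for mi, size in enumerate(config.module_sizes):
        genes = np.arange(start, start + size)
        start += size
        pairs = admissible(genes)
        if counts[mi] > len(pairs):
            raise ValueError(
                f"module {mi} has only {len(pairs)} admissible pairs for {counts[mi]} edges"
            )
        if counts[mi] < size - 1:
            raise ValueError(
                f"module {mi} needs at least {size - 1} edges to be connected"
            )
        profile = (
            config.effect_profile if mi in config.differential_modules else config.null_profile
        )
        # A module is a testable subnetwork, so it is connected by
        # construction: spanning path along the topological order first,
        # then extra random admissible pairs.
        by_rank = sorted(genes, key=lambda g: rank[g])
        spine = [(int(u), int(v)) for u, v in zip(by_rank[:-1], by_rank[1:])]
        rest = [pr for pr in pairs if pr not in set(spine)]
        n_extra = counts[mi] - len(spine)
        chosen = list(spine)
        if n_extra > 0:
            idx = rng.choice(len(rest), size=n_extra, replace=False)
            chosen += [rest[int(j)] for j in sorted(idx)]
        for u, v in sorted(chosen):
            edges.append((u, v, profile))
    return edges


def _tercile_labels(m: np.ndarray) -> list[str]:
    order = np.argsort(m, kind="stable")
    n = m.size
    labels = np.empty(n, dtype=object)
    labels[order[: n // 3]] = "resistant"
    labels[order[n // 3 : n - n // 3]] = "moderate"
    labels[order[n - n // 3 :]] = "sensitive"
    return list(labels)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, SensitivityProfile, SyntheticTruth]:
    """Forward-simulate a panel from a planted sensitivity-varying DAG.

    Raises ``ValueError`` if ``explicit_edges`` contain a cycle (forward
    generation requires a topological order).
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_cell_lines, config.n_genes
    m = _draw_sensitivity(config, rng)

    if config.explicit_edges is not None:
        graph = nx.DiGraph()
        graph.add_nodes_from(range(p))
        graph.add_edges_from([(u, v) for u, v, _ in config.explicit_edges])
        try:
            topo = list(nx.topological_sort(graph))
        except nx.NetworkXUnfeasible:
            raise ValueError("explicit edge set is cyclic; forward generation impossible")
        edges_idx = [(int(u), int(v), prof) for u, v, prof in config.explicit_edges]
    else:
        order = rng.permutation(p)
        edges_idx = _plant_edges(config, order, rng)
        topo = list(order)

    lo, hi = config.sensitivity_range
    default_mid = float(np.median(m))
    default_steep = 8.0 / (hi - lo)

    tensor = np.zeros((n, p, p))
    for u, v, prof in edges_idx:
        tensor[:, v, u] = prof.evaluate(m, default_mid, default_steep)

    parents: dict[int, list[int]] = {v: [] for v in range(p)}
    for u, v, _ in edges_idx:
        parents[v].append(u)

    X = np.zeros((n, p))
    for g in topo:
        g = int(g)
        if not parents[g]:
            X[:, g] = rng.standard_normal(n)
        else:
            mean = np.zeros(n)
            for u in parents[g]:
                mean = mean + tensor[:, g, u] * X[:, u]
            X[:, g] = mean + rng.normal(0.0, config.noise_sd, n)

    digits_g = max(2, len(str(p)))
    digits_c = max(3, len(str(n)))
    gene_ids = [f"G{i + 1:0{digits_g}d}" for i in range(p)]
    cell_ids = [f"CL{i + 1:0{digits_c}d}" for i in range(n)]

    edges_named = [(gene_ids[u], gene_ids[v], prof) for u, v, prof in edges_idx]
    diff_set = {(r, t) for r, t, prof in edges_named if prof.is_differential}

    module_of: dict[str, int] = {}
    if config.module_sizes is not None:
        start = 0
        for mi, size in enumerate(config.module_sizes):
            for g in range(start, start + size):
                module_of[gene_ids[g]] = mi
            start += size

    expr = ExpressionMatrix(X, cell_ids, gene_ids)
    profile = SensitivityProfile(m, cell_ids)
    truth = SyntheticTruth(
        coefficient_tensor=tensor,
        differential_edge_set=diff_set,
        sensitivity_vector=m.copy(),
        group_labels=_tercile_labels(m),
        edges=edges_named,
        gene_ids=gene_ids,
        cell_line_ids=cell_ids,
        noise_sd=config.noise_sd,
        module_of=module_of,
    )
    return expr, profile, truth


def null_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, SensitivityProfile, SyntheticTruth]:
    """Same machinery with every edge held constant in ``m``.

    Each planted profile is flattened to a constant at the midpoint of its two
    end values, so the coefficient tensor is identical across cell lines and
    the differential edge set is empty.
    """

    def flatten(prof: EffectProfile) -> EffectProfile:
        return EffectProfile.constant((prof.value_sensitive + prof.value_resistant) / 2.0)

    cfg = replace(
        config,
        effect_profile=flatten(config.effect_profile),
        null_profile=flatten(config.null_profile),
        explicit_edges=None
        if config.explicit_edges is None
        else tuple((u, v, flatten(prof)) for u, v, prof in config.explicit_edges),
    )
    expr, profile, truth = generate_dataset(cfg)
    assert not truth.differential_edge_set
    return expr, profile, truth


def write_truth_edges(truth: SyntheticTruth, path) -> None:
    """Planted edges as a TSV table for external assertions."""
    rows = [
        {
            "regulator": r,
            "target": t,
            "value_sensitive_end": prof.value_sensitive,
            "value_resistant_end": prof.value_resistant,
        }
        for r, t, prof in truth.edges
    ]
    pd.DataFrame(rows, columns=[
        "regulator", "target", "value_sensitive_end", "value_resistant_end",
    ]).to_csv(path, sep="\t", index=False)
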
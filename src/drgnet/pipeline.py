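"""End-to-end orchestration: filter -> estimate -> extract -> decompose -> test.

Reads DepMap-dialect CSV inputs (expression: first column cell-line id,
remaining columns genes, headers optionally ``"SYMBOL (ENTREZ)"``;
sensitivity: two columns, cell line and one continuous value), runs the
screening and differential-testing chain, and writes every intermediate
artifact as TSV stamped with the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SensitivityProfile, align
from .differential_network import (
    DiffTestResult,
    identify_differential_subnetworks,
    results_to_frame,
)
from .network_estimation import (
    EstimatorConfig,
    VaryingCoefficientNetwork,
    estimate_all_networks,
    networks_to_long_frame,
)
from .network_summary import (
    Subnetwork,
    connected_components,
    define_extreme_cell_lines,
    extract_top_edges,
    select_top_variance_genes,
    subnetworks_to_frame,
)

__all__ = [
    "PipelineConfig",
    "PipelineResults",
    "load_expression",
    "load_sensitivity",
    "read_networks_long",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_HEADER_RE = re.compile(r"^\s*(?P<symbol>.+?)\s*\((?P<entrez>[0-9]+)\)\s*$")


def load_expression(path) -> ExpressionMatrix:
    """Parse a DepMap-dialect expression CSV.

    Gene headers of the form ``"SYMBOL (ENTREZID)"`` are reduced to the
    symbol, with the numeric id retained as metadata; duplicated symbols are
    disambiguated by appending the id.  Non-numeric cells raise with their
    row/column location.
    """
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    for col in frame.columns:
        if frame[col].dtype == object:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = coerced.isna() & frame[col].notna()
            if bad.any():
                row = frame.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric expression value at row {row!r}, column {col!r}"
                )
            frame[col] = coerced
    if frame.isna().any().any():
        col = frame.columns[frame.isna().any().to_numpy().argmax()]
        row = frame.index[frame[col].isna().to_numpy().argmax()]
        raise ValueError(f"missing expression value at row {row!r}, column {col!r}")

    symbols, entrez = [], {}
    for col in frame.columns:
        match = _HEADER_RE.match(str(col))
        if match:
            symbols.append(match.group("symbol"))
            entrez[match.group("symbol")] = match.group("entrez")
        else:
            symbols.append(str(col).strip())
    # Disambiguate duplicate symbols with their numeric id where available.
    seen: dict[str, int] = {}
    for s in symbols:
        seen[s] = seen.get(s, 0) + 1
    if any(c > 1 for c in seen.values()):
        unique = []
        meta: dict[str, str] = {}
        for raw, sym in zip(frame.columns, symbols):
            match = _HEADER_RE.match(str(raw))
            if seen[sym] > 1 and match:
                name = f"{sym}_{match.group('entrez')}"
            elif seen[sym] > 1:
                name = f"{sym}_{len(unique)}"
            else:
                name = sym
            if match:
                meta[name] = match.group("entrez")
            unique.append(name)
        return ExpressionMatrix(frame.to_numpy(float), list(frame.index), unique, meta)
    return ExpressionMatrix(frame.to_numpy(float), list(frame.index), symbols, entrez)


def load_sensitivity(path) -> SensitivityProfile:
    """Two-column CSV: cell-line id, one continuous sensitivity value."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.shape[1] < 2:
        raise ValueError("sensitivity CSV needs at least two columns")
    ids = frame.iloc[:, 0].astype(str)
    values = pd.to_numeric(frame.iloc[:, 1], errors="coerce")
    keep = values.notna()
    return SensitivityProfile(values[keep].to_numpy(float), list(ids[keep]))


def read_networks_long(path) -> list[VaryingCoefficientNetwork]:
    """Rebuild networks from a long-format edge TSV (inverse of
    :func:`networks_to_long_frame` up to structurally zero entries)."""
    frame = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    genes = sorted(set(frame["regulator"]) | set(frame["target"]))
    pos = {g: i for i, g in enumerate(genes)}
    nets = []
    for cid, grp in frame.groupby("cell_line", sort=True):
        coef = np.zeros((len(genes), len(genes)))
        for _, r in grp.iterrows():
            coef[pos[r["target"]], pos[r["regulator"]]] = r["coefficient"]
        nets.append(VaryingCoefficientNetwork(coef, str(cid), float("nan"), genes))
    return nets


@dataclass(frozen=True)
class PipelineConfig:
    """Flat, serialisable configuration of one end-to-end run."""

    expression_path: str = ""
    sensitivity_path: str = ""
    output_dir: str = "drgnet_output"
    n_top_genes: int = 1000
    n_extreme: int = 100
    edge_fraction: float = 0.01
    gamma: float = 1.0
    tau: float = 0.05
    n_permutations: int = 500
    tail_mode: str = "small-is-extreme"
    seed: int = 0
    estimate_full_panel: bool = False
    per_network_edges: bool = False
    multiple_testing: str = "none"  # or "benjamini-hochberg"
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)

    def flat_items(self) -> list[tuple[str, str]]:
        items = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, EstimatorConfig):
                for g in dataclasses.fields(v):
                    items.append((f"estimator.{g.name}", repr(getattr(v, g.name))))
            else:
                items.append((f.name, repr(v)))
        return items

    def config_hash(self) -> str:
        # output_dir does not affect the analysis, so reruns into different
        # directories stamp identical hashes.
        blob = "\n".join(f"{k}={v}" for k, v in self.flat_items() if k != "output_dir")
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_file(self, path) -> None:
        Path(path).write_text(
            "".join(f"{k} = {v}\n" for k, v in self.flat_items()), encoding="utf-8"
        )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import ast

        kv: dict[str, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        est_kwargs = {
            k.split(".", 1)[1]: ast.literal_eval(v)
            for k, v in kv.items()
            if k.startswith("estimator.")
        }
        top_kwargs = {
            k: ast.literal_eval(v) for k, v in kv.items() if not k.startswith("estimator.")
        }
        return cls(estimator=EstimatorConfig(**est_kwargs), **top_kwargs)


@dataclass
class PipelineResults:
    config: PipelineConfig
    expression: ExpressionMatrix
    profile: SensitivityProfile
    sensitive_ids: list[str]
    resistant_ids: list[str]
    networks: list[VaryingCoefficientNetwork]
    top_edges: list[tuple[str, str]]
    subnetworks: list[Subnetwork]
    results: list[DiffTestResult]
    counts: dict[str, int]


def _write_tsv(frame: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# drgnet config_hash={config.config_hash()} seed={config.seed}\n")
        frame.to_csv(fh, sep="\t", index=False)


def run_pipeline(
    config: PipelineConfig,
    expression: ExpressionMatrix | None = None,
    profile: SensitivityProfile | None = None,
) -> PipelineResults:
    """Run the full screening + differential-testing chain.

    Inputs may be passed in memory; otherwise they are read from the paths in
    ``config``.  All stage outputs land in ``config.output_dir`` as TSVs
    headed by the configuration hash and seed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    stage = "load"
    try:
        if expression is None:
            expression = load_expression(config.expression_path)
        if profile is None:
            profile = load_sensitivity(config.sensitivity_path)
        expression, profile, dropped = align(expression, profile)
        counts["cell_lines_kept"] = expression.n_cell_lines
        counts["cell_lines_dropped"] = dropped
        logger.info("kept %d cell lines (%d dropped in join)", expression.n_cell_lines, dropped)

        stage = "filter"
        k = min(config.n_top_genes, expression.n_genes)
        expression = select_top_variance_genes(expression, k)
        counts["genes_kept"] = expression.n_genes
        logger.info("kept %d top-variance genes", expression.n_genes)

        stage = "extremes"
        sensitive_ids, resistant_ids = define_extreme_cell_lines(profile, config.n_extreme)
        counts["extreme_cell_lines"] = len(sensitive_ids) + len(resistant_ids)

        stage = "estimate"
        wanted = None if config.estimate_full_panel else sensitive_ids + resistant_ids
        est = dataclasses.replace(config.estimator, seed=config.seed)
        networks = estimate_all_networks(expression, profile, est, at_cell_lines=wanted)
        counts["networks_estimated"] = len(networks)
        logger.info("estimated %d networks", len(networks))

        stage = "extract"
        by_id = {n.cell_line_id: n for n in networks}
        resistant_networks = [by_id[c] for c in resistant_ids]
        top_edges = extract_top_edges(
            resistant_networks, config.edge_fraction, per_network=config.per_network_edges
        )
        counts["edges_extracted"] = len(top_edges)
        logger.info("extracted %d edges", len(top_edges))

        stage = "decompose"
        subnets = connected_components(top_edges) if top_edges else []
        counts["subnetworks"] = len(subnets)
        logger.info("found %d subnetworks", len(subnets))

        stage = "difftest"
        results = identify_differential_subnetworks(
            subnets,
            networks,
            sensitive_ids,
            resistant_ids,
            gamma=config.gamma,
            tau=config.tau,
            n_permutations=config.n_permutations,
            tail_mode=config.tail_mode,
            seed=config.seed,
        )
        if config.multiple_testing == "benjamini-hochberg" and results:
            from scipy.stats import false_discovery_control

            adj = false_discovery_control([r.p_value for r in results], method="bh")
            for r, q in zip(results, adj):
                r.p_value = float(q)
                r.significant = bool(q < config.tau)
        counts["significant_subnetworks"] = sum(r.significant for r in results)

        stage = "write"
        config.to_file(outdir / "config.txt")
        groups = pd.DataFrame(
            [(c, "sensitive") for c in sensitive_ids]
            + [(c, "resistant") for c in resistant_ids],
            columns=["cell_line", "group"],
        )
        _write_tsv(groups, outdir / "extreme_cell_lines.tsv", config)
        _write_tsv(networks_to_long_frame(networks), outdir / "networks_long.tsv", config)
        _write_tsv(
            pd.DataFrame(top_edges, columns=["regulator", "target"]),
            outdir / "top_edges.tsv",
            config,
        )
        if subnets:
            _write_tsv(
                subnetworks_to_frame(subnets, resistant_networks),
                outdir / "subnetworks.tsv",
                config,
            )
        _write_tsv(results_to_frame(results), outdir / "difftest_results.tsv", config)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResults(
        config=config,
        expression=expression,
        profile=profile,
        sensitive_ids=sensitive_ids,
        resistant_ids=resistant_ids,
        networks=networks,
        top_edges=top_edges,
        subnetworks=subnets,
        results=results,
        counts=counts,
    )
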
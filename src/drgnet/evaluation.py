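"""Simulation studies of the estimator and the differential test.

Replicated synthetic experiments used to characterise the method: null
calibration of the permutation test, recovery of a planted differential
module, and support/sign recovery of the kernel elastic-net estimator.
Each replicate derives its own seed from the study seed, so studies are
reproducible end to end.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .differential_network import identify_differential_subnetworks, permutation_test
from .network_estimation import EstimatorConfig, estimate_all_networks
from .network_summary import Subnetwork, connected_components, define_extreme_cell_lines
from .synthetic_data import EffectProfile, SyntheticConfig, generate_dataset, null_dataset

__all__ = [
    "replicate_seed",
    "null_calibration_study",
    "planted_module_study",
    "estimator_recovery_study",
]


def replicate_seed(base_seed: int, replicate: int) -> int:
    """Stable per-replicate seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), int(replicate)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _truth_subnetworks(truth) -> list[Subnetwork]:
    """Connected subnetworks of the planted edge set (one per component)."""
    comps = connected_components(sorted(truth.edge_set))
    return comps


def null_calibration_study(
    n_replicates: int = 200,
    n_cell_lines: int = 120,
    n_genes: int = 15,
    n_edges: int = 20,
    k_extreme: int = 30,
    n_permutations: int = 99,
    noise_sd: float = 0.3,
    tail_mode: str = "small-is-extreme",
    seed: int = 0,
    estimator: EstimatorConfig | None = None,
) -> dict:
    """Permutation p-values when no differential structure exists.

    Each replicate draws a fresh panel whose planted coefficients are
    constant in the sensitivity value, estimates networks for the extreme
    cell lines, and permutation-tests the largest planted component.
    Returns the p-values plus the rejection rate at 0.05 and a
    Kolmogorov-Smirnov uniformity p-value.
    """
    est = estimator or EstimatorConfig()
    p_values = np.empty(n_replicates)
    for rep in range(n_replicates):
        rs = replicate_seed(seed, rep)
        cfg = SyntheticConfig(
            n_cell_lines=n_cell_lines,
            n_genes=n_genes,
            n_true_edges=n_edges,
            noise_sd=noise_sd,
            seed=rs,
        )
        expr, prof, truth = null_dataset(cfg)
        sens, res = define_extreme_cell_lines(prof, k_extreme)
        nets = estimate_all_networks(expr, prof, est, at_cell_lines=sens + res)
        subnet = _truth_subnetworks(truth)[0]  # largest planted component
        result = permutation_test(
            sens,
            res,
            nets,
            subnet,
            n_permutations=n_permutations,
            tail_mode=tail_mode,
            seed=replicate_seed(rs, 1),
        )
        p_values[rep] = result.p_value
    rejection = float((p_values < 0.05).mean())
    ks = stats.kstest(p_values, "uniform")
    return {
        "p_values": p_values,
        "rejection_rate": rejection,
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "n_replicates": n_replicates,
    }


def planted_module_study(
    n_replicates: int = 50,
    n_cell_lines: int = 200,
    module_sizes: tuple[int, ...] = (5, 5, 5),
    n_edges: int = 15,
    k_extreme: int = 50,
    n_permutations: int = 500,
    noise_sd: float = 0.3,
    tau: float = 0.05,
    seed: int = 0,
    estimator: EstimatorConfig | None = None,
) -> dict:
    """Recovery of one differential module among null modules.

    The first module's coefficients rise from 0 at the sensitive end to 1.5
    at the resistant end; the remaining modules are constant at 1.  Reports
    how often the planted module attains the minimum p-value (ties allowed),
    is the strictly unique minimum, is flagged at ``tau``, and has the
    lowest observed DCS.
    """
    est = estimator or EstimatorConfig()
    attains_min = np.zeros(n_replicates, dtype=bool)
    unique_min = np.zeros(n_replicates, dtype=bool)
    flagged = np.zeros(n_replicates, dtype=bool)
    lowest_dcs = np.zeros(n_replicates, dtype=bool)
    for rep in range(n_replicates):
        rs = replicate_seed(seed, rep)
        cfg = SyntheticConfig(
            n_cell_lines=n_cell_lines,
            n_genes=sum(module_sizes),
            n_true_edges=n_edges,
            noise_sd=noise_sd,
            seed=rs,
            effect_profile=EffectProfile.logistic(0.0, 1.5),
            null_profile=EffectProfile.constant(1.0),
            module_sizes=module_sizes,
            differential_modules=(0,),
        )
        expr, prof, truth = generate_dataset(cfg)
        sens, res = define_extreme_cell_lines(prof, k_extreme)
        nets = estimate_all_networks(expr, prof, est, at_cell_lines=sens + res)
        subnets = []
        for mi in range(len(module_sizes)):
            genes = truth.module_genes(mi)
            edges = [(r, t) for r, t, _ in truth.edges if r in genes and t in genes]
            subnets.append(Subnetwork(genes, edges, subnetwork_id=f"S{mi + 1}"))
        results = identify_differential_subnetworks(
            subnets, nets, sens, res,
            tau=tau, n_permutations=n_permutations, seed=replicate_seed(rs, 1),
        )
        by_id = {r.subnetwork_id: r for r in results}
        planted = by_id["S1"]
        other_p = [by_id[f"S{i + 1}"].p_value for i in range(1, len(module_sizes))]
        other_d = [by_id[f"S{i + 1}"].dcs_observed for i in range(1, len(module_sizes))]
        attains_min[rep] = planted.p_value <= min(other_p)
        unique_min[rep] = planted.p_value < min(other_p)
        flagged[rep] = planted.significant
        lowest_dcs[rep] = planted.dcs_observed < min(other_d)
    return {
        "attains_min_p_rate": float(attains_min.mean()),
        "unique_min_p_rate": float(unique_min.mean()),
        "flagged_rate": float(flagged.mean()),
        "lowest_dcs_rate": float(lowest_dcs.mean()),
        "n_replicates": n_replicates,
    }


def estimator_recovery_study(
    n_cell_lines: int = 300,
    n_genes: int = 20,
    n_edges: int = 25,
    noise_sd: float = 0.3,
    seed: int = 0,
    estimator: EstimatorConfig | None = None,
) -> dict:
    """Sign agreement of the estimator on the planted support.

    Averages, over cell lines, the fraction of planted (nonzero-truth) edges
    whose estimated coefficient has the correct sign at that cell line's
    sensitivity value.
    """
    est = estimator or EstimatorConfig()
    cfg = SyntheticConfig(
        n_cell_lines=n_cell_lines,
        n_genes=n_genes,
        n_true_edges=n_edges,
        noise_sd=noise_sd,
        seed=seed,
    )
    expr, prof, truth = generate_dataset(cfg)
    nets = estimate_all_networks(expr, prof, est)
    idx = {g: i for i, g in enumerate(expr.gene_ids)}
    cpos = {c: i for i, c in enumerate(expr.cell_line_ids)}
    per_cell = []
    for net in nets:
        ci = cpos[net.cell_line_id]
        hits = []
        for r, t, _ in truth.edges:
            true = truth.coefficient_tensor[ci, idx[t], idx[r]]
            if abs(true) > 1e-8:
                hits.append(np.sign(net.coefficients[idx[t], idx[r]]) == np.sign(true))
        per_cell.append(np.mean(hits))
    return {
        "sign_agreement": float(np.mean(per_cell)),
        "n_cell_lines": n_cell_lines,
    }
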
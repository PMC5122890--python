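"""Whole-network reconstruction: per-node solves assembled into one matrix.

Each node's neighbor-weight row is recovered independently from the trace
(the per-node problems share nothing but the data), then the rows are
re-embedded into an N x N matrix and symmetrized.  Three methods are
supported:

* ``moea+knee``   — evolve the per-node Pareto front, pick the knee point
                    (the fully data-driven method);
* ``moea+min_re`` — pick the front member with the smallest reconstruction
                    error against a supplied ground truth (diagnostic upper
                    bound on what front selection could achieve);
* ``lasso``       — the single-penalty nonnegative lasso baseline.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import network_models
from .game_dynamics import GameTrace, SimulationConfig, make_payoff_matrix, simulate
from .knee_metrics import (
    MetricsReport,
    evaluate_matrices,
    select_knee,
)
from .linear_system import add_noise, build_local_system, truncate_to_nm
from .moea_core import MOEAConfig, ParetoFront, run_moeanet
from .network_models import WeightedNetwork
from .sparse_solvers import lasso_solve

__all__ = [
    "METHODS",
    "ReconstructionResult",
    "node_seed",
    "reconstruct_network",
    "evaluate_result",
    "benchmark",
    "summarize_benchmark",
]

logger = logging.getLogger(__name__)

METHODS = ("moea+knee", "moea+min_re", "lasso")


@dataclass
class ReconstructionResult:
    X_est: np.ndarray
    selection_mode: str
    config_snapshot: dict
    seeds: dict
    per_node_fronts: list[ParetoFront] | None = field(default=None, repr=False)


def node_seed(master_seed: int, node: int) -> np.random.SeedSequence:
    """Per-node seed stream: SeedSequence keyed by (master seed, node index)."""
    return np.random.SeedSequence([int(master_seed), int(node)])


def _assemble(rows: np.ndarray, mode: str) -> np.ndarray:
    if mode == "average":
        X = 0.5 * (rows + rows.T)
    elif mode == "max":
        X = np.maximum(rows, rows.T)
    elif mode == "min":
        X = np.minimum(rows, rows.T)
    else:
        raise ValueError(f"unknown symmetrization mode {mode!r}")
    np.fill_diagonal(X, 0.0)
    return X


def reconstruct_network(
    trace: GameTrace,
    method: str = "moea+knee",
    *,
    b: float = 1.2,
    sigma: float = 0.0,
    moea_config: MOEAConfig | None = None,
    lasso_lam: float = 0.001,
    prune_k: int = 10,
    n_samples: int = 100,
    symmetrize: str = "average",
    seed: int = 0,
    truth: WeightedNetwork | None = None,
    keep_fronts: bool = False,
) -> ReconstructionResult:
    """Reconstruct the full weighted adjacency matrix from a trace.

    ``sigma`` adds Gaussian measurement noise to each node's payoff vector
    at system-build time (seeded per node).  ``moea+min_re`` requires
    ``truth`` and exists purely as a diagnostic ceiling for front selection.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}; got {method!r}")
    if method == "moea+min_re" and truth is None:
        raise ValueError("moea+min_re requires a ground-truth network (diagnostic mode)")
    n = trace.n_agents
    pm = make_payoff_matrix(b)
    if moea_config is None:
        moea_config = MOEAConfig()
    rows = np.zeros((n, n))
    fronts: list[ParetoFront] = []
    node_seeds: list[int] = []

    for i in range(n):
        ss = node_seed(seed, i)
        s_noise, s_moea = ss.spawn(2)
        node_seeds.append(int(ss.generate_state(1)[0] % (2**31)))
        system = build_local_system(trace, i, pm)
        if sigma > 0:
            system = add_noise(system, sigma, seed=s_noise)
        if method == "lasso":
            sol = lasso_solve(system, lasso_lam)
            w = sol.weights
            detail = f"lam={lasso_lam:g} err={sol.error_term:.4g}"
        else:
            extra = dict.fromkeys((*moea_config.include_lambdas, lasso_lam))
            cfg = replace(moea_config, seed=s_moea, include_lambdas=tuple(extra))
            front = run_moeanet(system, cfg)
            if keep_fronts:
                fronts.append(front)
            if method == "moea+knee":
                sel = select_knee(front, prune_k=prune_k, n_samples=n_samples)
                chosen = sel.solution
                detail = (f"front={len(front)} knee={sel.chosen} "
                          f"f1={chosen.f1:.4g} f2={chosen.f2:.4g}")
            else:  # moea+min_re
                x_true = truth.adjacency[i][system.candidate_ids]
                W = front.weight_matrix
                errs = np.abs(W - x_true).sum(axis=1)
                k = int(np.argmin(errs))
                chosen = front.solutions[k]
                detail = f"front={len(front)} min_re={k} f1={chosen.f1:.4g}"
            w = chosen.weights
        rows[i] = system.embed(w, n)
        logger.info("node %d: %s", i, detail)

    X_est = _assemble(rows, symmetrize)
    snapshot = {
        "method": method,
        "b": b,
        "sigma": sigma,
        "lasso_lam": lasso_lam,
        "prune_k": prune_k,
        "n_samples": n_samples,
        "symmetrize": symmetrize,
        "moea": asdict(moea_config) if method != "lasso" else None,
    }
    return ReconstructionResult(
        X_est=X_est,
        selection_mode=method,
        config_snapshot=snapshot,
        seeds={"master": int(seed), "per_node": node_seeds},
        per_node_fronts=fronts if keep_fronts else None,
    )


def evaluate_result(result: ReconstructionResult, truth: WeightedNetwork,
                    threshold: float = 0.5) -> MetricsReport:
    """Score a reconstruction against the true network (all six metrics)."""
    if result.X_est.shape != truth.adjacency.shape:
        raise ValueError("estimate and truth have mismatched sizes")
    return evaluate_matrices(result.X_est, truth.adjacency, threshold=threshold)


_GENERATORS = {
    "er": lambda n, k, seed: network_models.gen_er(n, k, seed=seed),
    "ba": lambda n, k, seed: network_models.gen_ba(n, max(1, round(k / 2)), seed=seed),
    "nw": lambda n, k, seed: network_models.gen_nw(n, max(2, round(k / 2) * 2), 0.1, seed=seed),
    "ws": lambda n, k, seed: network_models.gen_ws(n, max(2, round(k / 2) * 2), 0.1, seed=seed),
}


def benchmark(config: dict) -> pd.DataFrame:
    """Run a simulate -> reconstruct -> evaluate sweep.

    ``config`` keys: ``model`` (er|ba|nw|ws), ``n``, ``k_avg``, ``b``,
    ``kappa``, ``sigma``, ``n_m``, ``method``, ``replicates``, ``seed``,
    ``sweep`` = {"variable": one of n_m|sigma|k_avg, "values": [...]},
    optional ``moea`` (MOEAConfig fields) and ``lasso_lam``.

    Returns one tidy row per (sweep value, replicate) with the six metrics;
    failures are recorded in the ``error`` column and the run continues.
    """
    model = config.get("model", "er")
    n = int(config.get("n", 50))
    base = {
        "k_avg": float(config.get("k_avg", 6)),
        "sigma": float(config.get("sigma", 0.0)),
        "n_m": float(config.get("n_m", 1.6)),
    }
    b = float(config.get("b", 1.2))
    kappa = float(config.get("kappa", 0.1))
    method = config.get("method", "moea+knee")
    replicates = int(config.get("replicates", 1))
    master = int(config.get("seed", 0))
    lasso_lam = float(config.get("lasso_lam", 0.001))
    moea_cfg = MOEAConfig(**config.get("moea", {}))
    sweep = config.get("sweep") or {"variable": "n_m", "values": [base["n_m"]]}
    var = sweep["variable"]
    if var not in base:
        raise ValueError(f"sweep variable must be one of {sorted(base)}; got {var!r}")

    records = []
    for value in sweep["values"]:
        cell = dict(base)
        cell[var] = float(value)
        max_nm = max(cell["n_m"], base["n_m"]) if var != "n_m" else max(sweep["values"])
        for rep in range(replicates):
            rec = {"model": model, "n": n, var: cell[var], "replicate": rep,
                   "method": method, "error": ""}
            seed_net = np.random.SeedSequence([master, 101, rep]).generate_state(1)[0] % (2**31)
            seed_sim = np.random.SeedSequence([master, 211, rep]).generate_state(1)[0] % (2**31)
            seed_rec = np.random.SeedSequence([master, 307, rep]).generate_state(1)[0] % (2**31)
            try:
                net = _GENERATORS[model](n, cell["k_avg"], int(seed_net))
                rounds = int(np.floor(float(max_nm) * n + 0.5))
                trace = simulate(net, SimulationConfig(rounds=rounds, b=b, kappa=kappa,
                                                       seed=int(seed_sim)))
                trace = truncate_to_nm(trace, cell["n_m"])
                result = reconstruct_network(
                    trace, method, b=b, sigma=cell["sigma"], moea_config=moea_cfg,
                    lasso_lam=lasso_lam, seed=int(seed_rec),
                    truth=net if method == "moea+min_re" else None,
                )
                report = evaluate_result(result, net)
                rec.update({k.lower(): v for k, v in report.to_dict().items()})
            except Exception as exc:  # record and continue
                logger.exception("benchmark cell %s=%s replicate %d failed", var, value, rep)
                rec["error"] = str(exc)
            records.append(rec)
    return pd.DataFrame.from_records(records)


def summarize_benchmark(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean and std of every metric column."""
    metric_cols = [c for c in ("re", "tpr", "fpr", "precision", "auroc", "aupr")
                   if c in rows.columns]
    group_cols = [c for c in ("model", "n", "n_m", "sigma", "k_avg", "method")
                  if c in rows.columns]
    ok = rows[rows["error"] == ""] if "error" in rows.columns else rows
    return ok.groupby(group_cols)[metric_cols].agg(["mean", "std"]).reset_index()
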
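"""Per-node linear inverse problem built from an observed game trace.

For a focal agent i the payoff identity P_i(t) = sum_l x_il S_i(t)^T P S_l(t)
casts the hidden neighbor-weight row X_i as the solution of a linear system
Y_i = A_i X_i:  Y_i stacks i's observed payoffs, and each entry of A_i is the
pairwise game payoff D_{i,l}(t) computed from the observed strategies alone.
Measurement noise enters as additive Gaussian perturbations of Y_i only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .game_dynamics import GameTrace, PayoffMatrix

__all__ = ["LocalSystem", "build_local_system", "add_noise", "truncate_to_nm"]


@dataclass
class LocalSystem:
    """The inverse problem (Y, A) of one focal node.

    ``A`` has one row per round and one column per candidate neighbor
    (every agent except the focal node itself); entries lie in {0, 1, b}.
    ``candidate_ids`` labels A's columns with agent indices.
    """

    node: int
    Y: np.ndarray
    A: np.ndarray
    candidate_ids: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.candidate_ids = np.asarray(self.candidate_ids, dtype=int)
        if self.A.shape != (self.Y.shape[0], self.candidate_ids.shape[0]):
            raise ValueError("inconsistent LocalSystem shapes")

    @property
    def m(self) -> int:
        """Number of rounds (rows) in the system."""
        return self.Y.shape[0]

    @property
    def n_candidates(self) -> int:
        return self.A.shape[1]

    def embed(self, weights: np.ndarray, n_agents: int) -> np.ndarray:
        """Re-embed a candidate-space weight vector to length N with a
        structural zero at the focal node."""
        full = np.zeros(n_agents)
        full[self.candidate_ids] = weights
        return full

    def dump_text(self, path) -> None:
        """Debug dump: first column Y, remaining columns A."""
        np.savetxt(path, np.column_stack([self.Y, self.A]), delimiter="\t")


def build_local_system(trace: GameTrace, i: int, payoff_matrix: PayoffMatrix) -> LocalSystem:
    """Assemble (Y_i, A_i) for focal node ``i`` purely from the trace.

    Y[t] is i's recorded payoff in round t; A[t, l] = S_i(t)^T P S_l(t) for
    every candidate l != i.  The focal node's own column is excluded
    (x_ii = 0 by the adjacency convention; reported vectors are re-embedded
    with a structural zero via :meth:`LocalSystem.embed`).
    """
    n = trace.n_agents
    if not 0 <= i < n:
        raise IndexError(f"focal index {i} out of range for trace with {n} agents")
    others = np.delete(np.arange(n), i)
    P = payoff_matrix.entries
    s_i = trace.strategies[i]          # (m,)
    s_others = trace.strategies[others]  # (n-1, m)
    A = P[s_i[None, :], s_others].T    # (m, n-1)
    Y = trace.payoffs[i].copy()
    return LocalSystem(node=i, Y=Y, A=np.ascontiguousarray(A), candidate_ids=others)


def add_noise(system: LocalSystem, sigma: float, seed=0) -> LocalSystem:
    """Return a copy with Y perturbed by i.i.d. Normal(0, sigma^2); A untouched."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0; got {sigma}")
    if sigma == 0:
        return LocalSystem(system.node, system.Y.copy(), system.A, system.candidate_ids)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, size=system.Y.shape)
    return LocalSystem(system.node, system.Y + eps, system.A, system.candidate_ids)


def truncate_to_nm(trace: GameTrace, n_m_target: float) -> GameTrace:
    """Keep the first round(n_m_target * N) rounds of a trace.

    The relative data length N_M = M / N is the natural unit in which data
    requirements are expressed; fractional products are rounded half up.
    """
    if n_m_target <= 0:
        raise ValueError("n_m_target must be positive")
    n = trace.n_agents
    m = int(math.floor(n_m_target * n + 0.5))  # round half up
    if m < 1:
        raise ValueError(f"n_m_target={n_m_target} yields zero rounds for N={n}")
    if m > trace.n_rounds:
        raise ValueError(
            f"requested {m} rounds (n_m={n_m_target}, N={n}) but trace has only {trace.n_rounds}"
        )
    return GameTrace(strategies=trace.strategies[:, :m].copy(), payoffs=trace.payoffs[:, :m].copy())
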
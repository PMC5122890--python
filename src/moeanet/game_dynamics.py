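"""Spatial prisoner's-dilemma dynamics on weighted networks.

Agents sit on the nodes of a weighted network and repeatedly play a
two-strategy game (cooperate ``C`` / defect ``D``) with every neighbor.
Per-round payoffs are weighted sums of pairwise game payoffs; between
rounds each agent imitates a uniformly random neighbor with a probability
given by the Fermi rule.  The recorded strategy/payoff time series is the
*only* observable downstream reconstruction modules may use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "C",
    "D",
    "STRATEGY_LABELS",
    "strategy_vector",
    "PayoffMatrix",
    "make_payoff_matrix",
    "pairwise_payoff",
    "total_payoff",
    "fermi_update_probability",
    "SimulationConfig",
    "GameTrace",
    "simulate",
    "write_trace",
    "read_trace",
]

# integer strategy codes used throughout: row/column indices into the payoff matrix
C: int = 0
D: int = 1
STRATEGY_LABELS: tuple[str, str] = ("C", "D")

_LABEL_TO_CODE = {"C": C, "D": D, C: C, D: D}


def strategy_vector(s: int | str) -> np.ndarray:
    """Unit indicator vector of a strategy: C -> (1, 0)^T, D -> (0, 1)^T."""
    code = _strategy_code(s)
    v = np.zeros(2)
    v[code] = 1.0
    return v


def _strategy_code(s: int | str) -> int:
    try:
        return _LABEL_TO_CODE[s]
    except (KeyError, TypeError):
        raise ValueError(f"unknown strategy {s!r}; expected 'C', 'D', 0 or 1") from None


@dataclass(frozen=True)
class PayoffMatrix:
    """2x2 prisoner's-dilemma reward structure parameterized by the temptation b.

    Rows index the focal strategy (C then D), columns the opponent.  With the
    spatial-game convention R = 1, Pu = Su = 0 and Te = b the matrix is
    ``[[1, 0], [b, 0]]`` and satisfies Te > R > Pu >= Su and 2R > Te + Su.
    """

    b: float
    entries: np.ndarray = field(repr=False)

    @property
    def temptation(self) -> float:
        return self.b

    @property
    def reward(self) -> float:
        return float(self.entries[C, C])


def make_payoff_matrix(b: float) -> PayoffMatrix:
    """Build the PDG payoff matrix for temptation parameter ``b``.

    Raises ``ValueError`` unless 1 < b < 2 (the weak prisoner's-dilemma
    regime; at b = 1 defection loses its temptation edge, at b >= 2 the
    social-dilemma ordering 2R > Te + Su breaks).
    """
    b = float(b)
    if not 1.0 < b < 2.0:
        raise ValueError(f"temptation parameter b must lie in the open interval (1, 2); got {b}")
    return PayoffMatrix(b=b, entries=np.array([[1.0, 0.0], [b, 0.0]]))


def pairwise_payoff(s_x: int | str, s_y: int | str, payoff_matrix: PayoffMatrix) -> float:
    """Payoff S_x^T P S_y of the focal strategy ``s_x`` against opponent ``s_y``."""
    return float(payoff_matrix.entries[_strategy_code(s_x), _strategy_code(s_y)])


def total_payoff(i, strategies_t, network, payoff_matrix: PayoffMatrix) -> float:
    """Round payoff of agent ``i``: the weight-weighted sum of pairwise payoffs.

    ``strategies_t`` is the full strategy assignment in force during the round
    (labels or codes, length N); the sum runs over all l != i with x_il > 0.
    """
    X = network.adjacency
    n = X.shape[0]
    i = int(i)
    if not 0 <= i < n:
        raise IndexError(f"agent index {i} out of range for network of size {n}")
    codes = np.asarray([_strategy_code(s) for s in strategies_t])
    if codes.shape[0] != n:
        raise ValueError("strategy assignment does not cover all agents")
    row = payoff_matrix.entries[codes[i], codes]  # pairwise payoffs of i against everyone
    row = row.copy()
    row[i] = 0.0  # no self-games
    return float(X[i] @ row)


def fermi_update_probability(p_i: float, p_j: float, kappa: float) -> float:
    """Probability that agent i adopts agent j's strategy under the Fermi rule.

    W(S_i <- S_j) = 1 / (1 + exp((P_i - P_j) / kappa)).  ``kappa`` sets the
    noise of rationality: small kappa makes imitation nearly deterministic in
    the payoff difference.  The exponent is clamped to avoid overflow.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be positive; got {kappa}")
    z = (p_i - p_j) / kappa
    z = min(max(z, -700.0), 700.0)
    return 1.0 / (1.0 + np.exp(z))


@dataclass
class SimulationConfig:
    """Parameters of one evolutionary-game run.

    ``episode_rounds`` controls the observation protocol: every that many
    rounds the strategies are redrawn i.i.d. Bernoulli(init_coop_fraction)
    and the game restarts from the fresh configuration.  The spatial PDG
    under Fermi imitation has absorbing homogeneous states that it reaches
    quickly on dense networks, after which the recorded payoffs carry no
    information about the hidden weights; observing several short episodes
    keeps the strategy configurations diverse and the per-node inverse
    problems well-posed.  The default of 6 rounds sits just below the
    typical time to quasi-absorption of the synchronous Fermi dynamics at
    the mean degrees studied here (~5-15 rounds), so nearly every recorded
    round carries structural information.  Set it to ``None`` to observe
    one uninterrupted run of the raw dynamics.
    """

    rounds: int
    b: float = 1.2
    kappa: float = 0.1
    init_coop_fraction: float = 0.5
    update_scheme: str = "synchronous"
    episode_rounds: int | None = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError(f"rounds must be >= 1; got {self.rounds}")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive; got {self.kappa}")
        if not 0.0 <= self.init_coop_fraction <= 1.0:
            raise ValueError("init_coop_fraction must lie in [0, 1]")
        if self.update_scheme != "synchronous":
            raise ValueError(f"unsupported update scheme {self.update_scheme!r}")
        if self.episode_rounds is not None and self.episode_rounds < 1:
            raise ValueError("episode_rounds must be >= 1 or None")


@dataclass
class GameTrace:
    """Observed strategy and payoff time series for all agents.

    ``strategies`` is an N x M array of codes (0 = C, 1 = D), ``payoffs``
    the matching N x M array of round payoffs, column t holding the payoffs
    earned under the strategies of column t.
    """

    strategies: np.ndarray
    payoffs: np.ndarray

    def __post_init__(self) -> None:
        self.strategies = np.asarray(self.strategies, dtype=np.int8)
        self.payoffs = np.asarray(self.payoffs, dtype=float)
        if self.strategies.shape != self.payoffs.shape:
            raise ValueError("strategies and payoffs must have identical N x M shape")

    @property
    def n_agents(self) -> int:
        return self.strategies.shape[0]

    @property
    def n_rounds(self) -> int:
        return self.strategies.shape[1]

    @property
    def n_m(self) -> float:
        """Relative data length: rounds M divided by network size N."""
        return self.n_rounds / self.n_agents


def simulate(network, config: SimulationConfig) -> GameTrace:
    """Run the spatial PDG and record the full strategy/payoff trace.

    Updating is synchronous: all round-t payoffs are computed from the
    round-t strategies, then every agent simultaneously picks one uniformly
    random neighbor and imitates it with Fermi probability.  Isolated nodes
    keep their strategy forever (payoff 0, nobody to imitate) and trigger a
    warning.  The run is fully reproducible from ``config.seed``.
    """
    X = network.adjacency
    n = X.shape[0]
    if n < 2:
        raise ValueError("network must have at least 2 nodes")
    pm = make_payoff_matrix(config.b)
    P = pm.entries
    rng = np.random.default_rng(config.seed)

    neighbors = [np.flatnonzero(X[i] > 0) for i in range(n)]
    isolated = [i for i, nb in enumerate(neighbors) if nb.size == 0]
    if isolated:
        warnings.warn(
            f"network has isolated node(s) {isolated}: payoff 0, strategy frozen",
            stacklevel=2,
        )

    m = config.rounds
    strategies = np.empty((n, m), dtype=np.int8)
    payoffs = np.empty((n, m), dtype=float)

    s = np.empty(n, dtype=np.int8)
    for t in range(m):
        if config.episode_rounds is None:
            if t == 0:
                s = (rng.random(n) >= config.init_coop_fraction).astype(np.int8)
        elif t % config.episode_rounds == 0:
            # fresh episode: redraw strategies i.i.d. (D where draw >= fraction)
            s = (rng.random(n) >= config.init_coop_fraction).astype(np.int8)
        pair = P[s[:, None], s[None, :]]  # pairwise game payoffs under current strategies
        pay = (X * pair).sum(axis=1)
        strategies[:, t] = s
        payoffs[:, t] = pay
        # synchronous Fermi imitation of one uniformly random neighbor
        pick = rng.random(n)
        accept = rng.random(n)
        s_new = s.copy()
        for i in range(n):
            nb = neighbors[i]
            if nb.size == 0:
                continue
            j = nb[min(int(pick[i] * nb.size), nb.size - 1)]
            if accept[i] < fermi_update_probability(pay[i], pay[j], config.kappa):
                s_new[i] = s[j]
        s = s_new

    return GameTrace(strategies=strategies, payoffs=payoffs)


def write_trace(trace: GameTrace, path) -> None:
    """Write a trace as canonical TSV: round, agent_id, strategy (C|D), payoff."""
    n, m = trace.n_agents, trace.n_rounds
    rounds = np.repeat(np.arange(m), n)
    agents = np.tile(np.arange(n), m)
    labels = np.asarray(STRATEGY_LABELS)[trace.strategies.T.reshape(-1)]
    df = pd.DataFrame(
        {
            "round": rounds,
            "agent_id": agents,
            "strategy": labels,
            # repr round-trips float64 exactly
            "payoff": [repr(float(v)) for v in trace.payoffs.T.reshape(-1)],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_trace(path) -> GameTrace:
    """Read a TSV trace written by :func:`write_trace`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"round", "agent_id", "strategy", "payoff"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace file missing columns {sorted(required - set(df.columns))}")
    n = int(df["agent_id"].max()) + 1
    m = int(df["round"].max()) + 1
    strategies = np.empty((n, m), dtype=np.int8)
    payoffs = np.empty((n, m), dtype=float)
    codes = df["strategy"].map({"C": C, "D": D})
    if codes.isna().any():
        bad = df.loc[codes.isna(), "strategy"].iloc[0]
        raise ValueError(f"unknown strategy label {bad!r} in trace file")
    strategies[df["agent_id"], df["round"]] = codes
    payoffs[df["agent_id"], df["round"]] = df["payoff"]
    return GameTrace(strategies=strategies, payoffs=payoffs)
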
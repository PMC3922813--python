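"""Stochastic agent-based simulation of the strategy/link co-evolution.

An explicit two-group network evolves by a sequence of events: with
probability W a strategy update (uniform focal player, uniform neighbor
of it, the focal player's strategy replaces the neighbor's with Fermi
probability on the accumulated-payoff difference), otherwise a link
event (uniform link; it breaks with its type's probability k_e, one
endpoint is retained uniformly and rewires — inside its own group with
probability p, to the other group otherwise — to a uniform eligible
non-neighbor).  The total link count is conserved at every event and the
graph stays simple; a fixed seed makes the whole trajectory
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import _kernels
from .game import LINK_TYPE_LABELS, ModelParams, PayoffScheme

__all__ = [
    "InterdependentNetwork",
    "SimulationParams",
    "SimulationRecord",
    "init_network",
    "accumulated_payoff",
    "run",
    "final_cooperation",
    "link_type_frequency_stats",
]


@dataclass
class InterdependentNetwork:
    """Two-group network with (group, strategy) node labels.

    ``group`` and ``strategy`` are int8 arrays (group 0/1 internally for
    groups 1/2; strategy 0=C, 1=D); ``edges`` is an (L, 2) int array and
    ``adj`` the dense adjacency byte matrix kept in sync with it.
    """

    group: np.ndarray
    strategy: np.ndarray
    edges: np.ndarray
    adj: np.ndarray = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return self.group.shape[0]

    @property
    def n_links(self) -> int:
        return self.edges.shape[0]

    @property
    def degree(self) -> np.ndarray:
        return self.adj.sum(axis=1).astype(np.int64)

    def cooperator_fractions(self) -> tuple[float, float]:
        g, s = self.group, self.strategy
        return (
            float(np.mean(s[g == 0] == 0)),
            float(np.mean(s[g == 1] == 0)),
        )

    def link_type_counts(self) -> np.ndarray:
        """Full recount of the ten link-type counts in canonical order."""
        counts = np.zeros(10, dtype=np.int64)
        for u, v in self.edges:
            counts[
                _kernels.link_type_index(
                    self.strategy[u], self.group[u], self.strategy[v], self.group[v]
                )
            ] += 1
        return counts

    def validate(self) -> None:
        """Check simple-graph and cache-consistency invariants."""
        u, v = self.edges[:, 0], self.edges[:, 1]
        if np.any(u == v):
            raise AssertionError("self-loop present")
        keys = np.minimum(u, v) * self.n_nodes + np.maximum(u, v)
        if np.unique(keys).size != keys.size:
            raise AssertionError("duplicate edge present")
        adj = np.zeros_like(self.adj)
        adj[u, v] = 1
        adj[v, u] = 1
        if not np.array_equal(adj, self.adj):
            raise AssertionError("adjacency matrix out of sync with edge list")

    def copy(self) -> "InterdependentNetwork":
        return InterdependentNetwork(
            self.group.copy(), self.strategy.copy(), self.edges.copy(), self.adj.copy()
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i in range(self.n_nodes):
            g.add_node(
                i,
                group=int(self.group[i]) + 1,
                strategy="C" if self.strategy[i] == 0 else "D",
            )
        g.add_edges_from(map(tuple, self.edges))
        return g

    def write_edgelist(self, path: str | Path) -> None:
        """Plain-text node table + edge list (group/strategy attributes)."""
        with open(path, "w") as fh:
            fh.write("# node group strategy\n")
            for i in range(self.n_nodes):
                s = "C" if self.strategy[i] == 0 else "D"
                fh.write(f"n {i} {int(self.group[i]) + 1} {s}\n")
            fh.write("# edge u v\n")
            for u, v in self.edges:
                fh.write(f"e {u} {v}\n")


def init_network(
    config, initial_coop_fraction, seed: int
) -> InterdependentNetwork:
    """Uniform random network with the exact prescribed link counts.

    Each intra-group compartment is a uniform G(N, L) simple graph and
    the inter-group compartment a uniform bipartite graph with exactly
    L12 edges.  Strategies are placed by exact count: floor(fraction*N)
    cooperators per group at uniformly random positions.
    ``initial_coop_fraction`` may be a scalar or a per-group pair.
    """
    f = np.broadcast_to(np.asarray(initial_coop_fraction, dtype=float), (2,))
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("initial cooperator fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    s1, s2, s3, s4, s5 = (int(x) for x in rng.integers(0, 2**31 - 1, size=5))
    N1, N2 = config.N1, config.N2
    N = N1 + N2
    group = np.zeros(N, dtype=np.int8)
    group[N1:] = 1
    strategy = np.ones(N, dtype=np.int8)  # D everywhere, then place Cs
    for g, (n, frac, s) in enumerate(((N1, f[0], s1), (N2, f[1], s2))):
        n_c = int(np.floor(frac * n))
        pos = np.random.default_rng(s).permutation(n)[:n_c]
        strategy[pos + (N1 if g == 1 else 0)] = 0
    g1 = nx.gnm_random_graph(N1, config.L1, seed=s3)
    g2 = nx.gnm_random_graph(N2, config.L2, seed=s4)
    gx = nx.bipartite.gnmk_random_graph(N1, N2, config.L12, seed=s5)
    edges = np.array(
        [(u, v) for u, v in g1.edges()]
        + [(u + N1, v + N1) for u, v in g2.edges()]
        + [(u, v) for u, v in gx.edges()],
        dtype=np.int64,
    ).reshape(config.L, 2)
    adj = np.zeros((N, N), dtype=np.uint8)
    if config.L:
        adj[edges[:, 0], edges[:, 1]] = 1
        adj[edges[:, 1], edges[:, 0]] = 1
    net = InterdependentNetwork(group, strategy, edges, adj)
    net.validate()
    return net


def accumulated_payoff(
    net: InterdependentNetwork, node: int, payoff: PayoffScheme
) -> float:
    """Sum of donation-game payoffs against all current neighbors.

    Neighbors in the same group and the other group count alike; an
    isolated node earns 0.
    """
    M = payoff.matrix
    s = net.strategy
    neighbors = np.nonzero(net.adj[node])[0]
    return float(sum(M[s[node], s[j]] for j in neighbors))


_IMITATION_MODES = {"neighbor": 0, "link": 1, "global": 2}


@dataclass(frozen=True)
class SimulationParams:
    """Full specification of one stochastic run.

    ``imitation`` selects how the compared pair of a strategy update is
    drawn.  "neighbor": uniform focal player, uniform neighbor of it, the
    focal player's strategy tries to replace the neighbor's.  "link":
    uniform link, fair coin for who is focal.  "global": uniform target
    player, model player drawn from the target's own group with
    probability p and from the other group otherwise — the microscopic
    realization of the mean-field transition probabilities, in which the
    network determines payoffs while comparison is population-wide.  The
    neighbor and link rules condition the compared payoffs on adjacency,
    which at finite degree carries a systematic drift component absent
    from the population-level theory (see docs/methods.md).
    """

    model: ModelParams
    initial_coop_fraction: tuple[float, float] | float = 0.5
    horizon: int = 100_000
    seed: int = 0
    sample_every: int | None = None
    stop_when_monomorphic: bool = False
    focal_replaces_neighbor: bool = True
    imitation: str = "neighbor"  # "neighbor" | "link" | "global"

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        if self.imitation not in _IMITATION_MODES:
            raise ValueError(
                f"imitation must be one of {sorted(_IMITATION_MODES)}"
            )

    @property
    def stride(self) -> int:
        if self.sample_every is not None:
            if self.sample_every <= 0:
                raise ValueError("sample_every must be > 0")
            return self.sample_every
        return max(1, self.horizon // 500)


@dataclass(frozen=True)
class SimulationRecord:
    """Sampled time series plus the final network."""

    times: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    link_type_counts: np.ndarray  # (S, 10)
    final: InterdependentNetwork
    n_events: int
    early_stopped: bool

    @property
    def final_cooperation(self) -> float:
        """Terminal cooperator fraction of the whole population."""
        s = self.final.strategy
        return float(np.mean(s == 0))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"event": self.times, "x1": self.x1, "x2": self.x2})
        for i, lab in enumerate(LINK_TYPE_LABELS):
            df[lab] = self.link_type_counts[:, i]
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def run(
    params: SimulationParams, net: InterdependentNetwork | None = None
) -> SimulationRecord:
    """Simulate the co-evolution process; deterministic given (params, seed).

    The provided network (or a fresh one drawn from the init seed) is
    copied, never mutated.
    """
    model = params.model
    cfg = model.config
    if net is None:
        net = init_network(cfg, params.initial_coop_fraction, params.seed)
    work = net.copy()
    stride = params.stride
    n_samples = params.horizon // stride + 1
    rec_x1 = np.empty(n_samples)
    rec_x2 = np.empty(n_samples)
    rec_counts = np.empty((n_samples, 10), dtype=np.int64)
    g_nodes = np.concatenate(
        [np.nonzero(work.group == 0)[0], np.nonzero(work.group == 1)[0]]
    ).astype(np.int64)
    g_offsets = np.array([0, cfg.N1, cfg.N1 + cfg.N2], dtype=np.int64)
    deg = work.degree
    type_counts = work.link_type_counts()
    n_events = _kernels.simulate_kernel(
        work.group,
        work.strategy,
        work.edges,
        work.adj,
        deg,
        type_counts,
        g_nodes,
        g_offsets,
        model.payoff.matrix,
        model.schedule.k_vector(),
        float(cfg.p),
        float(cfg.W),
        float(cfg.w),
        int(params.horizon),
        int(stride),
        int(params.seed) % (2**31 - 1),
        params.stop_when_monomorphic,
        params.focal_replaces_neighbor,
        _IMITATION_MODES[params.imitation],
        rec_x1,
        rec_x2,
        rec_counts,
    )
    times = np.arange(n_samples, dtype=np.int64) * stride
    return SimulationRecord(
        times=times,
        x1=rec_x1,
        x2=rec_x2,
        link_type_counts=rec_counts,
        final=work,
        n_events=int(n_events),
        early_stopped=int(n_events) < params.horizon,
    )


def final_cooperation(
    params: SimulationParams, replicates: int
) -> tuple[float, float, np.ndarray]:
    """Mean and standard error of the terminal cooperator fraction.

    Runs ``replicates`` independent simulations (replicate r reuses the
    base parameters with seed + r) and averages the terminal whole-
    population cooperator fraction.  Returns (mean, stderr, per-replicate
    values).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    finals = np.empty(replicates)
    for r in range(replicates):
        rec = run(
            SimulationParams(
                model=params.model,
                initial_coop_fraction=params.initial_coop_fraction,
                horizon=params.horizon,
                seed=params.seed + r,
                sample_every=params.sample_every,
                stop_when_monomorphic=params.stop_when_monomorphic,
                focal_replaces_neighbor=params.focal_replaces_neighbor,
                imitation=params.imitation,
            )
        )
        finals[r] = rec.final_cooperation
    stderr = float(finals.std(ddof=1) / np.sqrt(replicates)) if replicates > 1 else 0.0
    return float(finals.mean()), stderr, finals


def link_type_frequency_stats(
    record: SimulationRecord, burn_in: int, n_batches: int = 25
) -> pd.DataFrame:
    """Time-averaged link-type frequencies with batch-means standard errors.

    Drops samples with event index < ``burn_in``, splits the rest into
    ``n_batches`` contiguous batches and reports, per link type, the mean
    frequency and the standard error of the batch means (which absorbs
    autocorrelation when batches are long compared with the chain's
    relaxation time).
    """
    keep = record.times >= burn_in
    freqs = record.link_type_counts[keep] / record.final.n_links
    n = freqs.shape[0]
    if n < n_batches:
        raise ValueError("not enough post-burn-in samples for batching")
    usable = n - n % n_batches
    batches = freqs[:usable].reshape(n_batches, -1, 10).mean(axis=1)
    mean = freqs.mean(axis=0)
    se = batches.std(axis=0, ddof=1) / np.sqrt(n_batches)
    return pd.DataFrame(
        {"mean": mean, "stderr": se}, index=list(LINK_TYPE_LABELS)
    ).rename_axis("link_type")
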
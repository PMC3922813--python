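"""Embedded Markov chain over the ten link types.

With strategies frozen at cooperator frequencies (x1, x2), the linking
dynamics acts on a single selected link: a link of type e survives with
probability 1 - k_e; otherwise one endpoint (chosen uniformly) is
retained and rewires — with probability p to a uniformly random member
of its own group, to the other group otherwise — and the new partner is
a cooperator with the frequency of its group.  Tracking the type of one
link under repeated selections gives a 10-state Markov chain.

Because the jump destination depends only on the retained endpoint, the
jump chain factorizes: the group pair performs an autonomous walk with
stationary weights (p/2, p/2, 1-p) over (intra-1, intra-2, inter), and
endpoint strategies are independent Bernoulli draws of their group's
cooperator frequency.  Weighting each type by its mean holding time
1/k_e yields the closed-form stationary distribution

    pi_e = (1/Z) * g_e / k_e,
    g_e  = (p/2) (2 - delta_ss') x_g^(s) x_g^(s')   (intra-group g)
         = (1-p) x_1^(s) x_2^(s')                   (inter-group)

with x_g^(C) = x_g, x_g^(D) = 1 - x_g and Z the normalization.  This is
the mean-field approximation of the network process: exclusion of
current neighbors (an O(degree/N) effect) is ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .game import (
    LINK_TYPES,
    LINK_TYPE_LABELS,
    BreakingSchedule,
    LinkType,
    PopulationConfig,
)

__all__ = [
    "LinkChainParams",
    "TransitionMatrix",
    "LinkTypeDistribution",
    "build_transition_matrix",
    "stationary_distribution_numeric",
    "stationary_distribution_closed_form",
    "expected_link_counts",
]

_STATIONARITY_TOL = 1e-10


@dataclass(frozen=True)
class LinkChainParams:
    """Frozen strategy frequencies plus linking parameters.

    With ``finite_population=True`` (requires ``config``) the new-partner
    pool accounts for the retained endpoint excluding itself within its
    own group, an O(1/N) correction to the Bernoulli mean field: the
    intra-group pair weights then become without-replacement
    (hypergeometric) frequencies of the cooperator counts x_g N_g.
    """

    x1: float
    x2: float
    p: float
    schedule: BreakingSchedule
    config: PopulationConfig | None = None
    finite_population: bool = False

    def __post_init__(self) -> None:
        for name in ("x1", "x2", "p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.finite_population and self.config is None:
            raise ValueError("finite_population requires a PopulationConfig")

    def _counts(self, group: int) -> tuple[float, float]:
        n = self.config.N1 if group == 1 else self.config.N2
        x = self.x1 if group == 1 else self.x2
        return x * n, n

    def strategy_weight(self, strategy: str, group: int) -> float:
        x = self.x1 if group == 1 else self.x2
        return x if strategy == "C" else 1.0 - x

    def partner_weight(
        self, strategy: str, group: int, retained: tuple[str, int]
    ) -> float:
        """Probability the new partner in ``group`` carries ``strategy``.

        Mean field: the group's strategy frequency.  Finite population:
        the retained endpoint is excluded from its own group's pool.
        """
        if not self.finite_population:
            return self.strategy_weight(strategy, group)
        c, n = self._counts(group)
        if retained[1] == group:
            c_pool = c - (1.0 if retained[0] == "C" else 0.0)
            n_pool = n - 1.0
        else:
            c_pool, n_pool = c, n
        w = c_pool / n_pool if strategy == "C" else (n_pool - c_pool) / n_pool
        return min(max(w, 0.0), 1.0)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 10x10 matrix in canonical link-type order."""

    P: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (10, 10):
            raise ValueError("transition matrix must be 10x10")
        if np.any(P < -1e-15):
            raise ValueError("transition matrix has negative entries")
        if np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("transition matrix rows must sum to 1")
        object.__setattr__(self, "P", P)


@dataclass(frozen=True)
class LinkTypeDistribution:
    """Probability vector over the ten link types.

    ``Z`` is the closed-form normalization (sum of g_e / k_e) when the
    distribution came from the closed form, else NaN.  ``reducible`` is
    set when a boundary frequency (x in {0, 1}) collapses the support and
    the distribution is restricted to the recurrent class.
    """

    pi: np.ndarray
    Z: float = float("nan")
    reducible: bool = False
    labels: tuple[str, ...] = dc_field(default=LINK_TYPE_LABELS)

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (10,):
            raise ValueError("pi must have length 10")
        if np.any(pi < -1e-12) or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must be a normalized probability vector")
        object.__setattr__(self, "pi", pi)

    def __getitem__(self, t: LinkType | int | str) -> float:
        if isinstance(t, LinkType):
            return float(self.pi[LINK_TYPES.index(t)])
        if isinstance(t, str):
            return float(self.pi[self.labels.index(t)])
        return float(self.pi[t])

    def to_series(self) -> pd.Series:
        return pd.Series(self.pi, index=list(self.labels), name="pi")

    def to_csv(self, path: str | Path) -> None:
        self.to_series().rename_axis("link_type").to_csv(path)


def _jump_weights(params: LinkChainParams) -> np.ndarray:
    """Stationary weights g_e of the k-free jump chain (sum to 1).

    Mean field: Bernoulli product weights.  Finite population: intra
    pairs are drawn without replacement from the group (hypergeometric),
    which is exactly the stationary distribution of the self-exclusion-
    corrected jump kernel.
    """
    p = params.p
    g = np.empty(10)
    for i, t in enumerate(LINK_TYPES):
        (sa, ga), (sb, gb) = t.endpoint_a, t.endpoint_b
        if t.is_intra:
            mult = 1.0 if sa == sb else 2.0
            if params.finite_population:
                c, n = params._counts(ga)
                ca = c if sa == "C" else n - c
                cb = (c if sb == "C" else n - c) - (1.0 if sa == sb else 0.0)
                w = max(ca * cb, 0.0) / (n * (n - 1.0))
            else:
                w = params.strategy_weight(sa, ga) * params.strategy_weight(sb, gb)
            g[i] = (p / 2.0) * mult * w
        else:
            w = params.strategy_weight(sa, ga) * params.strategy_weight(sb, gb)
            g[i] = (1.0 - p) * w
    return g


def build_transition_matrix(params: LinkChainParams) -> TransitionMatrix:
    """One-selection transition matrix of the link-type chain.

    Entry (e, e'): probability that a selected link of type e is of type
    e' afterwards.  A link survives with probability 1 - k_e (diagonal
    mass), otherwise each endpoint is retained with probability 1/2 and
    the new partner's (group, strategy) is drawn per the intra-group bias
    p and the group frequencies.
    """
    kvec = params.schedule.k_vector()
    p = params.p
    P = np.zeros((10, 10))
    for i, t in enumerate(LINK_TYPES):
        P[i, i] += 1.0 - kvec[i]
        for retained in (t.endpoint_a, t.endpoint_b):
            s_r, g_r = retained
            for g_new in (1, 2):
                group_prob = p if g_new == g_r else 1.0 - p
                if group_prob == 0.0:
                    continue
                for s_new in ("C", "D"):
                    w = group_prob * params.partner_weight(s_new, g_new, retained)
                    if w == 0.0:
                        continue
                    j = LINK_TYPES.index(LinkType.of(retained, (s_new, g_new)))
                    P[i, j] += kvec[i] * 0.5 * w
    return TransitionMatrix(P)


def _recurrent_states(P: np.ndarray) -> np.ndarray:
    """Boolean mask of states in closed communicating classes."""
    adj = (P > 0.0).astype(np.int8)
    n_comp, comp = connected_components(adj, directed=True, connection="strong")
    closed = np.ones(n_comp, dtype=bool)
    for i in range(P.shape[0]):
        for j in np.nonzero(adj[i])[0]:
            if comp[j] != comp[i]:
                closed[comp[i]] = False
    n_closed = np.unique(comp[closed[comp]]).size
    if n_closed == 0:  # cannot happen for a finite chain
        raise RuntimeError("no recurrent class found")
    if n_closed > 1:
        raise ValueError(
            "chain has multiple closed classes; stationary distribution not unique"
        )
    return closed[comp]


def stationary_distribution_numeric(T: TransitionMatrix) -> LinkTypeDistribution:
    """Left fixed vector of T via a linear solve on the recurrent class.

    Raises ``ValueError`` when the stationary distribution is not unique
    (e.g. T = identity); returns a flagged distribution restricted to the
    recurrent class when transient states exist (boundary frequencies).
    """
    P = T.P
    mask = _recurrent_states(P)
    idx = np.nonzero(mask)[0]
    Q = P[np.ix_(idx, idx)]
    n = Q.shape[0]
    # solve pi (Q - I) = 0 with sum(pi) = 1, as an overdetermined system
    A = np.vstack([(Q - np.eye(n)).T, np.ones((1, n))])
    rhs = np.zeros(n + 1)
    rhs[-1] = 1.0
    pi_small, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    pi = np.zeros(10)
    pi[idx] = np.clip(pi_small, 0.0, None)
    pi /= pi.sum()
    residual = np.max(np.abs(pi @ P - pi))
    if residual > _STATIONARITY_TOL:
        raise ValueError(f"stationary solve failed, residual {residual:.2e}")
    reducible = not mask.all()
    if reducible:
        warnings.warn(
            "link-type chain is reducible; distribution restricted to the "
            "recurrent class",
            stacklevel=2,
        )
    return LinkTypeDistribution(pi=pi, reducible=reducible)


def stationary_distribution_closed_form(
    params: LinkChainParams,
) -> LinkTypeDistribution:
    """Closed-form stationary distribution pi_e = g_e / (k_e Z).

    g_e is the jump-chain weight (module docstring) and Z = sum_e g_e/k_e.
    Support collapses automatically at boundary frequencies; the result is
    then flagged reducible.
    """
    params.schedule.require_positive()
    g = _jump_weights(params)
    kvec = params.schedule.k_vector()
    unnorm = g / kvec
    Z = unnorm.sum()
    if Z <= 0.0:
        raise ValueError("degenerate parameters: empty stationary support")
    pi = unnorm / Z
    return LinkTypeDistribution(pi=pi, Z=float(Z), reducible=bool(np.any(g == 0.0)))


def expected_link_counts(
    pi: LinkTypeDistribution | np.ndarray, L: float
) -> np.ndarray:
    """Expected number of links of each type: L * pi (sums to L exactly)."""
    vec = pi.pi if isinstance(pi, LinkTypeDistribution) else np.asarray(pi, float)
    if L < 0:
        raise ValueError("total link count must be >= 0")
    counts = L * vec
    # guard against accumulated rounding so the counts sum to L exactly
    if counts.sum() != L and counts.sum() > 0:
        counts *= L / counts.sum()
    return counts
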
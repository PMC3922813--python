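"""Game parameters, link-type algebra and payoff matrices.

Two interacting groups play a donation-game prisoner's dilemma: a
cooperator (C) pays a cost ``c`` to hand its opponent a benefit ``b``,
a defector (D) pays and hands nothing.  Strategies are indexed C=0, D=1
throughout, so the payoff matrix in (C, D) ordering is::

    [[b - c, -c],
     [b,      0]]

which satisfies the PD ordering T > R > P > S with T=b, R=b-c, P=0, S=-c.

Links carry a type given by the (strategy, group) labels of their two
endpoints; with two strategies and two groups there are exactly ten
unordered types.  Each strategy pair has a breaking probability
``k_CC, k_CD, k_DD``; the inverse of the breaking probability is the
average lifetime (interaction rate) of a link of that pair, and dividing
the payoff matrix entrywise by it yields the effective ("rescaled") game
played on the co-evolving network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "C",
    "D",
    "STRATEGIES",
    "LinkType",
    "LINK_TYPES",
    "enumerate_link_types",
    "PayoffScheme",
    "build_payoff_matrix",
    "BreakingSchedule",
    "rescale_payoff_matrix",
    "PopulationConfig",
    "ModelParams",
    "load_params",
]

C = "C"
D = "D"
STRATEGIES = (C, D)
_STRAT_INDEX = {C: 0, D: 1}


@dataclass(frozen=True, order=True)
class LinkType:
    """Unordered (strategy, group) pair label carried by a link.

    Instances are canonical: endpoints are sorted by (group, strategy index),
    so the group-1 endpoint comes first for inter-group types and C precedes
    D within a group.  ``LinkType.of`` canonicalizes any endpoint order.
    """

    endpoint_a: tuple[str, int]
    endpoint_b: tuple[str, int]

    @staticmethod
    def of(a: tuple[str, int], b: tuple[str, int]) -> "LinkType":
        for s, g in (a, b):
            if s not in _STRAT_INDEX or g not in (1, 2):
                raise ValueError(f"bad endpoint label {(s, g)!r}")
        key = lambda e: (e[1], _STRAT_INDEX[e[0]])
        a, b = sorted((tuple(a), tuple(b)), key=key)
        return LinkType(a, b)

    @property
    def strategy_pair(self) -> str:
        """'CC', 'CD' or 'DD' (unordered)."""
        i, j = sorted((_STRAT_INDEX[self.endpoint_a[0]], _STRAT_INDEX[self.endpoint_b[0]]))
        return STRATEGIES[i] + STRATEGIES[j]

    @property
    def groups(self) -> tuple[int, int]:
        return (self.endpoint_a[1], self.endpoint_b[1])

    @property
    def is_intra(self) -> bool:
        return self.endpoint_a[1] == self.endpoint_b[1]

    @property
    def label(self) -> str:
        """Canonical string label, e.g. 'C1D2'."""
        (sa, ga), (sb, gb) = self.endpoint_a, self.endpoint_b
        return f"{sa}{ga}{sb}{gb}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def enumerate_link_types() -> list[LinkType]:
    """The ten link types in canonical order.

    Ordering: intra-group-1 (CC, CD, DD), intra-group-2 (CC, CD, DD),
    inter-group (C1C2, C1D2, D1C2, D1D2).  Stable across runs; this is
    the index set of the link-type Markov chain and of every exported
    count vector.
    """
    intra = lambda g: [
        LinkType.of((C, g), (C, g)),
        LinkType.of((C, g), (D, g)),
        LinkType.of((D, g), (D, g)),
    ]
    inter = [LinkType.of((s1, 1), (s2, 2)) for s1 in STRATEGIES for s2 in STRATEGIES]
    return intra(1) + intra(2) + inter


LINK_TYPES: tuple[LinkType, ...] = tuple(enumerate_link_types())
LINK_TYPE_LABELS: tuple[str, ...] = tuple(t.label for t in LINK_TYPES)
LINK_TYPE_INDEX: dict[LinkType, int] = {t: i for i, t in enumerate(LINK_TYPES)}


def build_payoff_matrix(b: float, c: float) -> np.ndarray:
    """Donation-game payoff matrix [[b-c, -c], [b, 0]] in (C, D) ordering.

    Raises ``ValueError`` unless b > c > 0 (otherwise the game is not a
    prisoner's dilemma).
    """
    if not (b > c > 0):
        raise ValueError(f"donation game requires b > c > 0, got b={b}, c={c}")
    return np.array([[b - c, -c], [b, 0.0]])


@dataclass(frozen=True)
class PayoffScheme:
    """Benefit/cost pair of the donation game plus its induced matrix."""

    b: float
    c: float

    def __post_init__(self) -> None:
        build_payoff_matrix(self.b, self.c)  # validates

    @property
    def matrix(self) -> np.ndarray:
        return build_payoff_matrix(self.b, self.c)


@dataclass(frozen=True)
class BreakingSchedule:
    """Per-link-type breaking probabilities.

    Parameterized by strategy pair (k_CC, k_CD, k_DD), applied identically
    to intra- and inter-group links; ``overrides`` may pin individual link
    types for group-dependent variants.  Values lie in [0, 1]; operations
    that need an irreducible chain (payoff rescaling, stationary
    distributions) additionally require strictly positive values.
    """

    k_CC: float
    k_CD: float
    k_DD: float
    overrides: Mapping[LinkType, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in self.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"breaking probability {name} = {v} outside [0, 1]")

    def items(self) -> Iterable[tuple[str, float]]:
        yield from (("k_CC", self.k_CC), ("k_CD", self.k_CD), ("k_DD", self.k_DD))
        for t, v in self.overrides.items():
            yield t.label, v

    def by_pair(self, pair: str) -> float:
        return {"CC": self.k_CC, "CD": self.k_CD, "DD": self.k_DD}[pair]

    def k(self, link_type: LinkType) -> float:
        if link_type in self.overrides:
            return self.overrides[link_type]
        return self.by_pair(link_type.strategy_pair)

    def k_vector(self) -> np.ndarray:
        """Breaking probabilities in canonical link-type order."""
        return np.array([self.k(t) for t in LINK_TYPES])

    @property
    def is_pair_uniform(self) -> bool:
        return all(
            self.overrides.get(t, self.by_pair(t.strategy_pair)) == self.by_pair(t.strategy_pair)
            for t in LINK_TYPES
        )

    def require_positive(self) -> None:
        for name, v in self.items():
            if v <= 0.0:
                raise ValueError(f"breaking probability {name} must be > 0 for this operation")


def rescale_payoff_matrix(M: np.ndarray, schedule: BreakingSchedule) -> np.ndarray:
    """Divide each entry of M by the breaking probability of its strategy pair.

    The C-C entry is divided by k_CC, the two mixed entries by k_CD and the
    D-D entry by k_DD: a link of pair (s, s') lives for a geometric number
    of selections with mean 1/k_ss', so the rescaled matrix is the payoff
    accumulated per unit linking turnover.
    """
    schedule.require_positive()
    M = np.asarray(M, dtype=float)
    if M.shape != (2, 2):
        raise ValueError("payoff matrix must be 2x2 in (C, D) ordering")
    divisors = np.array(
        [[schedule.k_CC, schedule.k_CD], [schedule.k_CD, schedule.k_DD]]
    )
    return M / divisors


@dataclass(frozen=True)
class PopulationConfig:
    """Sizes, link counts and dynamical rates of the two-group population.

    p is the intra-group attaching bias: after a break the retained
    endpoint rewires inside its own group with probability p, to the other
    group otherwise.  W is the per-event probability of a strategy-update
    event (link adjustment happens otherwise) and w the selection
    intensity of the Fermi rule.  The total link count L1 + L2 + L12 is
    conserved by the dynamics; the per-compartment counts are not.
    """

    N1: int
    N2: int
    L1: int
    L2: int
    L12: int
    p: float = 0.5
    W: float = 0.1
    w: float = 0.1

    def __post_init__(self) -> None:
        if min(self.N1, self.N2) < 2:
            raise ValueError("each group needs at least 2 members")
        for name in ("L1", "L2", "L12"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.L1 > self.N1 * (self.N1 - 1) // 2:
            raise ValueError("L1 exceeds the number of group-1 pairs")
        if self.L2 > self.N2 * (self.N2 - 1) // 2:
            raise ValueError("L2 exceeds the number of group-2 pairs")
        if self.L12 > self.N1 * self.N2:
            raise ValueError("L12 exceeds the number of cross-group pairs")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("intra-group bias p must lie in [0, 1]")
        if not (0.0 <= self.W <= 1.0):
            raise ValueError("strategy-update probability W must lie in [0, 1]")
        if self.w < 0.0:
            raise ValueError("selection intensity w must be >= 0")

    @property
    def N(self) -> int:
        return self.N1 + self.N2

    @property
    def L(self) -> int:
        return self.L1 + self.L2 + self.L12


@dataclass(frozen=True)
class ModelParams:
    """Bundle of payoff scheme, breaking schedule and population config."""

    payoff: PayoffScheme
    schedule: BreakingSchedule
    config: PopulationConfig

    @property
    def rescaled_matrix(self) -> np.ndarray:
        return rescale_payoff_matrix(self.payoff.matrix, self.schedule)

    @property
    def p(self) -> float:
        return self.config.p

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with payoff/schedule/config fields replaced by name.

        Accepts any field of the three sub-objects, e.g.
        ``params.with_(p=0.8, k_CD=0.5, b=1.2)``.
        """
        pay = {k: v for k, v in kwargs.items() if k in ("b", "c")}
        sch = {k: v for k, v in kwargs.items() if k in ("k_CC", "k_CD", "k_DD", "overrides")}
        cfg = {
            k: v
            for k, v in kwargs.items()
            if k in ("N1", "N2", "L1", "L2", "L12", "p", "W", "w")
        }
        unknown = set(kwargs) - set(pay) - set(sch) - set(cfg)
        if unknown:
            raise TypeError(f"unknown parameter(s): {sorted(unknown)}")
        return ModelParams(
            payoff=replace(self.payoff, **pay) if pay else self.payoff,
            schedule=replace(self.schedule, **sch) if sch else self.schedule,
            config=replace(self.config, **cfg) if cfg else self.config,
        )


_PAYOFF_KEYS = ("b", "c")
_SCHEDULE_KEYS = ("k_CC", "k_CD", "k_DD")
_CONFIG_KEYS = ("N1", "N2", "L1", "L2", "L12", "p", "W", "w")


def _coerce(key: str, value):
    if key in ("N1", "N2", "L1", "L2", "L12"):
        return int(value)
    return float(value)


def load_params(source: str | Path | Mapping) -> ModelParams:
    """Build ModelParams from a mapping, a YAML file, or flat key=value lines.

    Every field of PayoffScheme, BreakingSchedule and PopulationConfig is
    addressable by name (b, c, k_CC, k_CD, k_DD, N1, N2, L1, L2, L12, p,
    W, w); nested mappings under 'payoff'/'schedule'/'config' are also
    accepted.
    """
    if isinstance(source, Mapping):
        mapping = dict(source)
    else:
        text = Path(source).read_text()
        loaded = yaml.safe_load(text)
        if isinstance(loaded, Mapping):
            mapping = dict(loaded)
        else:  # flat key=value lines
            mapping = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"malformed config line: {line!r}")
                key, value = (part.strip() for part in line.split("=", 1))
                mapping[key] = value
    for section in ("payoff", "schedule", "config"):
        sub = mapping.pop(section, None)
        if sub:
            mapping.update(sub)
    known = _PAYOFF_KEYS + _SCHEDULE_KEYS + _CONFIG_KEYS
    unknown = set(mapping) - set(known)
    if unknown:
        raise ValueError(f"unknown parameter(s) in config: {sorted(unknown)}")
    missing = [k for k in known if k not in mapping and k not in ("p", "W", "w")]
    if missing:
        raise ValueError(f"missing parameter(s) in config: {missing}")
    vals = {k: _coerce(k, v) for k, v in mapping.items()}
    return ModelParams(
        payoff=PayoffScheme(b=vals["b"], c=vals["c"]),
        schedule=BreakingSchedule(
            k_CC=vals["k_CC"], k_CD=vals["k_CD"], k_DD=vals["k_DD"]
        ),
        config=PopulationConfig(**{k: vals[k] for k in _CONFIG_KEYS if k in vals}),
    )
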
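"""Named parameter presets for the study conditions.

All presets use the donation game b = 1, c = 0.3 with breaking
probabilities (k_CC, k_CD, k_DD) = (0.3, 0.6, 0.9): cooperator pairs
keep their links longest, mixed pairs break twice as often, defector
pairs are the most fragile.  This puts the critical benefit-to-cost
ratio at (b/c)* = k_CD/(k_CD - k_CC) = 2 (satisfied: b/c = 10/3) and
the unstable interior point at x* = 3/7, i.e. the dynamics is a
coordination game with a basin boundary close to — just below — the
half-filled initial condition, which is the regime where the
stochastic co-evolution is sensitive to the intra-group bias.
"""

from __future__ import annotations

from .game import BreakingSchedule, ModelParams, PayoffScheme, PopulationConfig

__all__ = ["bistable", "chain_agreement", "defection_dominant"]


def bistable(**overrides) -> ModelParams:
    """Bistable co-evolution preset (reduced scale).

    Two groups of 100 players, 300 links inside each group and 200
    across (average degree 8), intra-group bias p = 0.6, strategy
    updates with probability W = 1e-3 per event (fast rewiring: the
    whole link population turns over several times between strategy
    updates), selection intensity w = 0.1.
    """
    params = ModelParams(
        payoff=PayoffScheme(b=1.0, c=0.3),
        schedule=BreakingSchedule(k_CC=0.3, k_CD=0.6, k_DD=0.9),
        config=PopulationConfig(
            N1=100, N2=100, L1=300, L2=300, L12=200, p=0.6, W=1e-3, w=0.1
        ),
    )
    return params.with_(**overrides) if overrides else params


def chain_agreement(**overrides) -> ModelParams:
    """Sparse frozen-strategy preset for link-chain validation.

    W = 0 freezes strategies, so only the linking dynamics runs.  The
    10-state chain is a mean-field description: it ignores that a
    rewiring player cannot attach to current neighbors, whose strategy
    composition differs from the group's whenever breaking probabilities
    differ strongly across pairs.  This preset therefore uses a sparse
    network (average degree 2: L1 = L2 = 60, L12 = 80) and a mild
    breaking contrast k = (0.45, 0.5, 0.55), keeping that neglected
    correlation below Monte-Carlo resolution while the stationary
    distribution stays far from uniform (through x1 != x2 and p).
    """
    params = ModelParams(
        payoff=PayoffScheme(b=1.0, c=0.3),
        schedule=BreakingSchedule(k_CC=0.45, k_CD=0.5, k_DD=0.55),
        config=PopulationConfig(
            N1=100, N2=100, L1=60, L2=60, L12=80, p=0.6, W=0.0, w=0.1
        ),
    )
    return params.with_(**overrides) if overrides else params


def defection_dominant(**overrides) -> ModelParams:
    """Preset violating the benefit-to-cost condition (k_CC = k_CD).

    With equally fragile C-C and C-D links the critical ratio is
    infinite, all-defect is the only stable state and no interior
    equilibrium exists.
    """
    params = ModelParams(
        payoff=PayoffScheme(b=1.0, c=0.3),
        schedule=BreakingSchedule(k_CC=0.6, k_CD=0.6, k_DD=0.9),
        config=PopulationConfig(
            N1=100, N2=100, L1=300, L2=300, L12=200, p=0.6, W=1e-3, w=0.1
        ),
    )
    return params.with_(**overrides) if overrides else params
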
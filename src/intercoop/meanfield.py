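"""Deterministic population-level dynamics under fast rewiring.

When link adjustment is much more frequent than strategy updating, the
network sits at the stationary link-type distribution between strategy
events, and a player's expected payoff is computed against the effective
(breaking-probability-rescaled) game M'.  Writing x_g for the cooperator
frequency of group g and h for the other group, the biased mixing
frequency seen by a member of group g is

    y_g = p x_g + (1 - p) x_h,

and the average fitness of the two strategies is

    f_C,g = y_g R' + (1 - y_g) S',      f_D,g = y_g T' + (1 - y_g) P',

with (R', S', T', P') = ((b-c)/k_CC, -c/k_CD, b/k_CD, 0) the entries of
M'.  Under weak selection the stochastic pairwise-comparison process
reduces (after absorbing a constant timescale factor) to an extension of
the replicator dynamics,

    dx_g/dt = x_g (1 - x_g) (f_C,g - f_D,g),

whose fitness difference is affine: f_C,g - f_D,g = Delta y_g - c/k_CD
with Delta = (b - c)(1/k_CC - 1/k_CD).  The three symmetric equilibria
are (0,0), (1,1) and, when it lies inside the unit interval, the
diagonal interior point

    x* = c k_CC / ((b - c)(k_CD - k_CC)),

and the Jacobian eigenvalues at them are (with chi = x*(1-x*) Delta):

    (0,0):    -c/k_CD           (twice)        -> always stable
    (1,1):    -((b-c)/k_CC - b/k_CD)  (twice)  -> stable iff b/c exceeds
              the critical ratio k_CD / (k_CD - k_CC)
    (x*,x*):  chi  and  chi (2p - 1)           -> unstable node for
              p > 1/2, saddle for p < 1/2 (p_c = 1/2)

so the co-evolving system is a coordination (bistable) game exactly when
the benefit-to-cost ratio exceeds its critical value, which requires
cooperator-cooperator links to be more robust than mixed links
(k_CC < k_CD).

The finite-intensity drift (general w) and the two-channel pairwise
comparison of the transition probabilities are also provided; see
``transition_probabilities`` for the cross-group imitation channel and
its selection-independent mixing term.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .game import ModelParams

__all__ = [
    "FitnessProfile",
    "Trajectory",
    "EquilibriumReport",
    "fermi",
    "average_fitness",
    "transition_probabilities",
    "replicator_field",
    "integrate_trajectory",
    "jacobian",
    "equilibrium_eigenvalues",
    "classify_equilibria",
    "critical_benefit_cost",
    "interior_fixed_point",
    "critical_intra_group_bias",
    "basin_threshold_diagonal",
]


def _check_state(state) -> np.ndarray:
    x = np.asarray(state, dtype=float)
    if x.shape != (2,):
        raise ValueError("state must be (x1, x2)")
    if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
        raise ValueError(f"state {x} outside the unit square")
    return np.clip(x, 0.0, 1.0)


def _require_pair_uniform(params: ModelParams) -> None:
    if not params.schedule.is_pair_uniform:
        raise ValueError(
            "mean-field analysis requires a strategy-pair-keyed breaking "
            "schedule (no group-dependent overrides)"
        )


def fermi(delta: float, w: float) -> float:
    """Fermi acceptance probability 1 / (1 + exp(-w * delta))."""
    return 1.0 / (1.0 + math.exp(-w * delta)) if w * delta > -700 else 0.0


@dataclass(frozen=True)
class FitnessProfile:
    """Average payoffs of C and D in each group under fast rewiring."""

    fC1: float
    fD1: float
    fC2: float
    fD2: float

    def f(self, strategy: str, group: int) -> float:
        return getattr(self, f"f{strategy}{group}")


def average_fitness(state, params: ModelParams) -> FitnessProfile:
    """Evaluate the fast-rewiring fitness of both strategies in both groups.

    The first (weight p) term is payoff earned through same-group
    interactions, the second (weight 1-p) through cross-group ones; both
    use the rescaled matrix M', whose 1/k factors carry the expected
    interaction duration of each link type.
    """
    x1, x2 = _check_state(state)
    _require_pair_uniform(params)
    Mp = params.rescaled_matrix
    p = params.p

    def f(srow: int, xg: float, xh: float) -> float:
        same = xg * Mp[srow, 0] + (1.0 - xg) * Mp[srow, 1]
        cross = xh * Mp[srow, 0] + (1.0 - xh) * Mp[srow, 1]
        return p * same + (1.0 - p) * cross

    return FitnessProfile(
        fC1=f(0, x1, x2), fD1=f(1, x1, x2), fC2=f(0, x2, x1), fD2=f(1, x2, x1)
    )


def transition_probabilities(
    state, params: ModelParams, w: float | None = None, cross_imitation: bool = True
):
    """Per-group raising/lowering probabilities (T1+, T1-), (T2+, T2-).

    Each group's cooperator count changes through pairwise comparison with
    Fermi acceptance at intensity ``w`` (default: the configured selection
    intensity).  With ``cross_imitation=True`` the comparison has two
    channels, weighted by the attaching bias: with probability p the model
    player is drawn from the same group, with probability 1-p from the
    other group (a cooperator from either group may replace a defector of
    group g, as may the reverse).  The cross channel carries a
    selection-independent mixing drift proportional to (1-p)(x_h - x_g)
    that transports strategies between groups and vanishes on the
    diagonal.  With ``cross_imitation=False`` the comparison is
    within-group only (interdependence acts through the fitness alone);
    T+ - T- then vanishes identically at w = 0 and the weak-selection
    limit of the drift is exactly the replicator field.
    """
    x1, x2 = _check_state(state)
    if w is None:
        w = params.config.w
    fit = average_fitness(state, params)
    p = params.p
    out = []
    for xg, xh, g, h in ((x1, x2, 1, 2), (x2, x1, 2, 1)):
        fCg, fDg = fit.f("C", g), fit.f("D", g)
        fCh, fDh = fit.f("C", h), fit.f("D", h)
        if cross_imitation:
            t_plus = p * xg * (1 - xg) * fermi(fCg - fDg, w) + (1 - p) * xh * (
                1 - xg
            ) * fermi(fCh - fDg, w)
            t_minus = p * xg * (1 - xg) * fermi(fDg - fCg, w) + (1 - p) * (
                1 - xh
            ) * xg * fermi(fDh - fCg, w)
        else:
            t_plus = xg * (1 - xg) * fermi(fCg - fDg, w)
            t_minus = xg * (1 - xg) * fermi(fDg - fCg, w)
        out.append((t_plus, t_minus))
    return tuple(out)


def _affine_coefficients(params: ModelParams) -> tuple[float, float]:
    """(Delta, S') with f_C,g - f_D,g = Delta * y_g + S'."""
    Mp = params.rescaled_matrix
    delta = (Mp[0, 0] - Mp[1, 0]) - (Mp[0, 1] - Mp[1, 1])
    s = Mp[0, 1] - Mp[1, 1]
    return delta, s


def replicator_field(
    state, params: ModelParams, w: float | None = None, cross_imitation: bool = False
) -> np.ndarray:
    """Velocity (dx1, dx2) of the mean-field strategy dynamics.

    ``w=None`` (default) returns the weak-selection replicator field
    x_g (1 - x_g)(f_C,g - f_D,g) with the constant timescale factor
    absorbed.  A finite ``w`` returns the drift T+ - T- of the
    finite-intensity pairwise process; with ``cross_imitation=False``
    that drift equals tanh(w (f_C - f_D)/2)-weighted replicator motion
    and converges, after division by w/2, to the default field.
    """
    x1, x2 = _check_state(state)
    if w is not None:
        (t1p, t1m), (t2p, t2m) = transition_probabilities(
            state, params, w=w, cross_imitation=cross_imitation
        )
        return np.array([t1p - t1m, t2p - t2m])
    fit = average_fitness(state, params)
    return np.array(
        [x1 * (1 - x1) * (fit.fC1 - fit.fD1), x2 * (1 - x2) * (fit.fC2 - fit.fD2)]
    )


def jacobian(state, params: ModelParams) -> np.ndarray:
    """Analytic Jacobian of the weak-selection replicator field."""
    x1, x2 = _check_state(state)
    _require_pair_uniform(params)
    delta, s = _affine_coefficients(params)
    p = params.p
    y1 = p * x1 + (1 - p) * x2
    y2 = p * x2 + (1 - p) * x1
    d1 = delta * y1 + s
    d2 = delta * y2 + s
    return np.array(
        [
            [(1 - 2 * x1) * d1 + x1 * (1 - x1) * delta * p, x1 * (1 - x1) * delta * (1 - p)],
            [x2 * (1 - x2) * delta * (1 - p), (1 - 2 * x2) * d2 + x2 * (1 - x2) * delta * p],
        ]
    )


@dataclass(frozen=True)
class Trajectory:
    """Integrated mean-field orbit with convergence metadata."""

    t: np.ndarray
    states: np.ndarray  # shape (n, 2)
    converged: bool
    terminal: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "terminal", self.states[-1])


def _fixed_points(params: ModelParams) -> list[np.ndarray]:
    pts = [np.zeros(2), np.ones(2)]
    xs = interior_fixed_point(params)
    if xs is not None:
        pts.append(np.array([xs, xs]))
    return pts


def integrate_trajectory(
    state0,
    params: ModelParams,
    horizon: float = 2000.0,
    tol: float = 1e-6,
    rtol: float = 1e-8,
    w: float | None = None,
    n_samples: int = 200,
) -> Trajectory:
    """Integrate the mean-field flow from ``state0`` for ``horizon`` time.

    Adaptive (RK45, rtol=1e-8 by default); the unit square is forward
    invariant by construction, no projection is applied.  ``converged``
    is set when the terminal state is within ``tol`` of a fixed point.
    Slow or non-convergent runs simply return with ``converged=False``.
    """
    x0 = _check_state(state0)
    rhs = lambda t, x: replicator_field(np.clip(x, 0.0, 1.0), params, w=w)
    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        x0,
        method="RK45",
        rtol=rtol,
        atol=1e-12,
        t_eval=np.linspace(0.0, horizon, n_samples),
    )
    states = np.clip(sol.y.T, 0.0, 1.0)
    terminal = states[-1]
    converged = any(np.linalg.norm(terminal - fp) < tol for fp in _fixed_points(params))
    if not converged:
        warnings.warn("trajectory did not reach a fixed point within the horizon",
                      stacklevel=2)
    return Trajectory(t=sol.t, states=states, converged=converged)


def critical_benefit_cost(params: ModelParams) -> float:
    """Critical benefit-to-cost ratio k_CD / (k_CD - k_CC).

    Full cooperation (1,1) is stable iff b/c exceeds this value; with
    kappa = k_CC/k_CD it reads 1/(1 - kappa), so the threshold falls as
    mixed C-D links become more fragile and rises with sturdier C-C
    links.  Returns +inf when k_CC >= k_CD (cooperation never stable).
    """
    _require_pair_uniform(params)
    k_cc, k_cd = params.schedule.k_CC, params.schedule.k_CD
    if k_cc >= k_cd:
        return float("inf")
    return k_cd / (k_cd - k_cc)


def interior_fixed_point(params: ModelParams) -> float | None:
    """Diagonal interior equilibrium x* = c k_CC / ((b-c)(k_CD - k_CC)).

    x* lies in (0,1) exactly when the benefit-to-cost ratio exceeds its
    critical value; returns None otherwise (no interior equilibrium).
    """
    _require_pair_uniform(params)
    delta, s = _affine_coefficients(params)
    if delta <= 0.0:
        return None
    xs = -s / delta
    return xs if 0.0 < xs < 1.0 else None


def equilibrium_eigenvalues(params: ModelParams) -> dict[str, tuple[float, float]]:
    """Closed-form Jacobian eigenvalues at the three candidate equilibria.

    Keys '(0,0)', '(1,1)' and, when present, '(x*,x*)'.  At the corners
    the Jacobian is diagonal with a repeated eigenvalue; at the interior
    point the eigenvectors are the diagonal and anti-diagonal directions
    with eigenvalues chi and chi (2p - 1), chi = x*(1-x*) Delta.
    """
    delta, s = _affine_coefficients(params)
    p = params.p
    out = {"(0,0)": (s, s), "(1,1)": (-(delta + s), -(delta + s))}
    xs = interior_fixed_point(params)
    if xs is not None:
        chi = xs * (1 - xs) * delta
        out["(x*,x*)"] = (chi, chi * (2 * p - 1))
    return out


def _label(eigs: tuple[float, float]) -> str:
    a, b = eigs
    if a < 0 and b < 0:
        return "stable"
    if a > 0 and b > 0:
        return "unstable"
    if a * b < 0:
        return "saddle"
    return "degenerate"


@dataclass(frozen=True)
class EquilibriumReport:
    """Equilibria, eigenvalues, stability labels and thresholds."""

    equilibria: dict[str, tuple[float, float]]
    eigvals: dict[str, tuple[float, float]]
    labels: dict[str, str]
    x_star: float | None
    bc_critical: float
    p_critical: float
    bistable: bool

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "equilibria": {k: list(v) for k, v in self.equilibria.items()},
            "eigenvalues": {k: list(v) for k, v in self.eigvals.items()},
            "labels": self.labels,
            "x_star": self.x_star,
            "bc_critical": self.bc_critical,
            "p_critical": self.p_critical,
            "bistable": self.bistable,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def classify_equilibria(params: ModelParams) -> EquilibriumReport:
    """Stability classification of (0,0), (1,1) and the interior point.

    In the coordination regime (b/c above critical, p above 1/2) both
    corners are stable and (x*, x*) is an unstable node whose position
    sets the attraction basin of cooperation; for p below 1/2 the
    interior point is a saddle (transverse direction attracting).
    """
    eigs = equilibrium_eigenvalues(params)
    xs = interior_fixed_point(params)
    equilibria = {"(0,0)": (0.0, 0.0), "(1,1)": (1.0, 1.0)}
    if xs is not None:
        equilibria["(x*,x*)"] = (xs, xs)
    labels = {k: _label(v) for k, v in eigs.items()}
    bc = params.payoff.b / params.payoff.c
    bistable = (
        labels["(0,0)"] == "stable"
        and labels["(1,1)"] == "stable"
        and xs is not None
    )
    return EquilibriumReport(
        equilibria=equilibria,
        eigvals=eigs,
        labels=labels,
        x_star=xs,
        bc_critical=critical_benefit_cost(params),
        p_critical=critical_intra_group_bias(params),
        bistable=bistable,
    )


def critical_intra_group_bias(
    params: ModelParams, tol: float = 1e-9
) -> float | None:
    """Bias p_c at which the interior equilibrium changes character.

    Located by bisection on the sign of the transverse Jacobian
    eigenvalue at (x*, x*) (saddle below, unstable node above); requires
    an interior equilibrium.  For the affine fitness structure the sign
    change sits at p = 1/2 for every admissible parameter set.
    """
    xs = interior_fixed_point(params)
    if xs is None:
        return None

    def transverse(p: float) -> float:
        eigs = np.linalg.eigvals(jacobian((xs, xs), params.with_(p=p)))
        return float(np.min(eigs.real))

    lo, hi = 0.0, 1.0
    if transverse(lo) * transverse(hi) > 0:
        return None
    return float(brentq(transverse, lo, hi, xtol=tol))


def basin_threshold_diagonal(
    params: ModelParams, tol: float = 1e-6, horizon: float = 4000.0
) -> float | None:
    """Basin boundary on the diagonal, located by bisection of outcomes.

    Integrates from (x, x) and bisects on whether the orbit reaches
    (1,1) or (0,0); independent of the closed-form x*, so it serves as
    its oracle.  Returns None when the dynamics is not bistable.
    """
    report = classify_equilibria(params)
    if not report.bistable:
        return None

    def goes_up(x0: float) -> bool:
        traj = integrate_trajectory((x0, x0), params, horizon=horizon, tol=1e-4)
        return bool(traj.terminal.sum() > 1.0)

    lo, hi = 0.0, 1.0
    if goes_up(lo) or not goes_up(hi):
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if goes_up(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
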
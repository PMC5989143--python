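"""Two-armed decision tree and deterministic rollback.

Each arm (standard care, bundle) runs the same fixed topology: a chance
node for acute renal failure (ARF yes/no), a chance node for vital
status (survive/die), and — for ARF survivors only — a chance node for
chronic renal replacement therapy (RRT yes/no).  That yields five
terminal paths per arm.  Vital status is modelled independently of ARF
status within an arm (p(die|ARF) = p(die|no ARF) = p_mort): only
marginal mortality and ARF probabilities are available, so the two
events are combined as independent.

Payoffs per terminal path over the fixed 5-year horizon:

cost  = c_hosp + c_bundle (bundle arm only)
              + c_arf (ARF paths)
              + horizon * c_rrt_annual (RRT path; undiscounted)
QALYs = 0 for decedents; area under the piecewise-linear utility curve
        for survivors (non-ARF survivors follow the 1y/2.5y/5y utility
        track with u(0) taken as the 1-year value; ARF survivors hold a
        constant utility).

No discounting is applied anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .parameters import (
    ARMS,
    HORIZON_YEARS,
    ParameterValues,
    ScenarioParameterSet,
)

__all__ = [
    "TERMINAL_PATHS",
    "DecisionTree",
    "ArmOutcome",
    "IncrementalResult",
    "terminal_cost",
    "terminal_qaly",
    "qaly_accrual",
    "nonarf_track",
    "arf_track",
    "DEATH_TRACK",
    "path_probabilities",
    "roll_back",
    "incremental",
    "net_monetary_benefit",
    "calibrate_rrt_probability",
]

#: The five terminal paths of each arm's subtree.  Non-ARF patients and
#: decedents never reach the RRT node.
TERMINAL_PATHS = (
    ("no_arf", "survive"),
    ("no_arf", "die"),
    ("arf", "die"),
    ("arf", "survive", "no_rrt"),
    ("arf", "survive", "rrt"),
)

#: Classification tolerance for dominance/indifference ties (USD / QALY).
TIE_TOL = 1e-9

#: Utility track of decedents: constant zero.
DEATH_TRACK = ((0.0, 0.0),)


@dataclass(frozen=True)
class ArmOutcome:
    """Expected cost (USD) and QALYs per patient over the horizon."""

    expected_cost: float
    expected_qaly: float


@dataclass(frozen=True)
class IncrementalResult:
    """Bundle-minus-standard increments with dominance classification.

    ``classification`` is one of ``dominant`` (bundle strictly cheaper
    and strictly more effective), ``dominated`` (costlier with no health
    gain, or no cheaper with a health loss), ``tradeoff_ne`` /
    ``tradeoff_sw`` (cost and health move together; ICER defined), or
    ``indifferent``.  Strictness uses a 1e-9 tie tolerance.
    """

    delta_cost: float
    delta_qaly: float
    classification: str
    icer: float | None


def _coerce_values(params: ScenarioParameterSet | ParameterValues) -> ParameterValues:
    if isinstance(params, ScenarioParameterSet):
        return params.point_values()
    return params


# --------------------------------------------------------------------------
# Payoffs
# --------------------------------------------------------------------------


def qaly_accrual(utility_track, horizon: float) -> float:
    """QALYs accrued over [0, horizon] under a piecewise-linear utility
    curve through ``utility_track`` = ((t1, u1), (t2, u2), ...).

    The curve is anchored at u(0) := u(t1) (no earlier measurement
    exists) and held constant past the last knot; the integral is the
    trapezoidal area.  A single-knot (constant) track integrates to
    u * horizon; the all-zero death track gives 0.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    knots = sorted(utility_track)
    if not knots:
        return 0.0
    for _, u in knots:
        if not 0.0 <= u <= 1.0:
            raise ValueError(f"utility {u} outside [0, 1]")
    times = [t for t, _ in knots]
    utils = [u for _, u in knots]
    if times[0] > 0.0:
        times.insert(0, 0.0)
        utils.insert(0, utils[0])
    if times[-1] < horizon:
        times.append(horizon)
        utils.append(utils[-1])
    grid = np.asarray(times, dtype=float)
    vals = np.asarray(utils, dtype=float)
    keep = grid <= horizon
    if not keep.all():
        u_h = float(np.interp(horizon, grid, vals))
        grid = np.append(grid[keep], horizon)
        vals = np.append(vals[keep], u_h)
    return float(np.trapezoid(vals, grid))


def nonarf_track(shared) -> tuple[tuple[float, float], ...]:
    """Utility knots of non-ARF survivors at 1, 2.5 and 5 years post-ICU."""
    return (
        (1.0, shared["u_nonarf_1y"]),
        (2.5, shared["u_nonarf_2p5y"]),
        (5.0, shared["u_nonarf_5y"]),
    )


def arf_track(shared) -> tuple[tuple[float, float], ...]:
    """Constant utility track of ARF survivors."""
    return ((0.0, shared["u_arf"]),)


def terminal_cost(
    path: tuple[str, ...],
    params: ScenarioParameterSet | ParameterValues,
    arm: str,
) -> float:
    """Cost payoff (USD) of one terminal path for one arm.

    Hospital episode cost always accrues; the bundle arm adds the drug
    cost; ARF paths add the ARF episode cost; the RRT path adds the
    annual RRT cost for the full horizon, undiscounted.
    """
    if path not in TERMINAL_PATHS:
        raise ValueError(f"invalid terminal path {path!r}")
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    values = _coerce_values(params)
    shared = values.shared
    cost = shared["c_hosp"]
    if arm == "bundle":
        cost += shared["c_bundle"]
    if path[0] == "arf":
        cost += shared["c_arf"]
    if path[-1] == "rrt":
        cost += shared["c_rrt_annual"] * values.horizon_years
    return cost


def terminal_qaly(
    path: tuple[str, ...],
    params: ScenarioParameterSet | ParameterValues,
) -> float:
    """QALY payoff of one terminal path (arm-independent)."""
    if path not in TERMINAL_PATHS:
        raise ValueError(f"invalid terminal path {path!r}")
    values = _coerce_values(params)
    if "die" in path:
        return 0.0
    track = arf_track(values.shared) if path[0] == "arf" else nonarf_track(values.shared)
    return qaly_accrual(track, values.horizon_years)


# --------------------------------------------------------------------------
# Tree structure and rollback
# --------------------------------------------------------------------------


def path_probabilities(
    params: ScenarioParameterSet | ParameterValues, arm: str
) -> dict[tuple[str, ...], float]:
    """Probability of each terminal path for one arm.

    Death is independent of ARF status within the arm; sibling branches
    at every chance node are complementary, so the five path
    probabilities sum to 1 exactly (up to floating point).
    """
    values = _coerce_values(params)
    p = values.arms[arm]
    for name, v in p.items():
        if not 0.0 <= v <= 1.0 or not math.isfinite(v):
            raise ValueError(
                f"{arm}:{name} = {v} is not a probability; branch probabilities "
                "cannot be normalized"
            )
    p_arf, p_mort, p_rrt = p["p_arf"], p["p_mort"], p["p_rrt_given_arf_survivor"]
    return {
        ("no_arf", "survive"): (1 - p_arf) * (1 - p_mort),
        ("no_arf", "die"): (1 - p_arf) * p_mort,
        ("arf", "die"): p_arf * p_mort,
        ("arf", "survive", "no_rrt"): p_arf * (1 - p_mort) * (1 - p_rrt),
        ("arf", "survive", "rrt"): p_arf * (1 - p_mort) * p_rrt,
    }


@dataclass(frozen=True)
class DecisionTree:
    """The fixed two-armed tree topology with its analytic horizon.

    The topology itself is structural (ARF → vital status → RRT among
    ARF survivors); parameter values are supplied at evaluation time, so
    a single instance serves every scenario.
    """

    horizon_years: float = HORIZON_YEARS

    arms = ARMS
    terminal_paths = TERMINAL_PATHS

    def arm_outcome(
        self, params: ScenarioParameterSet | ParameterValues, arm: str
    ) -> ArmOutcome:
        values = _coerce_values(params)
        probs = path_probabilities(values, arm)
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(
                f"{arm}: terminal path probabilities sum to {total}, not 1"
            )
        cost = sum(
            pr * terminal_cost(path, values, arm) for path, pr in probs.items()
        )
        qaly = sum(pr * terminal_qaly(path, values) for path, pr in probs.items())
        return ArmOutcome(expected_cost=cost, expected_qaly=qaly)

    def outline(self, params: ScenarioParameterSet | ParameterValues) -> str:
        """Human-readable indented outline of the tree for audit."""
        values = _coerce_values(params)
        lines = ["decision: sepsis care strategy"]
        for arm in self.arms:
            p = values.arms[arm]
            lines.append(f"  arm: {arm}")
            for arf, p_a in (("arf", p["p_arf"]), ("no_arf", 1 - p["p_arf"])):
                lines.append(f"    {arf} (p={p_a:.4f})")
                for vital, p_v in (
                    ("die", p["p_mort"]),
                    ("survive", 1 - p["p_mort"]),
                ):
                    lines.append(f"      {vital} (p={p_v:.4f})")
                    if arf == "arf" and vital == "survive":
                        p_r = p["p_rrt_given_arf_survivor"]
                        for rrt, p_q in (("rrt", p_r), ("no_rrt", 1 - p_r)):
                            path = ("arf", "survive", rrt)
                            lines.append(
                                f"        {rrt} (p={p_q:.4f}) -> "
                                f"cost ${terminal_cost(path, values, arm):,.0f}, "
                                f"{terminal_qaly(path, values):.3f} QALY"
                            )
                    else:
                        path = (arf, vital)
                        lines.append(
                            f"        -> cost ${terminal_cost(path, values, arm):,.0f}, "
                            f"{terminal_qaly(path, values):.3f} QALY"
                        )
        return "\n".join(lines)


def roll_back(
    tree: DecisionTree,
    params: ScenarioParameterSet | ParameterValues,
) -> dict[str, ArmOutcome]:
    """Expected cost and QALYs per arm by probability-weighted rollback
    over the terminal paths."""
    return {arm: tree.arm_outcome(params, arm) for arm in tree.arms}


# --------------------------------------------------------------------------
# Incremental comparison
# --------------------------------------------------------------------------


def incremental(standard: ArmOutcome, bundle: ArmOutcome) -> IncrementalResult:
    """Bundle-versus-standard incremental result with dominance
    classification on the cost-effectiveness plane.

    Dominance is strict (cheaper AND more effective beyond the 1e-9
    tie tolerance).  Boundary cases with no health change are classified
    as ``dominated`` when the bundle costs more, and as a trade-off with
    a limiting (infinite) ICER when it costs less, since strict dominance
    requires a health gain.
    """
    for o in (standard, bundle):
        if not (math.isfinite(o.expected_cost) and math.isfinite(o.expected_qaly)):
            raise ValueError("arm outcomes must be finite")
    dc = bundle.expected_cost - standard.expected_cost
    dq = bundle.expected_qaly - standard.expected_qaly
    if abs(dc) <= TIE_TOL and abs(dq) <= TIE_TOL:
        return IncrementalResult(dc, dq, "indifferent", None)
    if dc < -TIE_TOL and dq > TIE_TOL:
        return IncrementalResult(dc, dq, "dominant", None)
    if dc >= -TIE_TOL and dq <= TIE_TOL:
        # costlier with no health gain, or no cheaper with a health loss
        return IncrementalResult(dc, dq, "dominated", None)
    # Remaining: NE (costlier or cost-neutral, more effective) or
    # SW (cheaper, less effective or health-neutral).
    quadrant = "tradeoff_ne" if dq > TIE_TOL else "tradeoff_sw"
    icer = dc / dq if abs(dq) > TIE_TOL else math.inf
    return IncrementalResult(dc, dq, quadrant, icer)


def net_monetary_benefit(delta_cost: float, delta_qaly: float, lam: float) -> float:
    """Net monetary benefit lambda * dQALY - dCost at willingness-to-pay
    ``lam`` (USD/QALY)."""
    if lam < 0:
        raise ValueError("willingness-to-pay must be nonnegative")
    return lam * delta_qaly - delta_cost


# --------------------------------------------------------------------------
# RRT-branch calibration against the full rollback
# --------------------------------------------------------------------------


def calibrate_rrt_probability(
    pset: ScenarioParameterSet,
    arm: str,
    target_cost: float,
    tree: DecisionTree | None = None,
) -> float:
    """RRT-branch probability making the arm's rolled-back expected cost
    equal ``target_cost``, found by root-finding on the full tree.

    This is the reference calibration routine; the closed-form defaults
    in :func:`sepcea.parameters.default_rrt_calibration` must agree with
    it (checked in the test suite).
    """
    tree = tree or DecisionTree(horizon_years=pset.horizon_years)
    values = pset.point_values()

    def objective(p_rrt: float) -> float:
        values.arms[arm]["p_rrt_given_arf_survivor"] = p_rrt
        return tree.arm_outcome(values, arm).expected_cost - target_cost

    lo, hi = objective(0.0), objective(1.0)
    if lo * hi > 0:
        raise ValueError(
            f"target cost {target_cost} not attainable for arm {arm!r} "
            f"(range [{lo + target_cost:.0f}, {hi + target_cost:.0f}])"
        )
    return float(brentq(objective, 0.0, 1.0, xtol=1e-12))
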
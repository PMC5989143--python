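"""Probabilistic sensitivity analysis.

Each draw samples every model parameter independently from its
moment-matched distribution (beta for probabilities and utilities, gamma
for costs) and rolls the drawn values back through the decision tree.
Parameters that are identical in both arms — all costs and utilities,
and in the ineffective-bundle scenario also the transition probabilities
— receive the *same* realized value in both arms within a draw (common
random numbers), so shared-parameter noise cancels exactly in the
increment.  With identical arm probabilities this makes every draw's
incremental cost equal the drawn bundle cost and its incremental QALYs
identically zero.

Summaries use empirical percentiles with the linear-interpolation
(closest-ranks) definition, i.e. ``numpy.percentile(...,
method="linear")``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .parameters import (
    ARMS,
    PROBABILITY_NAMES,
    ParameterSpec,
    ParameterValues,
    ScenarioParameterSet,
    moment_match,
)
from .tree import DecisionTree, roll_back

__all__ = [
    "PsaSample",
    "PsaSummary",
    "sample_parameters",
    "run_psa",
    "dominance_probability",
    "negative_health_probability",
    "quadrant_probabilities",
    "summarize",
    "ceac",
    "carry_worst_case_qalys",
    "samples_to_frame",
]


@dataclass(frozen=True)
class PsaSample:
    """One Monte-Carlo draw's per-arm and incremental outcomes."""

    draw_index: int
    cost_standard: float
    qaly_standard: float
    cost_bundle: float
    qaly_bundle: float
    delta_cost: float
    delta_qaly: float


@dataclass(frozen=True)
class PsaSummary:
    """Empirical summary of a PSA run (per patient)."""

    n_draws: int
    delta_cost_mean: float
    delta_cost_interval: tuple[float, float]
    delta_qaly_mean: float
    delta_qaly_interval: tuple[float, float]
    p_dominant: float
    p_negative_health: float
    percentiles: tuple[float, float]
    seed: int | None = None


# --------------------------------------------------------------------------
# Sampling
# --------------------------------------------------------------------------


def _draw(spec: ParameterSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    params = moment_match(spec)
    family = params["family"]
    if family == "point_mass":
        return np.full(n, params["value"])
    if family == "beta":
        return rng.beta(params["alpha"], params["beta"], size=n)
    if family == "gamma":
        return rng.gamma(params["shape"], params["scale"], size=n)
    if family == "normal_truncated":
        lo, hi = params["lower"], params["upper"]
        m, s = params["loc"], params["scale"]
        a, b = (lo - m) / s, (hi - m) / s
        return stats.truncnorm.rvs(a, b, loc=m, scale=s, size=n, random_state=rng)
    raise ValueError(f"unknown family {family!r}")


def sample_parameters(
    pset: ScenarioParameterSet, n: int, seed: int
) -> list[ParameterValues]:
    """``n`` independent joint parameter draws, reproducible by seed.

    Shared (arm-independent) parameters are drawn once per draw.  A
    per-arm probability whose two arm specs are identical (point,
    dispersion and family all equal — the ineffective-bundle scenario)
    is likewise drawn once and used in both arms; otherwise the arms
    draw independently.  Every family respects its support by
    construction, so no draw can fall outside it.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)

    shared_draws = {
        name: _draw(pset.shared_specs[name], n, rng)
        for name in sorted(pset.shared_specs)
    }
    arm_draws: dict[str, dict[str, np.ndarray]] = {arm: {} for arm in ARMS}
    for name in sorted(PROBABILITY_NAMES):
        s_std = pset.arm_specs["standard"][name]
        s_bun = pset.arm_specs["bundle"][name]
        if s_std == s_bun:
            common = _draw(s_std, n, rng)
            arm_draws["standard"][name] = common
            arm_draws["bundle"][name] = common
        else:
            arm_draws["standard"][name] = _draw(s_std, n, rng)
            arm_draws["bundle"][name] = _draw(s_bun, n, rng)

    return [
        ParameterValues(
            arms={
                arm: {name: float(arm_draws[arm][name][i]) for name in PROBABILITY_NAMES}
                for arm in ARMS
            },
            shared={name: float(col[i]) for name, col in shared_draws.items()},
            horizon_years=pset.horizon_years,
        )
        for i in range(n)
    ]


def run_psa(
    tree: DecisionTree,
    pset: ScenarioParameterSet,
    n: int,
    seed: int,
) -> list[PsaSample]:
    """Sample ``n`` parameter sets and roll each back through the tree."""
    samples = []
    for i, values in enumerate(sample_parameters(pset, n, seed)):
        outcome = roll_back(tree, values)
        std, bun = outcome["standard"], outcome["bundle"]
        samples.append(
            PsaSample(
                draw_index=i,
                cost_standard=std.expected_cost,
                qaly_standard=std.expected_qaly,
                cost_bundle=bun.expected_cost,
                qaly_bundle=bun.expected_qaly,
                delta_cost=bun.expected_cost - std.expected_cost,
                delta_qaly=bun.expected_qaly - std.expected_qaly,
            )
        )
    return samples


# --------------------------------------------------------------------------
# Summaries
# --------------------------------------------------------------------------


def _deltas(samples: Sequence[PsaSample]) -> tuple[np.ndarray, np.ndarray]:
    if not samples:
        raise ValueError("empty sample collection")
    dc = np.array([s.delta_cost for s in samples])
    dq = np.array([s.delta_qaly for s in samples])
    return dc, dq


def dominance_probability(samples: Sequence[PsaSample]) -> float:
    """Fraction of draws in which the bundle is strictly dominant
    (delta_cost < 0 and delta_qaly > 0)."""
    dc, dq = _deltas(samples)
    return float(np.mean((dc < 0) & (dq > 0)))


def negative_health_probability(samples: Sequence[PsaSample]) -> float:
    """Fraction of draws with a net health loss (delta_qaly < 0)."""
    _, dq = _deltas(samples)
    return float(np.mean(dq < 0))


def quadrant_probabilities(samples: Sequence[PsaSample]) -> dict[str, float]:
    """Cost-effectiveness-plane quadrant fractions (plus boundary ties);
    the five values sum to 1."""
    dc, dq = _deltas(samples)
    out = {
        "dominant": float(np.mean((dc < 0) & (dq > 0))),
        "dominated": float(np.mean((dc > 0) & (dq < 0))),
        "tradeoff_ne": float(np.mean((dc > 0) & (dq > 0))),
        "tradeoff_sw": float(np.mean((dc < 0) & (dq < 0))),
    }
    out["ties"] = 1.0 - sum(out.values())
    return out


def summarize(
    samples: Sequence[PsaSample],
    percentiles: tuple[float, float] = (2.5, 97.5),
    seed: int | None = None,
) -> PsaSummary:
    """Means and empirical uncertainty intervals of the incremental
    outcomes.

    Percentiles follow the linear-interpolation-between-closest-ranks
    rule (numpy's ``method="linear"``); the 2.5th percentile of the
    integers 1..100 is 3.475 under this rule.
    """
    lo, hi = percentiles
    if not (0 < lo < hi < 100):
        raise ValueError("percentiles must be an ordered pair within (0, 100)")
    dc, dq = _deltas(samples)
    dc_lo, dc_hi = np.percentile(dc, [lo, hi], method="linear")
    dq_lo, dq_hi = np.percentile(dq, [lo, hi], method="linear")
    return PsaSummary(
        n_draws=len(samples),
        delta_cost_mean=float(dc.mean()),
        delta_cost_interval=(float(dc_lo), float(dc_hi)),
        delta_qaly_mean=float(dq.mean()),
        delta_qaly_interval=(float(dq_lo), float(dq_hi)),
        p_dominant=dominance_probability(samples),
        p_negative_health=negative_health_probability(samples),
        percentiles=(float(lo), float(hi)),
        seed=seed,
    )


def ceac(
    samples: Sequence[PsaSample], lambda_grid: Iterable[float]
) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability curve: for each willingness-to-pay
    value, the fraction of draws with positive net monetary benefit."""
    dc, dq = _deltas(samples)
    curve = []
    for lam in lambda_grid:
        if lam < 0:
            raise ValueError("willingness-to-pay grid must be nonnegative")
        curve.append((float(lam), float(np.mean(lam * dq - dc > 0))))
    return curve


def carry_worst_case_qalys(
    samples: Sequence[PsaSample], donor: Sequence[PsaSample]
) -> list[PsaSample]:
    """Substitute the incremental QALYs of ``donor`` draws into ``samples``.

    Reporting convention for the ineffective-bundle scenario: under
    common random numbers its own incremental QALYs are identically
    zero, so to illustrate the worst plausible health outcome the
    less-effective scenario's QALY draws are carried over.  Off by
    default everywhere; the result is clearly a hybrid and is labelled
    as such by callers.
    """
    if len(samples) != len(donor):
        raise ValueError("sample collections must have equal length")
    return [
        PsaSample(
            draw_index=s.draw_index,
            cost_standard=s.cost_standard,
            qaly_standard=s.qaly_standard,
            cost_bundle=s.cost_bundle,
            qaly_bundle=s.qaly_bundle,
            delta_cost=s.delta_cost,
            delta_qaly=d.delta_qaly,
        )
        for s, d in zip(samples, donor)
    ]


def samples_to_frame(samples: Sequence[PsaSample]):
    """PSA draws as a pandas DataFrame (one row per draw)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "draw_index": [s.draw_index for s in samples],
            "cost_standard": [s.cost_standard for s in samples],
            "qaly_standard": [s.qaly_standard for s in samples],
            "cost_bundle": [s.cost_bundle for s in samples],
            "qaly_bundle": [s.qaly_bundle for s in samples],
            "delta_cost": [s.delta_cost for s in samples],
            "delta_qaly": [s.delta_qaly for s in samples],
        }
    )
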
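"""Patient-level synthetic cohorts and parameter-table fixtures.

The cohort simulator draws each synthetic patient's path through the
decision tree (ARF, vital status, chronic RRT among ARF survivors) from
the arm's branch probabilities and assigns the same terminal-path cost
and QALY formulas the cohort-level rollback uses.  Because payoffs are
deterministic given the path — utility and cost dispersions express
parameter uncertainty, which belongs to the PSA, not patient
heterogeneity — the cohort mean is an unbiased microsimulation estimate
of the rolled-back expectation, which makes the simulator an
independent oracle for the tree engine.

The fixture generator emits a complete three-scenario parameter table
(the role of a supplementary distributions table), including the
calibrated RRT-branch defaults, in the CSV schema that
:func:`sepcea.parameters.read_parameter_table` consumes.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import (
    ARMS,
    SCENARIOS,
    ParameterValues,
    ScenarioParameterSet,
    load_scenario,
    write_parameter_table,
)
from .tree import TERMINAL_PATHS, terminal_cost, terminal_qaly

__all__ = [
    "COHORT_COLUMNS",
    "simulate_cohort",
    "empirical_rates",
    "generate_fixture_table",
]

COHORT_COLUMNS = ("patient_id", "arm", "arf", "died", "rrt", "cost", "qaly")


def simulate_cohort(
    pset: ScenarioParameterSet | ParameterValues,
    arm: str,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate ``n`` patients through one arm of the tree.

    Vital status is drawn independently of ARF status (the tree's
    conditional-independence convention); RRT is drawn only among ARF
    survivors.  Returns a DataFrame with columns ``patient_id, arm, arf,
    died, rrt, cost, qaly``; reproducible by seed.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    if n < 0:
        raise ValueError("n must be nonnegative")
    values = (
        pset.point_values() if isinstance(pset, ScenarioParameterSet) else pset
    )
    p = values.arms[arm]
    rng = np.random.default_rng(seed)

    arf = rng.random(n) < p["p_arf"]
    died = rng.random(n) < p["p_mort"]
    rrt = arf & ~died & (rng.random(n) < p["p_rrt_given_arf_survivor"])

    path_cost = {path: terminal_cost(path, values, arm) for path in TERMINAL_PATHS}
    path_qaly = {path: terminal_qaly(path, values) for path in TERMINAL_PATHS}

    cost = np.empty(n)
    qaly = np.empty(n)
    for path, mask in _path_masks(arf, died, rrt).items():
        cost[mask] = path_cost[path]
        qaly[mask] = path_qaly[path]

    return pd.DataFrame(
        {
            "patient_id": np.arange(n, dtype=int),
            "arm": arm,
            "arf": arf,
            "died": died,
            "rrt": rrt,
            "cost": cost,
            "qaly": qaly,
        }
    )


def _path_masks(arf: np.ndarray, died: np.ndarray, rrt: np.ndarray):
    return {
        ("no_arf", "survive"): ~arf & ~died,
        ("no_arf", "die"): ~arf & died,
        ("arf", "die"): arf & died,
        ("arf", "survive", "no_rrt"): arf & ~died & ~rrt,
        ("arf", "survive", "rrt"): arf & ~died & rrt,
    }


def empirical_rates(cohort: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Observed mortality, ARF and conditional-RRT proportions with
    binomial standard errors sqrt(p(1-p)/n).

    ``rrt_given_arf_survivor`` is computed among ARF survivors (its
    denominator in the tree); if the cohort has none it is reported as
    (nan, nan).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")

    def rate(mask: pd.Series, denom: int) -> tuple[float, float]:
        if denom == 0:
            return (math.nan, math.nan)
        p = float(mask.sum()) / denom
        return (p, math.sqrt(p * (1.0 - p) / denom))

    n = len(cohort)
    arf_survivors = cohort[cohort["arf"] & ~cohort["died"]]
    return {
        "mortality": rate(cohort["died"], n),
        "arf": rate(cohort["arf"], n),
        "rrt_given_arf_survivor": rate(arf_survivors["rrt"], len(arf_survivors)),
    }


def generate_fixture_table(destination: str | Path, seed: int = 0) -> Path:
    """Write the complete three-scenario parameter table to
    ``destination``.

    The table content is fully determined by the model's point values,
    dispersions and calibrated RRT defaults, so it is identical for any
    seed; the seed argument is accepted for interface symmetry with the
    cohort simulator and to emphasize reproducibility.
    """
    destination = Path(destination)
    write_parameter_table([load_scenario(s) for s in SCENARIOS], destination)
    return destination
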
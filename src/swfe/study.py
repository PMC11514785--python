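"""Simulation-study harness: scenario grids, replicate loops, metrics.

Each scenario fixes the design (exposed + unexposed clusters over 5
periods), the true intervention effect, the ICC (via the latent-scale
conversion to the cluster-effect variance tau2), and the average cluster
size.  Per replicate the harness simulates a trial, expands the design
at the realized sizes, fits the fixed-effects GLM, and records the
estimate, its model-based variance, the one-sided 0.05 Wald decision
(testing H0: delta <= 0 for binary outcomes and H0: delta >= 0 for
counts) and whether the 95% Wald CI covers the true effect.  Scenario
metrics over the S replicates:

    abs bias   = mean(delta_hat_s) - delta
    rel bias % = 100 * abs bias / delta                (delta != 0 only)
    precision  = 1 / mean(Var_hat(delta_hat_s))
    power / type-I error = rejection fraction
    coverage   = fraction of 95% CIs containing delta
    RMSE       = sqrt(mean((delta_hat_s - delta)^2))
    MC SE      = SD of delta_hat_s

Replicates that fail to converge (e.g. separation) are excluded from
the averages and disclosed through ``n_converged``; a scenario with more
than 5% non-converged replicates is flagged.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from swfe.design import expand
from swfe.glm import fit, get_family, wald_ci, wald_one_sided
from swfe.simulate import (
    PopulationParams,
    default_mu_alpha,
    replicate_rng,
    scenario_design,
    simulate_trial,
    tau2_from_icc,
)

EXPOSED_LEVELS = (4, 8, 12)
UNEXPOSED_LEVELS = (0, 1, 2, 3, 4)
ICC_LEVELS = (0.01, 0.05, 0.1)
SIZE_LEVELS = (30, 100, 300)
DELTA_LEVELS = {"binary": (0.0, math.log(1.25)), "count": (0.0, math.log(0.80))}
PERIODS = 5
DEFAULT_REPLICATES = 2000
NONCONVERGENCE_FLAG_FRACTION = 0.05


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation-study factorial."""

    exposed: int
    unexposed: int
    delta: float
    icc: float
    mean_cluster_size: int
    family: str
    replicates: int = DEFAULT_REPLICATES
    seed: int = 0
    scenario_id: int = 0

    def __post_init__(self) -> None:
        get_family(self.family)
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.exposed < 1 or self.unexposed < 0:
            raise ValueError("invalid cluster counts")

    def population_params(self) -> PopulationParams:
        mu = default_mu_alpha(self.family)
        return PopulationParams(
            delta=self.delta,
            mu_alpha=mu,
            tau2=tau2_from_icc(self.icc, self.family, mu),
            family=self.family,
            period_slope=0.1,
            size_shape=float(self.mean_cluster_size),
            size_scale=1.0,
        )

    @property
    def test_direction(self) -> str:
        # benefit is an increase for binary outcomes, a decrease for counts
        return "greater" if self.family == "binary" else "less"


@dataclass(frozen=True)
class ScenarioMetrics:
    """Per-scenario simulation summaries."""

    spec: ScenarioSpec = field(repr=False)
    abs_bias: float
    rel_bias_pct: float | None
    precision: float
    power_or_type1: float
    coverage: float
    rmse: float
    mc_se: float
    n_converged: int
    S_effective: int
    convergence_flagged: bool


def build_grid(
    family: str,
    exposed=EXPOSED_LEVELS,
    unexposed=UNEXPOSED_LEVELS,
    deltas=None,
    iccs=ICC_LEVELS,
    sizes=SIZE_LEVELS,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
) -> list[ScenarioSpec]:
    """Full factorial scenario grid in deterministic lexicographic order.

    At the default levels this yields 3 x 5 x 2 x 3 x 3 = 270 scenarios
    per family.  ``scenario_id`` numbers the grid positions and seeds the
    per-replicate random substreams.
    """
    get_family(family)
    if deltas is None:
        deltas = DELTA_LEVELS[family]
    grid = []
    for sid, (e, u, d, icc, n) in enumerate(
        itertools.product(exposed, unexposed, deltas, iccs, sizes)
    ):
        grid.append(
            ScenarioSpec(
                exposed=e, unexposed=u, delta=d, icc=icc, mean_cluster_size=n,
                family=family, replicates=replicates, seed=seed, scenario_id=sid,
            )
        )
    return grid


def _run_replicate(spec: ScenarioSpec, design, params, rep: int):
    """One simulate-expand-fit-test cycle; returns None on non-convergence."""
    rng = replicate_rng(spec.seed, spec.scenario_id, rep)
    data = simulate_trial(design, params, rng)
    expanded = expand(design, data.cell_sizes(design))
    res = fit(data, expanded)
    if not res.converged:
        return None
    test = wald_one_sided(res, spec.test_direction, level=0.05)
    ci = wald_ci(res, level=0.95)
    covered = ci.lower <= spec.delta <= ci.upper
    return res.delta_hat, res.se_delta**2, test.reject, covered


def run_scenario(spec: ScenarioSpec, progress=None) -> ScenarioMetrics:
    """Run all replicates of a scenario and compute the summary metrics."""
    design = scenario_design(spec.exposed, spec.unexposed, PERIODS)
    params = spec.population_params()
    draws = []
    for rep in range(spec.replicates):
        out = _run_replicate(spec, design, params, rep)
        if out is not None:
            draws.append(out)
        if progress is not None and (rep + 1) % 100 == 0:
            progress(rep + 1, spec.replicates)
    if not draws:
        raise RuntimeError(f"no replicate of scenario {spec.scenario_id} converged")

    est = np.array([d[0] for d in draws])
    var = np.array([d[1] for d in draws])
    rej = np.array([d[2] for d in draws], dtype=bool)
    cov = np.array([d[3] for d in draws], dtype=bool)

    abs_bias = float(est.mean() - spec.delta)
    rel = 100.0 * abs_bias / spec.delta if spec.delta != 0 else None
    mc_se = float(est.std(ddof=1)) if len(est) > 1 else 0.0
    n_conv = len(draws)
    return ScenarioMetrics(
        spec=spec,
        abs_bias=abs_bias,
        rel_bias_pct=rel,
        precision=float(1.0 / var.mean()),
        power_or_type1=float(rej.mean()),
        coverage=float(cov.mean()),
        rmse=float(np.sqrt(np.mean((est - spec.delta) ** 2))),
        mc_se=mc_se,
        n_converged=n_conv,
        S_effective=spec.replicates,
        convergence_flagged=(spec.replicates - n_conv)
        > NONCONVERGENCE_FLAG_FRACTION * spec.replicates,
    )


SUMMARY_COLUMNS = [
    "scenario_id", "family", "exposed", "unexposed", "delta", "icc",
    "mean_cluster_size", "replicates", "seed",
    "abs_bias", "rel_bias_pct", "precision", "power_or_type1",
    "coverage", "rmse", "mc_se", "n_converged", "convergence_flagged",
]


def summarize(results: list[ScenarioMetrics]) -> pd.DataFrame:
    """Long-format results table keyed by all scenario factors."""
    if not results:
        raise ValueError("no scenario results to summarize")
    rows = []
    for r in results:
        s = r.spec
        rows.append(
            {
                "scenario_id": s.scenario_id,
                "family": s.family,
                "exposed": s.exposed,
                "unexposed": s.unexposed,
                "delta": s.delta,
                "icc": s.icc,
                "mean_cluster_size": s.mean_cluster_size,
                "replicates": s.replicates,
                "seed": s.seed,
                "abs_bias": r.abs_bias,
                "rel_bias_pct": r.rel_bias_pct,
                "precision": r.precision,
                "power_or_type1": r.power_or_type1,
                "coverage": r.coverage,
                "rmse": r.rmse,
                "mc_se": r.mc_se,
                "n_converged": r.n_converged,
                "convergence_flagged": r.convergence_flagged,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
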
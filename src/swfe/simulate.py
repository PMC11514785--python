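"""SW-CRT trial simulator and ICC conversion utilities.

Data-generating process (cross-sectional, exchangeable within-cluster
correlation): per-cluster random intercepts ``alpha_i ~ N(mu_alpha,
tau2)`` on the link scale; linear predictor ``delta * Z_ij +
period_slope * (j - 1) + alpha_i``; Bernoulli outcomes through the logit
link or Poisson outcomes through the log link, independent given the
cluster effects and sizes.  Cluster-period sample sizes arise in two
stages: an average size per cluster ``n_i ~ Gamma(shape=k, scale=theta)``
drawn once and reused across periods, then realized cell sizes
``n_ij ~ Poisson(n_i)``.

The latent-scale intracluster correlation implied by ``tau2`` is

    binary:  rho = tau2 / (tau2 + pi^2 / 3)
    count:   rho = tau2 / (tau2 + ln(1 + exp(-mu_alpha)))

(logistic-normal and Poisson-lognormal latent-variable approximations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from swfe.design import CellSizes, Design, add_clusters, make_stepped_design
from swfe.glm import OutcomeFamily, TrialData, get_family


@dataclass(frozen=True)
class PopulationParams:
    """True parameters of the trial data-generating process.

    Parameters
    ----------
    delta
        Intervention effect on the link scale (log OR / log RR).
    mu_alpha
        Mean of the cluster random intercepts on the link scale.
    tau2
        Between-cluster variance of the intercepts (>= 0).
    family
        ``"binary"`` or ``"count"``.
    period_slope
        Linear secular trend per period on the link scale; period j
        contributes ``period_slope * (j - 1)`` so phi_1 = 0.
    size_shape, size_scale
        Gamma(shape, scale) law of the per-cluster average size n_i;
        E[n_i] = shape * scale.
    """

    delta: float
    mu_alpha: float
    tau2: float
    family: str
    period_slope: float = 0.1
    size_shape: float = 100.0
    size_scale: float = 1.0

    def __post_init__(self) -> None:
        get_family(self.family)
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if self.size_shape <= 0 or self.size_scale <= 0:
            raise ValueError("gamma size parameters must be positive")

    @property
    def icc(self) -> float:
        return icc_from_tau2(self.tau2, self.family, self.mu_alpha)


def _latent_variance(family: str | OutcomeFamily, mu_alpha: float | None) -> float:
    fam = get_family(family)
    if fam.name == "binary":
        return np.pi**2 / 3.0
    if mu_alpha is None:
        raise ValueError("the count-family ICC approximation needs mu_alpha")
    return float(np.log1p(np.exp(-mu_alpha)))


def icc_from_tau2(
    tau2: float, family: str | OutcomeFamily, mu_alpha: float | None = None
) -> float:
    """Latent-scale ICC implied by the cluster-effect variance tau2.

    Binary: ``tau2 / (tau2 + pi^2/3)``.  Count:
    ``tau2 / (tau2 + ln(1 + 1/exp(mu_alpha)))``.
    """
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    if tau2 == 0:
        return 0.0
    return tau2 / (tau2 + _latent_variance(family, mu_alpha))


def tau2_from_icc(
    icc: float, family: str | OutcomeFamily, mu_alpha: float | None = None
) -> float:
    """Inverse of :func:`icc_from_tau2`; round-trips to 1e-12."""
    if not 0 <= icc < 1:
        raise ValueError("icc must lie in [0, 1)")
    if icc == 0:
        return 0.0
    return icc / (1.0 - icc) * _latent_variance(family, mu_alpha)


def draw_cell_sizes(
    params: PopulationParams, I: int, J: int, rng: np.random.Generator
) -> CellSizes:
    """Draw cluster-period sizes: n_i ~ Gamma(k, theta), n_ij ~ Poisson(n_i)."""
    n_i = rng.gamma(shape=params.size_shape, scale=params.size_scale, size=I)
    n = rng.poisson(lam=np.repeat(n_i[:, None], J, axis=1))
    return CellSizes(n.astype(np.int64))


def simulate_trial(
    design: Design,
    params: PopulationParams,
    rng: np.random.Generator,
    sizes: CellSizes | None = None,
) -> TrialData:
    """Simulate one cross-sectional SW-CRT dataset.

    Cluster effects, cell sizes (unless supplied) and outcomes are drawn
    from ``rng``; outcomes are independent Bernoulli/Poisson draws given
    the cluster effects and sizes.  All cells of the design are
    generated — the data configuration only filters the *analysis*.
    """
    fam = get_family(params.family)
    if sizes is None:
        sizes = draw_cell_sizes(params, design.I, design.J, rng)
    sizes.check_against(design)
    alpha = params.mu_alpha + np.sqrt(params.tau2) * rng.standard_normal(design.I)
    j_idx = np.arange(design.J)
    eta = params.delta * design.Z + params.period_slope * j_idx[None, :] + alpha[:, None]
    mu = fam.mean(eta)

    clusters, periods, treats, ys = [], [], [], []
    for i in range(design.I):
        for j in range(design.J):
            c = int(sizes.n[i, j])
            if c == 0:
                continue
            if fam.name == "binary":
                y = rng.binomial(1, mu[i, j], size=c)
            else:
                y = rng.poisson(mu[i, j], size=c)
            clusters.append(np.full(c, i + 1))
            periods.append(np.full(c, j + 1))
            treats.append(np.full(c, int(design.Z[i, j])))
            ys.append(y)
    records = pd.DataFrame(
        {
            "cluster": np.concatenate(clusters),
            "period": np.concatenate(periods),
            "treat": np.concatenate(treats),
            "y": np.concatenate(ys),
        }
    )
    return TrialData(records=records, family=fam.name)


def replicate_rng(seed: int, scenario_id: int, replicate: int) -> np.random.Generator:
    """Independent, reproducible substream for (seed, scenario, replicate)."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(scenario_id, replicate))
    return np.random.Generator(np.random.PCG64(ss))


CASE_STUDY_SEED = 20171201  # default stream for the synthetic case-study stand-in


def make_case_study_fixture(
    rng: np.random.Generator | None = None,
) -> tuple[Design, TrialData]:
    """Synthetic stand-in for a 5-cluster, 5-period palliative-care-shaped trial.

    Four stepped clusters plus a fifth unexposed cluster (never treated),
    binary outcomes with baseline event probability near 0.30, about
    3460 individuals in total.  The real trial's data are not public;
    this fixture only mimics its shape (clusters, periods, one unexposed
    cluster, overall size and event rate) so the analysis pipeline can
    be exercised end to end.  Deterministic under the default stream.
    """
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(CASE_STUDY_SEED)))
    design = add_clusters(make_stepped_design(4, 5), n_unexposed=1)
    # total N ~= 3462 over 25 cells -> mean cell size ~138.5, i.e. n_i ~ Gamma(138.5, 1)
    params = PopulationParams(
        delta=0.05,
        mu_alpha=float(np.log(0.30 / 0.70)),
        tau2=0.1731,
        family="binary",
        period_slope=0.1,
        size_shape=3462 / 25,
        size_scale=1.0,
    )
    data = simulate_trial(design, params, rng)
    return design, data


def scenario_design(exposed: int, unexposed: int, periods: int = 5) -> Design:
    """Standard wedge with ``exposed`` clusters plus ``unexposed`` all-control clusters."""
    return add_clusters(make_stepped_design(exposed, periods), unexposed, 0)


def default_mu_alpha(family: str | OutcomeFamily) -> float:
    """Baseline cluster-effect mean: ln(0.30/0.70) binary, ln(0.30) count."""
    fam = get_family(family)
    return float(np.log(0.30 / 0.70)) if fam.name == "binary" else float(np.log(0.30))
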
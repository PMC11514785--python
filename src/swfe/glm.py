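"""Fixed-effects logistic and Poisson regression for SW-CRT data.

The analysis model is

    logit(E[Y_ijk]) = delta * Z_ij + phi_j + alpha_i      (binary outcomes)
    log(E[Y_ijk])   = delta * Z_ij + phi_j + alpha_i      (count outcomes)

with a separate fixed effect ``alpha_i`` per cluster and period effects
``phi_j`` (``phi_1 = 0``).  The intervention effect ``delta`` is the log
odds ratio (binary) or log rate ratio (count).  Estimation is by
Newton-Raphson / iteratively reweighted least squares on the full
likelihood; the large-sample covariance of the estimates is the inverse
Fisher information ``(X'VX)^{-1}`` evaluated at the MLE, where
``V = diag(v(mu))`` with variance-function weights ``v(mu) = mu(1-mu)``
for logistic and ``v(mu) = mu`` for Poisson regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln
from scipy.stats import norm

from swfe.design import CellSizes, Design, ExpandedDesign, expand

# IRLS controls: convergence on the score (gradient of the log-likelihood)
SCORE_TOL = 1e-8
MAX_ITER = 100
# any coefficient this large on the link scale is treated as divergent
SEPARATION_BOUND = 20.0
WEIGHT_FLOOR = 1e-12


@dataclass(frozen=True)
class OutcomeFamily:
    """Outcome family: link, mean, variance-function weight, log-likelihood."""

    name: str
    link: str
    mean: Callable[[np.ndarray], np.ndarray]
    weight: Callable[[np.ndarray], np.ndarray]

    def loglik(self, y: np.ndarray, mu: np.ndarray) -> float:
        if self.name == "binary":
            # clip to avoid log(0) in degenerate fitted values
            mu = np.clip(mu, 1e-300, 1 - 1e-16)
            return float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
        # Poisson, with the ln(y!) constant so criteria are comparable
        mu = np.clip(mu, 1e-300, None)
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))

    def check_outcomes(self, y: np.ndarray) -> None:
        if self.name == "binary":
            if not np.isin(y, (0, 1)).all():
                raise ValueError("binary outcomes must be 0 or 1")
        else:
            if (y < 0).any() or not np.all(np.mod(y, 1) == 0):
                raise ValueError("count outcomes must be non-negative integers")


BINARY = OutcomeFamily(
    name="binary",
    link="logit",
    mean=expit,
    weight=lambda mu: mu * (1.0 - mu),
)
COUNT = OutcomeFamily(
    name="count",
    link="log",
    mean=np.exp,
    weight=lambda mu: mu,
)

_FAMILIES = {"binary": BINARY, "count": COUNT}


def get_family(name: str | OutcomeFamily) -> OutcomeFamily:
    """Resolve a family by name (``"binary"`` or ``"count"``)."""
    if isinstance(name, OutcomeFamily):
        return name
    try:
        return _FAMILIES[name]
    except KeyError:
        raise ValueError(f"unknown outcome family {name!r}; expected 'binary' or 'count'")


@dataclass(frozen=True)
class TrialData:
    """Individual-level SW-CRT records.

    ``records`` has one row per individual with columns
    ``cluster, period, treat, y`` (cluster and period 1-based).
    """

    records: pd.DataFrame
    family: str

    def __post_init__(self) -> None:
        required = {"cluster", "period", "treat", "y"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"trial data missing columns: {sorted(missing)}")
        get_family(self.family).check_outcomes(self.records["y"].to_numpy())

    @property
    def n_obs(self) -> int:
        return len(self.records)

    def cell_sizes(self, design: Design) -> CellSizes:
        """Realized cluster-period sample sizes on the design's grid."""
        n = np.zeros((design.I, design.J), dtype=np.int64)
        counts = self.records.groupby(["cluster", "period"]).size()
        for (i, j), c in counts.items():
            if not (1 <= i <= design.I and 1 <= j <= design.J):
                raise ValueError(f"record cell (cluster={i}, period={j}) outside design")
            n[i - 1, j - 1] = c
        return CellSizes(n)

    def check_against(self, design: Design) -> None:
        """Verify every record's treat flag matches the design's Z."""
        df = self.records
        z = design.Z[df["cluster"].to_numpy() - 1, df["period"].to_numpy() - 1]
        bad = df.loc[df["treat"].to_numpy() != z, ["cluster", "period"]]
        if len(bad):
            cells = sorted(set(map(tuple, bad.to_numpy())))
            raise ValueError(f"treat flags disagree with the design in cells {cells}")

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, family: str) -> "TrialData":
        df = pd.read_csv(path)
        return cls(records=df, family=family)


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of the fixed-effects GLM."""

    beta_hat: np.ndarray
    cov: np.ndarray
    delta_hat: float
    se_delta: float
    loglik: float
    n_obs: int
    n_params: int
    converged: bool
    n_iter: int
    column_map: tuple[str, ...]
    family: str
    diagnosis: str | None = None  # e.g. "separation", "max_iter"
    loglik_path: tuple[float, ...] = field(default=(), repr=False)


def mean_response(X: np.ndarray, beta: np.ndarray, family: str | OutcomeFamily) -> np.ndarray:
    """Mean response mu = g^{-1}(X beta) for the given family."""
    fam = get_family(family)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.shape[1] != beta.shape[0]:
        raise ValueError(f"X has {X.shape[1]} columns but beta has {beta.shape[0]} entries")
    return fam.mean(X @ beta)


def glm_weights(mu: np.ndarray, family: str | OutcomeFamily) -> np.ndarray:
    """Variance-function weights v(mu): mu(1-mu) for binary, mu for count."""
    fam = get_family(family)
    mu = np.asarray(mu, dtype=float)
    if fam.name == "binary":
        if ((mu <= 0) | (mu >= 1)).any():
            raise ValueError("binary means must lie strictly inside (0, 1)")
    else:
        if (mu <= 0).any():
            raise ValueError("count means must be strictly positive")
    return fam.weight(mu)


def information_matrix(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Fisher information X'VX with V = diag(w); exactly symmetric."""
    X = np.asarray(X, dtype=float)
    w = np.asarray(w, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")
    M = (X * w[:, None]).T @ X
    return (M + M.T) / 2.0


def _check_rank(X: np.ndarray, column_map: tuple[str, ...]) -> None:
    """Raise if X is rank-deficient, naming columns implicated by QR pivots."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = [column_map[piv[k]] for k in range(len(diag)) if diag[k] <= tol]
    if bad:
        raise ValueError(f"model matrix is rank deficient; collinear columns: {bad}")


def _align_outcomes(data: TrialData, expanded: ExpandedDesign) -> np.ndarray:
    """Order the outcome vector to match the expanded design's rows.

    Within a cluster-period cell individuals are exchangeable, so any
    within-cell order is valid; records are grouped by (cluster, period)
    and laid out in the expanded row order.
    """
    df = data.records
    cells: dict[tuple[int, int], np.ndarray] = {
        (int(i), int(j)): g["y"].to_numpy(dtype=float)
        for (i, j), g in df.groupby(["cluster", "period"])
    }
    y = np.empty(expanded.n_obs)
    pos = 0
    idx = expanded.row_index
    # expanded rows are contiguous per cell in lexicographic order
    boundaries = np.flatnonzero(np.any(np.diff(idx, axis=0) != 0, axis=1)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [expanded.n_obs]])
    for a, b in zip(starts, ends):
        cell = (int(idx[a, 0]), int(idx[a, 1]))
        vals = cells.get(cell)
        if vals is None or len(vals) != b - a:
            have = 0 if vals is None else len(vals)
            raise ValueError(
                f"cell (cluster={cell[0]}, period={cell[1]}): design expects "
                f"{b - a} individuals, data has {have}"
            )
        y[a:b] = vals
        pos += b - a
    if pos != len(df):
        raise ValueError("data contain records in cells absent from the expanded design")
    return y


def _initial_beta(X: np.ndarray, y: np.ndarray, column_map: tuple[str, ...],
                  fam: OutcomeFamily) -> np.ndarray:
    """Start at beta = 0 except cluster effects at link-transformed cluster means."""
    beta = np.zeros(X.shape[1])
    for k, name in enumerate(column_map):
        if not name.startswith("alpha_"):
            continue
        rows = X[:, k] == 1.0
        m = float(y[rows].mean())
        if fam.name == "binary":
            m = min(max(m, 0.02), 0.98)
            beta[k] = np.log(m / (1 - m))
        else:
            beta[k] = np.log(max(m, 0.02))
    return beta


def fit(data: TrialData, expanded: ExpandedDesign) -> FitResult:
    """Fit the fixed-effects GLM by Newton-Raphson IRLS.

    Convergence requires the maximum absolute score component to drop
    below ``1e-8`` within 100 iterations.  Step-halving keeps the
    log-likelihood non-decreasing.  A cluster with all-0 or all-1 binary
    outcomes drives its fixed effect to infinity (complete separation);
    this is detected (coefficient beyond +/-20 on the link scale, or
    weight underflow) and flagged via ``diagnosis="separation"`` with
    ``converged=False`` rather than raised.
    """
    fam = get_family(data.family)
    X = expanded.X
    _check_rank(X, expanded.column_map)
    y = _align_outcomes(data, expanded)
    fam.check_outcomes(y)

    beta = _initial_beta(X, y, expanded.column_map, fam)
    eta = X @ beta
    mu = fam.mean(eta)
    ll = fam.loglik(y, mu)
    ll_path = [ll]
    converged = False
    diagnosis = None
    n_iter = 0

    for n_iter in range(1, MAX_ITER + 1):
        w = fam.weight(mu)
        if w.min() < WEIGHT_FLOOR or np.abs(beta).max() > SEPARATION_BOUND:
            diagnosis = "separation"
            break
        score = X.T @ (y - mu)
        if np.abs(score).max() < SCORE_TOL:
            converged = True
            n_iter -= 1  # this pass only verified convergence
            break
        info = information_matrix(X, w)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            diagnosis = "singular_information"
            break
        # step-halving: never decrease the log-likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            mu_c = fam.mean(X @ cand)
            ll_c = fam.loglik(y, mu_c)
            if ll_c >= ll - 1e-12:
                break
            scale /= 2.0
        beta, mu, ll = cand, mu_c, ll_c
        ll_path.append(ll)
        if np.abs(beta).max() > SEPARATION_BOUND:
            diagnosis = "separation"
            break
    else:
        diagnosis = "max_iter"

    if converged:
        w = fam.weight(mu)
        info = information_matrix(X, w)
        cov = np.linalg.inv(info)
        cov = (cov + cov.T) / 2.0
        se_delta = float(np.sqrt(cov[0, 0]))
    else:
        cov = np.full((X.shape[1], X.shape[1]), np.nan)
        se_delta = float("nan")

    return FitResult(
        beta_hat=beta,
        cov=cov,
        delta_hat=float(beta[0]),
        se_delta=se_delta,
        loglik=ll,
        n_obs=X.shape[0],
        n_params=X.shape[1],
        converged=converged,
        n_iter=n_iter,
        column_map=expanded.column_map,
        family=fam.name,
        diagnosis=diagnosis,
        loglik_path=tuple(ll_path),
    )


@dataclass(frozen=True)
class WaldTest:
    z: float
    p_value: float
    reject: bool
    direction: str
    level: float


def wald_one_sided(fit_result: FitResult, direction: str, level: float = 0.05) -> WaldTest:
    """One-sided Wald test of the intervention effect.

    ``direction="greater"`` tests H0: delta <= 0 (rejects for large
    positive z); ``direction="less"`` tests H0: delta >= 0.
    """
    if not fit_result.converged:
        raise ValueError("cannot test a non-converged fit")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    z = fit_result.delta_hat / fit_result.se_delta
    if direction == "greater":
        p = float(norm.sf(z))
    else:
        p = float(norm.cdf(z))
    return WaldTest(z=float(z), p_value=p, reject=p < level, direction=direction, level=level)


@dataclass(frozen=True)
class WaldCI:
    lower: float
    upper: float
    exp_lower: float
    exp_upper: float
    level: float


def wald_ci(fit_result: FitResult, level: float = 0.95) -> WaldCI:
    """Two-sided Wald CI for delta, on the linear and exponentiated scales.

    The exponentiated interval is the odds-ratio (binary) or rate-ratio
    (count) CI: the exponentials of the linear bounds.
    """
    if not fit_result.converged:
        raise ValueError("cannot form a CI from a non-converged fit")
    z = norm.ppf(0.5 + level / 2.0)
    lo = fit_result.delta_hat - z * fit_result.se_delta
    hi = fit_result.delta_hat + z * fit_result.se_delta
    return WaldCI(lower=float(lo), upper=float(hi),
                  exp_lower=float(np.exp(lo)), exp_upper=float(np.exp(hi)), level=level)


def interval_from_estimate(delta_hat: float, se: float, level: float = 0.95) -> WaldCI:
    """Wald interval directly from (delta_hat, SE), e.g. published table values."""
    z = norm.ppf(0.5 + level / 2.0)
    lo, hi = delta_hat - z * se, delta_hat + z * se
    return WaldCI(lower=float(lo), upper=float(hi),
                  exp_lower=float(np.exp(lo)), exp_upper=float(np.exp(hi)), level=level)


def aic_bic(fit_result: FitResult) -> tuple[float, float]:
    """AIC = -2 loglik + 2p and BIC = -2 loglik + p ln(N)."""
    if not fit_result.converged:
        raise ValueError("criteria require a converged fit")
    p, n = fit_result.n_params, fit_result.n_obs
    return (-2.0 * fit_result.loglik + 2.0 * p,
            -2.0 * fit_result.loglik + p * np.log(n))


@dataclass(frozen=True)
class HomogeneityReport:
    """AIC/BIC comparison of models without/with unexposed-cluster x period terms."""

    aic_base: float
    bic_base: float
    aic_interaction: float
    bic_interaction: float
    aic_favors: str  # "base" or "interaction"
    bic_favors: str
    n_interaction_terms: int
    estimable: bool


def _interaction_columns(expanded: ExpandedDesign, design: Design) -> tuple[np.ndarray, list[str]]:
    """Unexposed-cluster x period dummies (period 1 as reference)."""
    cols, names = [], []
    idx = expanded.row_index
    for i, role in enumerate(design.roles):
        if role != "unexposed":
            continue
        in_cluster = idx[:, 0] == i + 1
        for j in range(2, design.J + 1):
            col = (in_cluster & (idx[:, 1] == j)).astype(float)
            if col.any():
                cols.append(col)
                names.append(f"gamma_{i + 1}_{j}")
    if not cols:
        return np.empty((expanded.n_obs, 0)), []
    return np.column_stack(cols), names


def period_homogeneity_check(data: TrialData, design: Design) -> HomogeneityReport:
    """Compare models excluding vs including unexposed-cluster x period terms.

    Including an unexposed cluster is only sensible if its underlying
    period effects match those of the exposed clusters.  This check fits
    the base fixed-effects model and the model augmented with interaction
    dummies between the unexposed cluster(s) and the period indicators,
    and reports which model AIC and BIC each favor (lower is better).
    """
    if not any(r == "unexposed" for r in design.roles):
        raise ValueError("the homogeneity check requires at least one unexposed cluster")
    sizes = data.cell_sizes(design)
    expanded = expand(design, sizes)
    base = fit(data, expanded)

    inter, names = _interaction_columns(expanded, design)
    if inter.shape[1] == 0:
        # no estimable interaction terms: the two models coincide
        a, b = aic_bic(base)
        return HomogeneityReport(a, b, a, b, "base", "base", 0, estimable=True)

    X_aug = np.column_stack([expanded.X, inter])
    aug = ExpandedDesign(
        X=X_aug,
        column_map=expanded.column_map + tuple(names),
        row_index=expanded.row_index,
        design=design,
    )
    try:
        full = fit(data, aug)
        estimable = full.converged
    except ValueError:
        full = None
        estimable = False
    a0, b0 = aic_bic(base)
    if full is not None and full.converged:
        a1, b1 = aic_bic(full)
    else:
        a1 = b1 = float("nan")
    return HomogeneityReport(
        aic_base=a0, bic_base=b0, aic_interaction=a1, bic_interaction=b1,
        aic_favors="base" if not (a1 < a0) else "interaction",
        bic_favors="base" if not (b1 < b0) else "interaction",
        n_interaction_terms=inter.shape[1],
        estimable=estimable,
    )
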
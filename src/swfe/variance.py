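"""Analytic variance of the intervention-effect estimator.

For the fixed-effects GLM the large-sample covariance of the estimates
is ``(X'VX)^{-1}`` with ``V = diag(v(mu))``.  Ordering the coefficient
vector as ``beta = (delta, phi_2..phi_J, alpha_1..alpha_I)`` and
partitioning the information matrix

    X'VX = [[A, B'],
            [B, D]],

the variance of the intervention-effect estimator is the reciprocal of
the Schur complement:

    Var(delta_hat) = (X'VX)^{-1}_{11} = (A - B' D^{-1} B)^{-1},

where the scalar ``A`` is the total weight of intervention-exposed
observations, ``B`` collects cross-products between the intervention
column and the period/cluster dummies, and ``D`` is the weighted
cross-product of the dummy columns.

Because covariates are constant within a cluster-period cell, the
information matrix is assembled exactly at cell level: each cell
contributes ``n_ij * v(mu_ij) * x_ij x_ij'``, with ``mu_ij`` the mean
implied by the supplied true (or fitted) parameters.  This module
evaluates, for a trial with unexposed clusters, the precision ordering
between the three data configurations

    Var(delta | full)  <  Var(delta | plus_first_period)
                       =  Var(delta | exposed_only)

whenever an unexposed cluster contributes observations in at least two
periods, and the equivalence between adding an unexposed and an
always-exposed cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from swfe.design import (
    CONFIG_EXPOSED_ONLY,
    CONFIG_FULL,
    CONFIG_PLUS_FIRST,
    ROLE_UNEXPOSED,
    CellSizes,
    Design,
    add_clusters,
    make_stepped_design,
)
from swfe.glm import OutcomeFamily, get_family

PSD_TOL = -1e-8          # minimum-eigenvalue tolerance for D_full - D_first
EQUALITY_RTOL = 1e-9     # Var(delta | plus_first_period) == Var(delta | exposed_only)
STRICT_GAP_RTOL = 1e-12  # strict-inequality assertion margin


@dataclass(frozen=True)
class BlockDecomposition:
    """Partition of the information matrix around the intervention column."""

    A: float
    B: np.ndarray
    D: np.ndarray

    @classmethod
    def from_information(cls, M: np.ndarray) -> "BlockDecomposition":
        return cls(A=float(M[0, 0]), B=M[1:, 0].copy(), D=M[1:, 1:].copy())

    def reassemble(self) -> np.ndarray:
        p = 1 + self.B.shape[0]
        M = np.empty((p, p))
        M[0, 0] = self.A
        M[1:, 0] = self.B
        M[0, 1:] = self.B
        M[1:, 1:] = self.D
        return M


def split_beta(beta: np.ndarray, I: int, J: int) -> tuple[float, np.ndarray, np.ndarray]:
    """Split a full-configuration coefficient vector into (delta, phi, alpha).

    ``beta = (delta, phi_2..phi_J, alpha_1..alpha_I)``; the returned
    ``phi`` is length ``J`` with ``phi[0] = 0``.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != 1 + (J - 1) + I:
        raise ValueError(
            f"beta has {beta.shape[0]} entries; expected {1 + (J - 1) + I} "
            f"for I={I}, J={J} (delta, phi_2..phi_J, alpha_1..alpha_I)"
        )
    return float(beta[0]), np.concatenate([[0.0], beta[1 : J]]), beta[J:]


def cell_weights(
    design: Design, sizes: CellSizes, beta: np.ndarray, family: str | OutcomeFamily
) -> np.ndarray:
    """Total GLM weight of each retained cell: n_ij * v(mu_ij)."""
    fam = get_family(family)
    delta, phi, alpha = split_beta(beta, design.I, design.J)
    eta = delta * design.Z + phi[None, :] + alpha[:, None]
    mu = fam.mean(eta)
    w = sizes.n * fam.weight(mu)
    return np.where(design.cell_mask(), w, 0.0)


def information_from_design(
    design: Design, sizes: CellSizes, beta: np.ndarray, family: str | OutcomeFamily
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Exact Fisher information at cell level, with its column labels."""
    sizes.check_against(design)
    w = cell_weights(design, sizes, beta, family)
    mask = design.cell_mask()
    # a cluster with no individuals in any retained cell carries no
    # information and no estimable fixed effect: drop it from the layout
    eff_n = np.where(mask, sizes.n, 0)
    retained = np.flatnonzero(mask.any(axis=1) & (eff_n.sum(axis=1) > 0))
    J = design.J
    p = 1 + (J - 1) + len(retained)
    M = np.zeros((p, p))
    for k, i in enumerate(retained):
        ci = 1 + (J - 1) + k
        for j in range(J):
            if not mask[i, j] or w[i, j] == 0.0:
                continue
            x = np.zeros(p)
            x[0] = design.Z[i, j]
            if j > 0:
                x[j] = 1.0
            x[ci] = 1.0
            M += w[i, j] * np.outer(x, x)
    column_map = (
        ("Z",)
        + tuple(f"phi_{j}" for j in range(2, J + 1))
        + tuple(f"alpha_{i + 1}" for i in retained)
    )
    return (M + M.T) / 2.0, column_map


def schur_variance(M: np.ndarray, column_map: tuple[str, ...] | None = None) -> float:
    """Var(delta_hat) = (A - B' D^{-1} B)^{-1} via symmetric factorization."""
    blocks = BlockDecomposition.from_information(M)
    try:
        c = cho_factor(blocks.D, lower=True)
    except np.linalg.LinAlgError:
        label = "" if column_map is None else f" (columns {column_map[1:]})"
        raise ValueError(
            "the period/cluster block D of the information matrix is singular; "
            f"some period or cluster effect is inestimable{label}"
        )
    schur = blocks.A - float(blocks.B @ cho_solve(c, blocks.B))
    if schur <= 0:
        raise ValueError("non-positive Schur complement: no exposed information")
    return 1.0 / schur


def var_delta(
    design: Design,
    sizes: CellSizes,
    beta: np.ndarray,
    family: str | OutcomeFamily,
) -> float:
    """Analytic Var(delta_hat) for a design under its data configuration.

    ``beta`` supplies the true (design-stage) or fitted (post-fit)
    parameters on the full-configuration layout
    ``(delta, phi_2..phi_J, alpha_1..alpha_I)``; entries of dropped
    clusters are simply unused.
    """
    M, cmap = information_from_design(design, sizes, beta, family)
    return schur_variance(M, cmap)


@dataclass(frozen=True)
class OrderingReport:
    """Numerical check of the configuration precision ordering."""

    var_exposed_only: float
    var_plus_first: float
    var_full: float
    equality_holds: bool       # Var(plus_first) == Var(exposed_only)
    strict_gain: bool          # Var(full) < Var(plus_first), strictly
    d_diff_min_eigenvalue: float
    d_diff_psd: bool
    unexposed_spans_periods: bool


def ordering_report(
    design: Design,
    sizes: CellSizes,
    beta: np.ndarray,
    family: str | OutcomeFamily,
) -> OrderingReport:
    """Compare Var(delta_hat) across the three data configurations.

    Verifies (a) keeping only period 1 of the unexposed clusters leaves
    the variance unchanged relative to dropping them, (b) keeping all
    their periods strictly reduces it whenever an unexposed cluster has
    positive sizes in at least two periods, and (c) the dummy-block
    difference D_full - D_plus_first is positive semi-definite.  When no
    unexposed cluster spans two periods the equality case is reported,
    not raised.
    """
    if not any(r == ROLE_UNEXPOSED for r in design.roles):
        raise ValueError("ordering requires at least one unexposed cluster")
    v_dot = var_delta(design.with_config(CONFIG_EXPOSED_ONLY), sizes, beta, family)
    v_first = var_delta(design.with_config(CONFIG_PLUS_FIRST), sizes, beta, family)
    v_full = var_delta(design.with_config(CONFIG_FULL), sizes, beta, family)

    M_first, _ = information_from_design(
        design.with_config(CONFIG_PLUS_FIRST), sizes, beta, family
    )
    M_full, _ = information_from_design(
        design.with_config(CONFIG_FULL), sizes, beta, family
    )
    d_diff = M_full[1:, 1:] - M_first[1:, 1:]
    min_eig = float(np.linalg.eigvalsh((d_diff + d_diff.T) / 2.0).min())

    spans = any(
        role == ROLE_UNEXPOSED and int((sizes.n[i] > 0).sum()) >= 2
        for i, role in enumerate(design.roles)
    )
    equality = abs(v_first - v_dot) <= EQUALITY_RTOL * max(v_dot, v_first)
    strict = v_full < v_first * (1.0 - STRICT_GAP_RTOL) if spans else False
    return OrderingReport(
        var_exposed_only=v_dot,
        var_plus_first=v_first,
        var_full=v_full,
        equality_holds=equality,
        strict_gain=strict,
        d_diff_min_eigenvalue=min_eig,
        d_diff_psd=min_eig >= PSD_TOL,
        unexposed_spans_periods=spans,
    )


@dataclass(frozen=True)
class EquivalenceReport:
    var_with_unexposed: float
    var_with_always_exposed: float
    abs_difference: float
    rel_difference: float
    matched_weights: bool


def always_exposed_equivalence(
    base: Design,
    base_sizes: CellSizes,
    beta: np.ndarray,
    family: str | OutcomeFamily,
    extra_sizes: np.ndarray,
    extra_alpha: float,
    match_weights: bool = True,
) -> EquivalenceReport:
    """Compare adding one unexposed vs one always-exposed cluster.

    The extra cluster (per-period sizes ``extra_sizes``, intercept
    ``extra_alpha``) is appended twice: once all-control and once
    all-intervention.  With ``match_weights=True`` the always-exposed
    copy's intercept is shifted to ``extra_alpha - delta`` so each of its
    cells carries the same linear predictor — hence the same GLM weight
    total — as the unexposed copy; under matched weights the two
    variances are equal.  With ``match_weights=False`` both variances are
    reported as-is (they differ when ``delta != 0``).
    """
    extra_sizes = np.asarray(extra_sizes, dtype=np.int64)
    if extra_sizes.shape != (base.J,):
        raise ValueError(f"extra_sizes must have one entry per period (J={base.J})")
    delta = float(np.asarray(beta, dtype=float)[0])

    def variance(role_always: bool) -> float:
        d = add_clusters(base, 0, 1) if role_always else add_clusters(base, 1, 0)
        sizes = CellSizes(np.vstack([base_sizes.n, extra_sizes[None, :]]))
        alpha = extra_alpha - delta if (role_always and match_weights) else extra_alpha
        beta_ext = np.concatenate([np.asarray(beta, dtype=float), [alpha]])
        return var_delta(d.with_config(CONFIG_FULL), sizes, beta_ext, family)

    v_u = variance(role_always=False)
    v_a = variance(role_always=True)
    diff = abs(v_u - v_a)
    return EquivalenceReport(
        var_with_unexposed=v_u,
        var_with_always_exposed=v_a,
        abs_difference=diff,
        rel_difference=diff / max(v_u, v_a),
        matched_weights=match_weights,
    )


def _stepped_extension(base_exposed: int, periods: int, k: int) -> Design:
    """Standard wedge plus k additional randomized clusters.

    The extra clusters are assigned to crossover steps round-robin,
    earliest step first, so unbalanced counts remain as even as possible.
    """
    base = make_stepped_design(base_exposed, periods)
    if k == 0:
        return base
    steps = periods - 1
    rows = []
    for m in range(k):
        step = m % steps
        row = np.zeros(periods, dtype=np.int8)
        row[step + 1 :] = 1
        rows.append(row)
    Z = np.vstack([base.Z, np.vstack(rows)])
    roles = base.roles + ("stepped",) * k
    return Design(Z=Z, roles=roles)


def precision_gain_curve(
    base: Design,
    added_clusters: int,
    mode: str,
    cell_size: int,
    beta: np.ndarray,
    family: str | OutcomeFamily,
    extra_alpha: float | None = None,
) -> pd.DataFrame:
    """Precision 1/Var(delta_hat) as clusters are added to a base wedge.

    ``mode="unexposed"`` appends never-treated clusters;
    ``mode="randomized"`` appends clusters randomized into the wedge
    (round-robin over steps).  Added clusters get uniform cell size
    ``cell_size`` and intercept ``extra_alpha`` (default: the mean of the
    base design's cluster effects).  Returns a table with columns
    ``added``, ``mode``, ``variance``, ``precision``.
    """
    if mode not in ("unexposed", "randomized"):
        raise ValueError("mode must be 'unexposed' or 'randomized'")
    n_stepped = sum(r == "stepped" for r in base.roles)
    if n_stepped != base.I:
        raise ValueError("the base design for the gain curve must be a pure wedge")
    beta = np.asarray(beta, dtype=float)
    _, _, alpha_base = split_beta(beta, base.I, base.J)
    if extra_alpha is None:
        extra_alpha = float(alpha_base.mean())

    rows = []
    for k in range(added_clusters + 1):
        if mode == "unexposed":
            d = add_clusters(base, k, 0)
        else:
            d = _stepped_extension(base.I, base.J, k)
        sizes = CellSizes.constant(d, cell_size)
        beta_ext = np.concatenate([beta[: 1 + base.J - 1 + base.I],
                                   np.full(k, extra_alpha)])
        v = var_delta(d.with_config(CONFIG_FULL), sizes, beta_ext, family)
        rows.append({"added": k, "mode": mode, "variance": v, "precision": 1.0 / v})
    return pd.DataFrame(rows)
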
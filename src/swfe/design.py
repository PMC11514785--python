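"""SW-CRT design construction, validation, and model-matrix expansion.

A stepped-wedge design is an ``I x J`` matrix ``Z`` of intervention
indicators: cluster ``i`` is exposed in period ``j`` iff ``Z[i, j] == 1``.
Stepped clusters cross over from control to intervention exactly once
(uni-directional rows, non-decreasing left to right).  A trial may also
contain *unexposed* clusters (all-control rows) or *always-exposed*
clusters (all-intervention rows).

Three data configurations control which observations enter the analysis
of a trial with unexposed clusters:

``exposed_only``
    drop unexposed clusters entirely;
``plus_first_period``
    keep only period 1 of each unexposed cluster;
``full``
    keep everything.

Clusters and periods are 1-based in all user-facing labels, matching the
conventional ``i = 1..I``, ``j = 1..J`` notation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

ROLE_STEPPED = "stepped"
ROLE_UNEXPOSED = "unexposed"
ROLE_ALWAYS = "always_exposed"
ROLES = (ROLE_STEPPED, ROLE_UNEXPOSED, ROLE_ALWAYS)

CONFIG_EXPOSED_ONLY = "exposed_only"
CONFIG_PLUS_FIRST = "plus_first_period"
CONFIG_FULL = "full"
CONFIGS = (CONFIG_EXPOSED_ONLY, CONFIG_PLUS_FIRST, CONFIG_FULL)


@dataclass(frozen=True)
class Design:
    """Intervention layout of an SW-CRT plus per-cluster roles.

    Parameters
    ----------
    Z
        ``I x J`` array of 0/1 intervention indicators.
    roles
        Per-cluster role, each one of ``{"stepped", "unexposed",
        "always_exposed"}``.
    config
        Data configuration selecting which observations enter the
        analysis; one of ``{"exposed_only", "plus_first_period",
        "full"}``.  Defaults to ``"full"``.
    """

    Z: np.ndarray
    roles: tuple[str, ...]
    config: str = CONFIG_FULL

    def __post_init__(self) -> None:
        Z = np.asarray(self.Z, dtype=np.int8)
        object.__setattr__(self, "Z", Z)
        object.__setattr__(self, "roles", tuple(self.roles))
        if Z.ndim != 2:
            raise ValueError("Z must be a 2-D clusters x periods matrix")
        if not np.isin(Z, (0, 1)).all():
            raise ValueError("Z entries must be 0 or 1")
        if len(self.roles) != Z.shape[0]:
            raise ValueError(
                f"got {len(self.roles)} roles for {Z.shape[0]} clusters"
            )
        if self.config not in CONFIGS:
            raise ValueError(f"unknown config {self.config!r}; expected one of {CONFIGS}")
        for i, role in enumerate(self.roles):
            row = Z[i]
            if role == ROLE_STEPPED:
                if (np.diff(row) < 0).any():
                    raise ValueError(
                        f"cluster {i + 1} is stepped but its row is not "
                        "non-decreasing (crossover must be uni-directional)"
                    )
            elif role == ROLE_UNEXPOSED:
                if row.any():
                    raise ValueError(f"cluster {i + 1} is unexposed but its row is not all 0")
            elif role == ROLE_ALWAYS:
                if not row.all():
                    raise ValueError(
                        f"cluster {i + 1} is always_exposed but its row is not all 1"
                    )
            else:
                raise ValueError(f"unknown role {role!r} for cluster {i + 1}")

    @property
    def I(self) -> int:  # noqa: E743 - matches the field's standard symbol
        """Number of clusters."""
        return self.Z.shape[0]

    @property
    def J(self) -> int:
        """Number of periods."""
        return self.Z.shape[1]

    def with_config(self, config: str) -> "Design":
        """Return the same layout under a different data configuration."""
        return replace(self, config=config)

    def cell_mask(self) -> np.ndarray:
        """Boolean ``I x J`` mask of cells retained by ``config``."""
        mask = np.ones(self.Z.shape, dtype=bool)
        for i, role in enumerate(self.roles):
            if role != ROLE_UNEXPOSED:
                continue
            if self.config == CONFIG_EXPOSED_ONLY:
                mask[i, :] = False
            elif self.config == CONFIG_PLUS_FIRST:
                mask[i, 1:] = False
        return mask

    def retained_clusters(self) -> np.ndarray:
        """1-based labels of clusters with at least one retained cell."""
        return np.flatnonzero(self.cell_mask().any(axis=1)) + 1


@dataclass(frozen=True)
class CellSizes:
    """Cluster-period sample sizes ``n[i, j]`` (non-negative integers)."""

    n: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.n)
        if n.ndim != 2:
            raise ValueError("cell sizes must form a 2-D clusters x periods matrix")
        if not np.issubdtype(n.dtype, np.integer):
            if not np.all(np.mod(n, 1) == 0):
                raise ValueError("cell sizes must be integers")
            n = n.astype(np.int64)
        if (n < 0).any():
            raise ValueError("cell sizes must be non-negative")
        object.__setattr__(self, "n", n.astype(np.int64))

    @classmethod
    def constant(cls, design: Design, size: int) -> "CellSizes":
        """Uniform sizes: every cluster-period cell holds ``size`` individuals."""
        return cls(np.full((design.I, design.J), size, dtype=np.int64))

    @property
    def total(self) -> int:
        return int(self.n.sum())

    def check_against(self, design: Design) -> None:
        if self.n.shape != design.Z.shape:
            raise ValueError(
                f"cell sizes shape {self.n.shape} does not match design "
                f"{design.Z.shape}"
            )


@dataclass(frozen=True)
class ExpandedDesign:
    """Individual-level model matrix for the fixed-effects GLM.

    ``X`` has one row per individual and columns in the fixed order
    ``(Z, phi_2..phi_J, alpha_1..alpha_I')`` where ``I'`` counts clusters
    retained by the design's data configuration.  There is no global
    intercept; ``phi_1 = 0`` for identifiability.  ``row_index`` holds
    the 1-based (cluster, period) pair of every row.
    """

    X: np.ndarray
    column_map: tuple[str, ...]
    row_index: np.ndarray  # (N, 2) int array of 1-based (cluster, period)
    design: Design = field(repr=False)

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_params(self) -> int:
        return self.X.shape[1]


def make_stepped_design(exposed_clusters: int, periods: int) -> Design:
    """Balanced standard wedge: equal numbers of clusters cross at each step.

    All clusters start in control in period 1; one block of
    ``exposed_clusters / (periods - 1)`` clusters crosses over at each of
    the ``periods - 1`` steps, the first block at period 2.  Earlier
    clusters cross earlier.

    Raises
    ------
    ValueError
        If ``exposed_clusters`` is not divisible by ``periods - 1``
        (only balanced steps are supported) or ``periods < 2``.
    """
    if periods < 2:
        raise ValueError("a stepped-wedge design needs at least 2 periods")
    if exposed_clusters < 1:
        raise ValueError("need at least one exposed cluster")
    steps = periods - 1
    if exposed_clusters % steps != 0:
        raise ValueError(
            f"{exposed_clusters} exposed clusters cannot be split evenly over "
            f"{steps} steps; counts must be divisible"
        )
    per_step = exposed_clusters // steps
    Z = np.zeros((exposed_clusters, periods), dtype=np.int8)
    for step in range(steps):
        rows = slice(step * per_step, (step + 1) * per_step)
        Z[rows, step + 1 :] = 1
    return Design(Z=Z, roles=(ROLE_STEPPED,) * exposed_clusters)


def add_clusters(design: Design, n_unexposed: int, n_always: int = 0) -> Design:
    """Append unexposed (all-0) and/or always-exposed (all-1) clusters."""
    if n_unexposed < 0 or n_always < 0:
        raise ValueError("cluster counts must be non-negative")
    if n_unexposed == 0 and n_always == 0:
        return design
    blocks = [design.Z]
    roles = list(design.roles)
    if n_unexposed:
        blocks.append(np.zeros((n_unexposed, design.J), dtype=np.int8))
        roles += [ROLE_UNEXPOSED] * n_unexposed
    if n_always:
        blocks.append(np.ones((n_always, design.J), dtype=np.int8))
        roles += [ROLE_ALWAYS] * n_always
    return Design(Z=np.vstack(blocks), roles=tuple(roles), config=design.config)


def expand(design: Design, sizes: CellSizes) -> ExpandedDesign:
    """Expand a design to the individual-level model matrix ``X``.

    The data configuration filter is applied first; only retained cells
    produce rows and only retained clusters get a fixed-effect column.
    Rows are ordered lexicographically by (cluster, period, individual).

    Raises
    ------
    ValueError
        If a retained cluster has zero individuals in every retained
        period — its fixed effect would be inestimable.
    """
    sizes.check_against(design)
    mask = design.cell_mask()
    eff_n = np.where(mask, sizes.n, 0)
    retained = np.flatnonzero(mask.any(axis=1))  # 0-based cluster indices
    empty = [int(i) + 1 for i in retained if eff_n[i].sum() == 0]
    if empty:
        raise ValueError(
            f"retained cluster(s) {empty} have zero individuals in all "
            "periods; their fixed effects are inestimable"
        )

    J = design.J
    p = 1 + (J - 1) + len(retained)
    col_of_cluster = {i: 1 + (J - 1) + k for k, i in enumerate(retained)}

    N = int(eff_n.sum())
    X = np.zeros((N, p))
    row_index = np.empty((N, 2), dtype=np.int64)
    pos = 0
    for i in retained:
        for j in range(J):
            c = int(eff_n[i, j])
            if c == 0:
                continue
            rows = slice(pos, pos + c)
            X[rows, 0] = design.Z[i, j]
            if j > 0:
                X[rows, j] = 1.0
            X[rows, col_of_cluster[i]] = 1.0
            row_index[rows, 0] = i + 1
            row_index[rows, 1] = j + 1
            pos += c

    column_map = (
        ("Z",)
        + tuple(f"phi_{j}" for j in range(2, J + 1))
        + tuple(f"alpha_{i + 1}" for i in retained)
    )
    return ExpandedDesign(X=X, column_map=column_map, row_index=row_index, design=design)


def write_design_csv(design: Design, path: str | Path) -> None:
    """Write a design as CSV: one row per cluster, 0/1 periods + role column."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([f"period_{j}" for j in range(1, design.J + 1)] + ["role"])
        for i in range(design.I):
            writer.writerow([int(z) for z in design.Z[i]] + [design.roles[i]])


def read_design_csv(path: str | Path, config: str = CONFIG_FULL) -> Design:
    """Read a design written by :func:`write_design_csv`."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if not header or header[-1] != "role":
            raise ValueError(f"{path}: expected a trailing 'role' column")
        rows, roles = [], []
        for line in reader:
            if not line:
                continue
            rows.append([int(v) for v in line[:-1]])
            roles.append(line[-1])
    if not rows:
        raise ValueError(f"{path}: design file contains no clusters")
    return Design(Z=np.array(rows, dtype=np.int8), roles=tuple(roles), config=config)
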
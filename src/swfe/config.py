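"""Run-configuration parsing and validation for the command-line surface.

Configs are YAML mappings.  Validation is eager and exhaustive: every
violation found is reported in a single error, and unknown keys are
rejected by name.  The cluster-effect variance may be given either as
``tau2`` directly or as ``icc`` (converted through the latent-scale
approximation); supplying both is an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from swfe.glm import get_family
from swfe.simulate import PopulationParams, default_mu_alpha, tau2_from_icc

_KNOWN_KEYS = {
    "family", "delta", "mu_alpha", "tau2", "icc", "period_slope",
    "mean_cluster_size", "size_scale", "replicates", "seed",
    "exposed", "unexposed", "periods", "verbosity",
}
_DEFAULTS = {
    "period_slope": 0.1,
    "size_scale": 1.0,
    "mean_cluster_size": 100,
    "replicates": 2000,
    "verbosity": 1,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration with defaults applied."""

    family: str
    delta: float
    mu_alpha: float
    tau2: float
    period_slope: float
    mean_cluster_size: float
    size_scale: float
    replicates: int
    seed: int
    exposed: int | None = None
    unexposed: int | None = None
    periods: int = 5
    verbosity: int = 1

    def population_params(self) -> PopulationParams:
        return PopulationParams(
            delta=self.delta,
            mu_alpha=self.mu_alpha,
            tau2=self.tau2,
            family=self.family,
            period_slope=self.period_slope,
            size_shape=float(self.mean_cluster_size) / self.size_scale,
            size_scale=self.size_scale,
        )

    def echo(self) -> dict:
        """Plain-dict form for provenance records."""
        return {k: getattr(self, k) for k in (
            "family", "delta", "mu_alpha", "tau2", "period_slope",
            "mean_cluster_size", "size_scale", "replicates", "seed",
            "exposed", "unexposed", "periods",
        )}


def parse_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Raises ``ValueError`` listing *every* violation at once.
    """
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")

    errors: list[str] = []
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    for key in unknown:
        errors.append(f"unknown key {key!r}")

    merged = {**_DEFAULTS, **{k: v for k, v in raw.items() if k in _KNOWN_KEYS}}

    family = merged.get("family")
    if family is None:
        errors.append("missing required key 'family'")
    else:
        try:
            get_family(family)
        except ValueError as e:
            errors.append(str(e))
            family = None

    if "seed" not in merged:
        errors.append("missing required key 'seed' (stochastic runs must be seeded)")
    if "delta" not in merged:
        errors.append("missing required key 'delta'")

    if "icc" in merged and "tau2" in merged:
        errors.append("'icc' and 'tau2' are mutually exclusive; supply exactly one")
    if "icc" not in merged and "tau2" not in merged:
        errors.append("one of 'icc' or 'tau2' is required")

    mu_alpha = merged.get("mu_alpha")
    if mu_alpha is None and family is not None:
        mu_alpha = default_mu_alpha(family)

    tau2 = merged.get("tau2")
    if tau2 is None and "icc" in merged and family is not None:
        icc = merged["icc"]
        try:
            tau2 = tau2_from_icc(float(icc), family, mu_alpha)
        except (TypeError, ValueError) as e:
            errors.append(f"invalid icc: {e}")
    if tau2 is not None and tau2 < 0:
        errors.append("tau2 must be non-negative")

    replicates = merged.get("replicates")
    if not isinstance(replicates, int) or replicates < 1:
        errors.append(f"replicates must be a positive integer, got {replicates!r}")
    if merged.get("mean_cluster_size", 1) <= 0:
        errors.append("mean_cluster_size must be positive")
    if merged.get("size_scale", 1) <= 0:
        errors.append("size_scale must be positive")

    if errors:
        raise ValueError(f"{path}: invalid configuration:\n  - " + "\n  - ".join(errors))

    return RunConfig(
        family=family,
        delta=float(merged["delta"]),
        mu_alpha=float(mu_alpha),
        tau2=float(tau2),
        period_slope=float(merged["period_slope"]),
        mean_cluster_size=float(merged["mean_cluster_size"]),
        size_scale=float(merged["size_scale"]),
        replicates=int(replicates),
        seed=int(merged["seed"]),
        exposed=merged.get("exposed"),
        unexposed=merged.get("unexposed"),
        periods=int(merged.get("periods", 5)),
        verbosity=int(merged.get("verbosity", 1)),
    )
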
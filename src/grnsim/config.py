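"""Key-value simulation configuration (.tsim-style dialect).

Files are ``key = value`` lines; ``#`` starts a comment; keys are
case-insensitive.  Every key is validated against the preconditions of the
module that consumes it, so a config that parses cannot violate a module
contract downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import get_type_hints

__all__ = ["ConfigError", "SimulationConfig", "parse_config", "write_config"]

_MODES = ("deterministic", "stochastic", "delay")
_BINDING_FORMS = ("occupancy", "literal")


class ConfigError(ValueError):
    """Raised for unknown keys, type mismatches or constraint violations."""


@dataclass
class SimulationConfig:
    # run control
    seed: int = 1
    workers: int = 1
    outdir: str = "output"
    trajectory_dump: bool = False
    # population
    n_individuals: int = 100
    n_genes: int = 50
    n_core: int = 12
    allele_probs: tuple = (1 / 3, 1 / 3, 1 / 3)
    genotype_file: str = ""
    core_file: str = ""
    # network geometry
    network_prefix: str = ""
    basal_fractions: tuple = (1.0, 0.0, 0.0)
    basal_shape_d1: tuple = (1.0, 0.0)
    basal_shape_d2: tuple = (1.0, 0.0)
    basal_shape_d3: tuple = (1.0, 0.0)
    edge_rate: float = 0.02
    merge_iterations: int = 1
    activation_fraction: float = 0.5
    # polymorphism map
    p_mu: float = 2.0
    kappa: float = 0.5
    kappa_expression: float = -1.0  # -1 means "follow kappa"
    # dynamics
    mode: str = "deterministic"
    tmax: float = 200.0
    tau: float = 0.0
    gamma: float = 0.0
    sigma_q: float = 0.01
    rel_tol: float = 1e-4
    abs_tol: float = 1e-7
    burn_in: float = 0.2
    gp: float = 1.0
    h: float = 1.0
    ga: float = 9.0
    gr: float = 9.0
    phi_a: float = 2.0
    h_a: float = 1.0
    h_r: float = 1.0
    exponent_base: int = 0  # 0 means "number of genes"
    binding_form: str = "occupancy"
    per_gene_exponent: bool = False
    ks: float = 0.5
    zx: float = 0.2
    zs: float = 0.05
    # study grids
    kappa_grid: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    phi: float = 0.0
    phi_grid: tuple = (0.05, 0.1, 0.2, 0.3)
    n_replicates: int = 10
    omega: float = 1.0
    sigma_env2: float = 0.0

    def validate(self) -> None:
        def fail(key: str, msg: str) -> None:
            raise ConfigError(f"config key {key!r}: {msg}")

        if self.seed < 0:
            fail("seed", "must be nonnegative")
        if self.workers < 1:
            fail("workers", "must be >= 1")
        if self.n_individuals < 1:
            fail("n_individuals", "must be >= 1")
        if self.n_genes < 1:
            fail("n_genes", "must be >= 1")
        if not (0 <= self.n_core <= self.n_genes):
            fail("n_core", f"must be in 0..{self.n_genes}")
        probs = self.allele_probs
        if len(probs) != 3 or any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            fail("allele_probs", "must be 3 nonnegative reals summing to 1")
        if len(self.basal_fractions) != 3 or any(f < 0 for f in self.basal_fractions):
            fail("basal_fractions", "must be 3 nonnegative reals")
        if abs(sum(self.basal_fractions) - 1.0) > 1e-9:
            fail("basal_fractions", "must sum to 1")
        for key in ("basal_shape_d1", "basal_shape_d2", "basal_shape_d3"):
            if len(getattr(self, key)) != 2:
                fail(key, "must be two reals (flavor, inverse temperature)")
        if not self.edge_rate > 0:
            fail("edge_rate", "must be > 0")
        if self.merge_iterations < 0:
            fail("merge_iterations", "must be >= 0")
        if not (0.0 <= self.activation_fraction <= 1.0):
            fail("activation_fraction", "must be in [0, 1]")
        if not self.p_mu > 0:
            fail("p_mu", "must be positive")
        if not (0.0 <= self.kappa <= 1.0):
            fail("kappa", f"kappa must be in [0, 1], got {self.kappa}")
        if self.kappa_expression != -1.0 and not (0.0 <= self.kappa_expression <= 1.0):
            fail("kappa_expression", "must be in [0, 1] or -1 to follow kappa")
        if self.mode not in _MODES:
            fail("mode", f"must be one of {_MODES}")
        if not self.tmax > 0:
            fail("tmax", "must be positive")
        if self.tau < 0 or self.gamma < 0 or self.sigma_q < 0:
            fail("tau", "tau, gamma, sigma_q must be nonnegative")
        if self.mode == "stochastic" and self.tau > 0:
            fail("tau", "stochastic mode forces tau = 0")
        if self.mode == "delay" and self.gamma > 0:
            fail("gamma", "delay mode requires gamma = 0")
        if not (0.0 <= self.burn_in < 1.0):
            fail("burn_in", "must be in [0, 1)")
        if not (self.rel_tol > 0 and self.abs_tol > 0):
            fail("rel_tol", "tolerances must be positive")
        for key in ("h", "h_a", "h_r", "phi_a", "ks", "zx", "zs"):
            if not getattr(self, key) > 0:
                fail(key, "must be positive")
        if self.exponent_base < 0:
            fail("exponent_base", "must be >= 1, or 0 for 'number of genes'")
        if self.binding_form not in _BINDING_FORMS:
            fail("binding_form", f"must be one of {_BINDING_FORMS}")
        for key in ("kappa_grid",):
            if any(not (0.0 <= k <= 1.0) for k in getattr(self, key)):
                fail(key, "kappa must be in [0, 1]")
        if self.phi < 0 or any(p < 0 for p in self.phi_grid):
            fail("phi", "phi values must be nonnegative")
        if self.n_replicates < 1:
            fail("n_replicates", "must be >= 1")
        if not self.omega > 0:
            fail("omega", "must be positive")
        if self.sigma_env2 < 0:
            fail("sigma_env2", "must be nonnegative")


_HINTS = get_type_hints(SimulationConfig)
_FIELDS = {f.name: f for f in fields(SimulationConfig)}


def _parse_value(key: str, raw: str, lineno: int):
    kind = _HINTS[key]
    raw = raw.strip()
    try:
        if kind is bool:
            low = raw.lower()
            if low in ("1", "true", "yes", "on"):
                return True
            if low in ("0", "false", "no", "off"):
                return False
            raise ValueError(f"not a boolean: {raw!r}")
        if kind is int:
            return int(raw)
        if kind is float:
            return float(raw)
        if kind is tuple:
            parts = raw.replace(",", " ").split()
            return tuple(float(p) for p in parts)
        return raw
    except ValueError as exc:
        raise ConfigError(f"line {lineno}: key {key!r}: {exc}") from None


def parse_config(path) -> SimulationConfig:
    """Parse and fully validate a configuration file."""
    values = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            if "=" not in text:
                raise ConfigError(f"{path}: line {lineno}: expected 'key = value'")
            key_raw, val_raw = text.split("=", 1)
            key = key_raw.strip().lower()
            if key not in _FIELDS:
                raise ConfigError(f"{path}: line {lineno}: unknown key {key!r}")
            values[key] = _parse_value(key, val_raw, lineno)
    cfg = SimulationConfig(**values)
    cfg.validate()
    return cfg


def write_config(cfg: SimulationConfig, path) -> None:
    """Write a config so that ``parse_config(write_config(c)) == c``."""
    with open(path, "w") as fh:
        for f in fields(cfg):
            value = getattr(cfg, f.name)
            if isinstance(value, tuple):
                rendered = " ".join(repr(v) for v in value)
            elif isinstance(value, bool):
                rendered = "true" if value else "false"
            elif isinstance(value, float):
                rendered = repr(value)
            else:
                rendered = str(value)
            fh.write(f"{f.name} = {rendered}\n")
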
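"""Coupled mRNA/protein dynamics under a thermodynamic binding model.

Each gene transcribes at a rate proportional to the binding probability of
the polymerase complex at its promoter.  That probability is modulated by
the (possibly delayed) protein concentrations of the gene's activators and
repressors through Boltzmann-weighted binding factors.  The resulting
system

    dx/dt = Kx * p(s(t - tau)) - Zx * x
    ds/dt = Ks * x(t - tau)    - Zs * s

is integrated either as a stochastic problem (fixed-step Euler-Maruyama
with multiplicative noise, tau = 0) or as a delay problem (embedded
Runge-Kutta 2(3) pair with cubic-Hermite history interpolation).
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field, replace

import numpy as np

from .network import RegulatoryNetwork

__all__ = [
    "RegulatoryParameters",
    "KineticParameters",
    "SystemState",
    "Trajectory",
    "ModeError",
    "SimulationError",
    "DdeSolution",
    "default_regulatory_params",
    "default_kinetic_params",
    "masked_concentrations",
    "activator_factor",
    "repressor_factor",
    "regulatory_factor",
    "binding_probability",
    "binding_probabilities",
    "rhs",
    "integrate_em",
    "integrate_dde",
    "solve_dde",
    "simulate_genotype",
]

EM_STEP_FRACTION = 5e-4  # dt = EM_STEP_FRACTION * Tmax, i.e. 2000 steps per run
MODES = ("stochastic", "delay", "deterministic")


class ModeError(ValueError):
    """Raised when integrator and kinetic parameters disagree on the mode."""


class SimulationError(RuntimeError):
    """Solver failure, annotated with the genotype being simulated."""


def _as_vector(value, n: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"{name} must be a scalar or length-{n} vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass(eq=False)
class RegulatoryParameters:
    """Thermodynamic constants of the promoter-binding kernel.

    ``binding_form`` selects between the occupancy reading
    ``p_i = 2 / (1 + exp(Gp_i/H_i) / F_i)`` (default) and the literal
    matrix reading ``p_i = 2 exp(-Gp_i/H_i) / (1 + F_i)``.
    ``exponent_base`` is the ``n`` of the 1/n exponents of the binding
    factors; ``per_gene_exponent`` replaces it by each target's regulator
    count instead.
    """

    Gp: np.ndarray
    H: np.ndarray
    GA: np.ndarray
    GR: np.ndarray
    Phi: np.ndarray
    hA: float = 1.0
    hR: float = 1.0
    exponent_base: int = 1
    binding_form: str = "occupancy"
    per_gene_exponent: bool = False

    def __post_init__(self) -> None:
        n = np.asarray(self.Gp, dtype=float).size
        self.Gp = _as_vector(self.Gp, n, "Gp")
        self.H = _as_vector(self.H, n, "H")
        self.GA = _as_vector(self.GA, n, "GA")
        self.GR = _as_vector(self.GR, n, "GR")
        self.Phi = _as_vector(self.Phi, n, "Phi")
        if np.any(self.H <= 0):
            raise ValueError("H must be strictly positive")
        if np.any(self.Phi <= 0):
            raise ValueError("Phi must be strictly positive")
        if not (self.hA > 0 and self.hR > 0):
            raise ValueError("hA and hR must be strictly positive")
        if self.exponent_base < 1:
            raise ValueError(f"exponent_base must be >= 1, got {self.exponent_base}")
        if self.binding_form not in ("occupancy", "literal"):
            raise ValueError(f"unknown binding_form {self.binding_form!r}")

    @property
    def n_genes(self) -> int:
        return int(self.Gp.size)


@dataclass(eq=False)
class KineticParameters:
    """Per-gene rate constants plus the run-level mode parameters."""

    Kx: np.ndarray
    Ks: np.ndarray
    Zx: np.ndarray
    Zs: np.ndarray
    tau: float = 0.0
    gamma: float = 0.0
    sigma_q: float = 0.0
    Tmax: float = 200.0

    def __post_init__(self) -> None:
        n = np.asarray(self.Kx, dtype=float).size
        self.Kx = _as_vector(self.Kx, n, "Kx")
        self.Ks = _as_vector(self.Ks, n, "Ks")
        self.Zx = _as_vector(self.Zx, n, "Zx")
        self.Zs = _as_vector(self.Zs, n, "Zs")
        for name, v in (("Kx", self.Kx), ("Ks", self.Ks), ("Zx", self.Zx), ("Zs", self.Zs)):
            if np.any(v <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if self.tau < 0 or self.gamma < 0 or self.sigma_q < 0:
            raise ValueError("tau, gamma and sigma_q must be nonnegative")
        if self.tau > 0 and self.gamma > 0:
            raise ValueError("stochastic mode forces tau=0: tau and gamma cannot both be positive")
        if not self.Tmax > 0:
            raise ValueError(f"Tmax must be positive, got {self.Tmax}")

    @property
    def n_genes(self) -> int:
        return int(self.Kx.size)


@dataclass(eq=False)
class SystemState:
    """Instantaneous mRNA (x) and protein (s) concentrations."""

    x: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.x.shape != self.s.shape or self.x.ndim != 1:
            raise ValueError("x and s must be 1-D vectors of equal length")
        if np.any(self.x < 0) or np.any(self.s < 0):
            raise ValueError("concentrations must be nonnegative")


@dataclass(eq=False)
class Trajectory:
    """Time-indexed mRNA/protein concentrations of one integration run."""

    times: np.ndarray
    x: np.ndarray  # (T, n)
    s: np.ndarray  # (T, n)
    mode: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.times.ndim != 1 or self.x.shape != self.s.shape or self.x.shape[0] != self.times.size:
            raise ValueError("inconsistent trajectory shapes")


def default_regulatory_params(
    n: int,
    Gp=1.0,
    H=1.0,
    GA=9.0,
    GR=9.0,
    Phi=2.0,
    hA: float = 1.0,
    hR: float = 1.0,
    exponent_base: int | None = None,
    binding_form: str = "occupancy",
    per_gene_exponent: bool = False,
) -> RegulatoryParameters:
    """Repository default constants (order-of-magnitude choices, not fitted)."""
    return RegulatoryParameters(
        Gp=_as_vector(Gp, n, "Gp"),
        H=_as_vector(H, n, "H"),
        GA=_as_vector(GA, n, "GA"),
        GR=_as_vector(GR, n, "GR"),
        Phi=_as_vector(Phi, n, "Phi"),
        hA=hA,
        hR=hR,
        exponent_base=n if exponent_base is None else exponent_base,
        binding_form=binding_form,
        per_gene_exponent=per_gene_exponent,
    )


def default_kinetic_params(
    n: int,
    Kx=2.0,
    Ks=0.5,
    Zx=0.2,
    Zs=0.05,
    tau: float = 0.0,
    gamma: float = 0.0,
    sigma_q: float = 0.0,
    Tmax: float = 200.0,
) -> KineticParameters:
    """Mammalian-cell order-of-magnitude rates (minutes); repository defaults."""
    return KineticParameters(
        Kx=_as_vector(Kx, n, "Kx"),
        Ks=_as_vector(Ks, n, "Ks"),
        Zx=_as_vector(Zx, n, "Zx"),
        Zs=_as_vector(Zs, n, "Zs"),
        tau=tau,
        gamma=gamma,
        sigma_q=sigma_q,
        Tmax=Tmax,
    )


# ---------------------------------------------------------------------------
# thermodynamic kernel
# ---------------------------------------------------------------------------

def masked_concentrations(s_delayed: np.ndarray, adjacency: np.ndarray, i: int) -> np.ndarray:
    """Concentrations of gene i's regulators: ``s_delayed * adjacency[:, i]``."""
    s_delayed = np.asarray(s_delayed, dtype=float)
    adjacency = np.asarray(adjacency)
    if adjacency.ndim != 2 or adjacency.shape[0] != s_delayed.size:
        raise ValueError("adjacency shape does not match concentration vector")
    if not (0 <= i < adjacency.shape[1]):
        raise IndexError(f"gene index {i} out of range")
    return s_delayed * adjacency[:, i]


def activator_factor(sA: np.ndarray, params: RegulatoryParameters) -> np.ndarray:
    """Entrywise ``[(hA + s^2 e^-GA Phi) / (hA + s^2 e^-GA)]^(1/n)``; 1 at s=0."""
    sA = np.asarray(sA, dtype=float)
    s2e = sA * sA * np.exp(-params.GA)
    base = (params.hA + s2e * params.Phi) / (params.hA + s2e)
    return base ** (1.0 / params.exponent_base)


def repressor_factor(sR: np.ndarray, params: RegulatoryParameters) -> np.ndarray:
    """Entrywise ``[1 + hR s^2 e^-GR]^(-1/n)``; in (0, 1], 1 at s=0."""
    sR = np.asarray(sR, dtype=float)
    return (1.0 + params.hR * sR * sR * np.exp(-params.GR)) ** (-1.0 / params.exponent_base)


def regulatory_factor(fA: np.ndarray, fR: np.ndarray) -> float:
    """Determinant of the diagonal product of the factor matrices: prod(fA)*prod(fR)."""
    return float(np.prod(np.asarray(fA, dtype=float)) * np.prod(np.asarray(fR, dtype=float)))


def binding_probability(F, params: RegulatoryParameters) -> np.ndarray:
    """Promoter binding probability from regulatory factors, clamped to [0, 1]."""
    F = np.asarray(F, dtype=float)
    g = params.Gp / params.H
    if params.binding_form == "occupancy":
        p = 2.0 / (1.0 + np.exp(g) / F)
    else:
        p = 2.0 * np.exp(-g) / (1.0 + F)
    return np.clip(p, 0.0, 1.0)


def _log_factor_terms(s: np.ndarray, reg: RegulatoryParameters):
    """Per-regulator log binding factors before the 1/n exponent."""
    s2 = s * s
    ea = s2 * np.exp(-reg.GA)
    log_a = np.log(reg.hA + ea * reg.Phi) - np.log(reg.hA + ea)
    log_r = -np.log1p(reg.hR * s2 * np.exp(-reg.GR))
    return log_a, log_r


def binding_probabilities(
    s: np.ndarray, reg: RegulatoryParameters, net: RegulatoryNetwork
) -> np.ndarray:
    """Vectorised binding probabilities of all genes given regulator proteins.

    Equivalent to masking concentrations per target and multiplying the
    per-regulator factors: absent regulators contribute a factor of 1.
    """
    AT = net.A.T.astype(float)
    RT = net.R.T.astype(float)
    return _binding_probabilities_fast(np.asarray(s, dtype=float), reg, AT, RT,
                                       _exponents(reg, net))


def _exponents(reg: RegulatoryParameters, net: RegulatoryNetwork) -> np.ndarray:
    if reg.per_gene_exponent:
        nb = np.asarray(net.N.sum(axis=0), dtype=float).ravel()
        return np.maximum(nb, 1.0)
    return np.full(reg.n_genes, float(reg.exponent_base))


def _binding_probabilities_fast(s, reg, AT, RT, exponents):
    log_a, log_r = _log_factor_terms(s, reg)
    logF = (AT @ log_a + RT @ log_r) / exponents
    return binding_probability(np.exp(logF), reg)


def rhs(
    state: SystemState,
    x_delayed: np.ndarray,
    s_delayed: np.ndarray,
    kin: KineticParameters,
    reg: RegulatoryParameters,
    net: RegulatoryNetwork,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic part of the rate equations at the given (delayed) state."""
    x_delayed = np.asarray(x_delayed, dtype=float)
    s_delayed = np.asarray(s_delayed, dtype=float)
    n = kin.n_genes
    if state.x.size != n or x_delayed.size != n or s_delayed.size != n:
        raise ValueError("state dimension does not match kinetic parameters")
    p = binding_probabilities(s_delayed, reg, net)
    dx = kin.Kx * p - kin.Zx * state.x
    ds = kin.Ks * x_delayed - kin.Zs * state.s
    return dx, ds


# ---------------------------------------------------------------------------
# Euler-Maruyama (stochastic mode, tau = 0)
# ---------------------------------------------------------------------------

def integrate_em(
    initial: SystemState,
    kin: KineticParameters,
    reg: RegulatoryParameters,
    net: RegulatoryNetwork,
    seed=None,
) -> Trajectory:
    """Fixed-step Euler-Maruyama integration with multiplicative noise.

    The step is ``dt = 5e-4 * Tmax`` (2000 steps regardless of Tmax);
    the update is ``c += f(c) dt + gamma * c * eta`` with
    ``eta ~ Normal(0, sigma_q^2 dt)`` i.i.d. per component, and states
    are clamped at zero after every step.
    """
    if kin.tau != 0:
        raise ModeError(f"stochastic mode requires tau=0, got tau={kin.tau}")
    n = kin.n_genes
    n_steps = int(round(1.0 / EM_STEP_FRACTION))
    dt = EM_STEP_FRACTION * kin.Tmax
    rng = np.random.default_rng(seed)
    AT = net.A.T.astype(float)
    RT = net.R.T.astype(float)
    exponents = _exponents(reg, net)
    Kx, Ks, Zx, Zs = kin.Kx, kin.Ks, kin.Zx, kin.Zs
    noisy = kin.gamma > 0 and kin.sigma_q > 0
    noise_sd = kin.sigma_q * math.sqrt(dt)

    c = np.concatenate([initial.x, initial.s]).astype(float)
    out = np.empty((n_steps + 1, 2 * n))
    out[0] = c
    for k in range(n_steps):
        x = c[:n]
        s = c[n:]
        p = _binding_probabilities_fast(s, reg, AT, RT, exponents)
        f = np.concatenate([Kx * p - Zx * x, Ks * x - Zs * s])
        c = c + f * dt
        if noisy:
            c = c + kin.gamma * out[k] * rng.normal(0.0, noise_sd, size=2 * n)
        np.maximum(c, 0.0, out=c)
        out[k + 1] = c
    times = np.linspace(0.0, kin.Tmax, n_steps + 1)
    return Trajectory(times=times, x=out[:, :n], s=out[:, n:], mode="stochastic")


# ---------------------------------------------------------------------------
# delay integrator: embedded Runge-Kutta 2(3) with Hermite history
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class DdeSolution:
    """Solution of a (delay) differential equation with dense output."""

    t: np.ndarray
    y: np.ndarray  # (T, dim)
    f: np.ndarray = field(repr=False, default=None)  # derivatives at nodes
    n_steps: int = 0
    n_rejected: int = 0

    def sol(self, t_query: float) -> np.ndarray:
        """Cubic-Hermite interpolation between stored nodes."""
        ts = self.t
        if t_query <= ts[0]:
            return self.y[0]
        if t_query >= ts[-1]:
            return self.y[-1]
        k = bisect_right(ts.tolist(), t_query) - 1
        t0, t1 = ts[k], ts[k + 1]
        h = t1 - t0
        th = (t_query - t0) / h
        h00 = (1 + 2 * th) * (1 - th) ** 2
        h10 = th * (1 - th) ** 2
        h01 = th * th * (3 - 2 * th)
        h11 = th * th * (th - 1)
        return (
            h00 * self.y[k]
            + h10 * h * self.f[k]
            + h01 * self.y[k + 1]
            + h11 * h * self.f[k + 1]
        )


def solve_dde(
    fun,
    t_span: tuple[float, float],
    y0: np.ndarray,
    tau: float = 0.0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    history=None,
    max_steps: int = 200000,
    max_step: float = math.inf,
) -> DdeSolution:
    """Integrate ``y' = fun(t, y, y(t - tau))`` with a Bogacki-Shampine 2(3) pair.

    The history for ``t <= t0`` is the constant ``y0`` unless a callable
    ``history(t)`` is given.  Delayed values inside the integration window
    are evaluated from the cubic-Hermite continuous extension; when
    ``tau > 0`` the step size is capped at ``tau`` so delayed lookups never
    overrun the computed solution, and steps are aligned with the
    derivative-discontinuity points ``t0 + k*tau``.

    The initial step is derived from the slope at the initial time and the
    step-size upper bound is adjusted adaptively during the integration.
    """
    t0, tmax = float(t_span[0]), float(t_span[1])
    if tmax <= t0:
        raise ValueError("t_span must be increasing")
    y0 = np.asarray(y0, dtype=float)
    dim = y0.size
    if history is None:
        history = lambda t: y0  # noqa: E731 - constant pre-history

    ts: list[float] = [t0]
    ys: list[np.ndarray] = [y0]
    fs: list[np.ndarray] = []

    def delayed(t: float) -> np.ndarray:
        td = t - tau
        if td <= t0:
            return np.asarray(history(td), dtype=float)
        k = bisect_right(ts, td) - 1
        if k >= len(ts) - 1:
            return ys[-1]
        ta, tb = ts[k], ts[k + 1]
        h = tb - ta
        th = (td - ta) / h
        h00 = (1 + 2 * th) * (1 - th) ** 2
        h10 = th * (1 - th) ** 2
        h01 = th * th * (3 - 2 * th)
        h11 = th * th * (th - 1)
        return h00 * ys[k] + h10 * h * fs[k] + h01 * ys[k + 1] + h11 * h * fs[k + 1]

    def eval_fun(t: float, y: np.ndarray) -> np.ndarray:
        ydel = y if tau == 0.0 else delayed(t)
        return np.asarray(fun(t, y, ydel), dtype=float)

    # breakpoints where the delayed argument crosses the initial time
    breaks: list[float] = []
    if tau > 0:
        k = 1
        while t0 + k * tau < tmax and k <= 1000:
            breaks.append(t0 + k * tau)
            k += 1

    f0 = eval_fun(t0, y0)
    fs.append(f0)

    # initial step from the initial slope
    scale = atol + rtol * np.abs(y0)
    d0 = math.sqrt(float(np.mean((y0 / scale) ** 2)))
    d1 = math.sqrt(float(np.mean((f0 / scale) ** 2)))
    h = 0.01 * d0 / d1 if (d0 > 1e-5 and d1 > 1e-5) else 1e-6
    h_cap = min(max_step, tau if tau > 0 else math.inf, tmax - t0)
    h = min(h, h_cap)

    t, y, f = t0, y0, f0
    n_acc = n_rej = 0
    break_idx = 0
    while t < tmax:
        if n_acc + n_rej > max_steps:
            raise SimulationError(
                f"delay integrator exceeded {max_steps} steps at t={t:.6g} "
                f"(rtol={rtol}, atol={atol})"
            )
        h = min(h, tmax - t)
        while break_idx < len(breaks) and breaks[break_idx] <= t + 1e-12:
            break_idx += 1
        if break_idx < len(breaks) and t + h > breaks[break_idx] - 1e-12:
            h = breaks[break_idx] - t
        # Bogacki-Shampine stages
        k1 = f
        k2 = eval_fun(t + 0.5 * h, y + 0.5 * h * k1)
        k3 = eval_fun(t + 0.75 * h, y + 0.75 * h * k2)
        y_new = y + h * (2.0 / 9.0 * k1 + 1.0 / 3.0 * k2 + 4.0 / 9.0 * k3)
        k4 = eval_fun(t + h, y_new)
        # embedded 2nd-order error estimate
        err_vec = h * (
            (2.0 / 9.0 - 7.0 / 24.0) * k1
            + (1.0 / 3.0 - 0.25) * k2
            + (4.0 / 9.0 - 1.0 / 3.0) * k3
            - 0.125 * k4
        )
        scale = atol + rtol * np.maximum(np.abs(y), np.abs(y_new))
        err = math.sqrt(float(np.mean((err_vec / scale) ** 2)))
        if err <= 1.0 or h <= 1e-14 * max(1.0, abs(t)):
            t = t + h
            y = y_new
            f = k4  # FSAL: k4 is exactly f(t+h, y_new)
            ts.append(t)
            ys.append(y)
            fs.append(f)
            n_acc += 1
            factor = 0.9 * err ** (-1.0 / 3.0) if err > 0 else 5.0
            h = min(h * min(5.0, max(0.2, factor)), h_cap)
        else:
            n_rej += 1
            h = h * min(1.0, max(0.2, 0.9 * err ** (-1.0 / 3.0)))
    return DdeSolution(
        t=np.asarray(ts),
        y=np.asarray(ys),
        f=np.asarray(fs),
        n_steps=n_acc,
        n_rejected=n_rej,
    )


def integrate_dde(
    initial: SystemState,
    kin: KineticParameters,
    reg: RegulatoryParameters,
    net: RegulatoryNetwork,
    rel_tol: float = 1e-5,
    abs_tol: float = 1e-8,
) -> Trajectory:
    """Integrate the gene system in delay (tau > 0) or deterministic mode."""
    if kin.gamma > 0:
        raise ModeError("delay/deterministic mode requires gamma=0")
    n = kin.n_genes
    AT = net.A.T.astype(float)
    RT = net.R.T.astype(float)
    exponents = _exponents(reg, net)
    Kx, Ks, Zx, Zs = kin.Kx, kin.Ks, kin.Zx, kin.Zs

    def fun(t, y, ydel):
        x = y[:n]
        s = y[n:]
        p = _binding_probabilities_fast(ydel[n:], reg, AT, RT, exponents)
        return np.concatenate([Kx * p - Zx * x, Ks * ydel[:n] - Zs * s])

    y0 = np.concatenate([initial.x, initial.s])
    sol = solve_dde(fun, (0.0, kin.Tmax), y0, tau=kin.tau, rtol=rel_tol, atol=abs_tol)
    y = np.maximum(sol.y, 0.0)
    mode = "delay" if kin.tau > 0 else "deterministic"
    return Trajectory(times=sol.t, x=y[:, :n], s=y[:, n:], mode=mode)


def simulate_genotype(
    Kx_j: np.ndarray,
    kin: KineticParameters,
    reg: RegulatoryParameters,
    net: RegulatoryNetwork,
    mode: str = "deterministic",
    seed=None,
    genotype_id: str | None = None,
    burn_in_fraction: float = 0.2,
    rel_tol: float = 1e-5,
    abs_tol: float = 1e-8,
    keep_trajectory: bool = True,
):
    """Integrate one genotype from the all-ones state and time-average.

    Returns a :class:`~grnsim.traits.GeneProducts` holding per-gene mean
    mRNA and protein over the final ``1 - burn_in_fraction`` of the span.
    """
    from .traits import GeneProducts, time_average

    if mode not in MODES:
        raise ModeError(f"unknown mode {mode!r}; expected one of {MODES}")
    n = kin.n_genes
    kin_j = replace(kin, Kx=_as_vector(Kx_j, n, "Kx"))
    if mode == "deterministic":
        kin_j = replace(kin_j, tau=0.0, gamma=0.0)
    initial = SystemState(x=np.ones(n), s=np.ones(n))
    try:
        if mode == "stochastic":
            if kin_j.tau != 0:
                raise ModeError("stochastic mode requires tau=0")
            traj = integrate_em(initial, kin_j, reg, net, seed=seed)
        else:
            traj = integrate_dde(initial, kin_j, reg, net, rel_tol=rel_tol, abs_tol=abs_tol)
    except (SimulationError, ModeError, ValueError) as exc:
        label = genotype_id if genotype_id is not None else "<unnamed>"
        raise SimulationError(f"genotype {label}: {exc}") from exc
    mean_x, mean_s = time_average(traj, burn_in_fraction)
    return GeneProducts(
        genotype_id=genotype_id,
        mean_mrna=mean_x,
        mean_protein=mean_s,
        trajectory=traj if keep_trajectory else None,
    )
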
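"""Omnigenic trait construction and population-level response studies.

A trait value is the weighted sum of a genotype's time-averaged core-gene
protein products, each normalised by the reference genotype's product.
Population studies rerun the full dynamics pipeline over grids of the
gene-by-gene response parameter (kappa) or of the environment response
parameter (phi) and summarise the genomic/environmental variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dynamics as _dyn
from .genotypes import (
    GenotypePopulation,
    CoreGenes,
    marker_effect_matrix,
    reference_genotype,
    sample_expression_rates,
)
from .network import RegulatoryNetwork

__all__ = [
    "GeneProducts",
    "TraitResult",
    "EnvironmentModel",
    "GxeResult",
    "time_average",
    "normalize_products",
    "compute_trait",
    "standardized_expression",
    "regulatory_correlations",
    "population_gene_products",
    "population_traits",
    "gxg_variance_curve",
    "gxe_simulate",
    "variance_components",
]

_P_STREAM = 1
_GENOTYPE_STREAM = 2
_ENV_STREAM = 3


@dataclass(eq=False)
class GeneProducts:
    """Burn-in-corrected time averages of one genotype's gene products."""

    genotype_id: str | None
    mean_mrna: np.ndarray
    mean_protein: np.ndarray
    trajectory: _dyn.Trajectory | None = None

    def __post_init__(self) -> None:
        self.mean_mrna = np.asarray(self.mean_mrna, dtype=float)
        self.mean_protein = np.asarray(self.mean_protein, dtype=float)
        if self.mean_mrna.shape != self.mean_protein.shape:
            raise ValueError("mean product vectors must have equal shape")
        if np.any(self.mean_mrna < 0) or np.any(self.mean_protein < 0):
            raise ValueError("mean products must be nonnegative")


@dataclass(eq=False)
class TraitResult:
    genotypic_values: np.ndarray
    weights: np.ndarray
    normalized_products: np.ndarray
    kappa: float
    phi: float | None = None


@dataclass(eq=False)
class EnvironmentModel:
    """Virtual environment acting through the transcription-rate expectation."""

    phi: float
    mu_x: np.ndarray
    n_replicates: int = 10
    sigma_env2: float = 0.0
    omega: float = 1.0  # phi = omega * sigma_env2; accepted but phi drives the model

    def __post_init__(self) -> None:
        self.mu_x = np.asarray(self.mu_x, dtype=float)
        if self.phi < 0:
            raise ValueError(f"phi must be nonnegative, got {self.phi}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if np.any(self.mu_x <= 0):
            raise ValueError("mu_x must be strictly positive")
        if not self.omega > 0:
            raise ValueError("omega must be positive")


@dataclass(eq=False)
class GxeResult:
    genotypic_values: np.ndarray
    phenotypes: np.ndarray  # (m, n_replicates)
    phi: float


def time_average(trajectory: _dyn.Trajectory, burn_in_fraction: float = 0.2):
    """Trapezoidal per-gene time averages over the post-burn-in window.

    The window is ``[t0 + burn_in * (tmax - t0), tmax]``; its left endpoint
    is obtained by linear interpolation when it falls between saved times.
    """
    if not (0.0 <= burn_in_fraction < 1.0):
        raise ValueError(f"burn_in_fraction must be in [0, 1), got {burn_in_fraction}")
    t = trajectory.times
    if t.size < 2:
        raise ValueError("trajectory must contain at least two time points")
    t_start = t[0] + burn_in_fraction * (t[-1] - t[0])
    mask = t >= t_start
    if mask.sum() < 2 and not np.isclose(t_start, t[-1]):
        raise ValueError("averaging window contains too few points")

    def _avg(series: np.ndarray) -> np.ndarray:
        sub_t = t[mask]
        sub = series[mask]
        if sub_t[0] > t_start:
            boundary = np.array(
                [np.interp(t_start, t, series[:, g]) for g in range(series.shape[1])]
            )
            sub_t = np.concatenate([[t_start], sub_t])
            sub = np.vstack([boundary, sub])
        span = sub_t[-1] - sub_t[0]
        if span <= 0:
            return sub[-1].astype(float)
        return np.trapezoid(sub, sub_t, axis=0) / span

    return _avg(trajectory.x), _avg(trajectory.s)


def normalize_products(pop_products: np.ndarray, ref_products: np.ndarray) -> np.ndarray:
    """Entrywise division of population products by the reference products."""
    pop_products = np.asarray(pop_products, dtype=float)
    ref_products = np.asarray(ref_products, dtype=float).ravel()
    if pop_products.ndim != 2 or pop_products.shape[1] != ref_products.size:
        raise ValueError("product matrix and reference vector shapes disagree")
    bad = np.flatnonzero(ref_products <= 0)
    if bad.size:
        raise ValueError(
            f"reference product nonpositive for core gene(s) {bad.tolist()}; "
            "cannot normalise"
        )
    return pop_products / ref_products


def compute_trait(S_bar: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Trait values ``y_j = sum_i W_ji * S_bar_ji`` (weighted product sum)."""
    S_bar = np.asarray(S_bar, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        if W.size != S_bar.shape[1]:
            raise ValueError("weight vector length must equal the number of core genes")
        W = np.broadcast_to(W, S_bar.shape)
    if W.shape != S_bar.shape:
        raise ValueError(f"weight matrix shape {W.shape} != product shape {S_bar.shape}")
    return (W * S_bar).sum(axis=1)


def standardized_expression(series: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-sd version of a time series (s.e.l.)."""
    series = np.asarray(series, dtype=float)
    sd = series.std()
    if sd == 0:
        raise ValueError("cannot standardise a constant series (zero variance)")
    return (series - series.mean()) / sd


def regulatory_correlations(
    trajectory: _dyn.Trajectory,
    network: RegulatoryNetwork,
    burn_in_fraction: float = 0.2,
    signal: str = "mrna",
) -> pd.DataFrame:
    """Pearson correlations of standardised expression along regulatory edges.

    Returns one row per directed edge with columns ``regulator``, ``target``,
    ``edge_type`` and ``correlation``.  Constant series are skipped with a
    warning; self-edges cannot occur (zero adjacency diagonal).
    """
    t = trajectory.times
    t_start = t[0] + burn_in_fraction * (t[-1] - t[0])
    mask = t >= t_start
    data = (trajectory.x if signal == "mrna" else trajectory.s)[mask]
    rows = []
    for label, adj in (("activation", network.A), ("repression", network.R)):
        for reg_idx, tgt in zip(*np.nonzero(adj)):
            a = data[:, reg_idx]
            b = data[:, tgt]
            if a.std() == 0 or b.std() == 0:
                warnings.warn(
                    f"constant expression series on edge {reg_idx}->{tgt}; skipped",
                    stacklevel=2,
                )
                continue
            try:
                corr = float(np.corrcoef(standardized_expression(a), standardized_expression(b))[0, 1])
            except ValueError:
                continue
            rows.append((int(reg_idx), int(tgt), label, corr))
    return pd.DataFrame(rows, columns=["regulator", "target", "edge_type", "correlation"])


# ---------------------------------------------------------------------------
# population-level studies
# ---------------------------------------------------------------------------

def _simulate_job(args):
    """Top-level worker so population runs can cross process boundaries."""
    (Kx_j, kin, reg, net, mode, seed, gid, burn_in, rel_tol, abs_tol) = args
    return _dyn.simulate_genotype(
        Kx_j,
        kin,
        reg,
        net,
        mode=mode,
        seed=seed,
        genotype_id=gid,
        burn_in_fraction=burn_in,
        rel_tol=rel_tol,
        abs_tol=abs_tol,
        keep_trajectory=False,
    )


def _genotype_seed(master_seed, j: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed), _GENOTYPE_STREAM, int(j)])


def population_gene_products(
    rates: np.ndarray,
    M: np.ndarray,
    net: RegulatoryNetwork,
    reg: _dyn.RegulatoryParameters,
    kin: _dyn.KineticParameters,
    mode: str = "deterministic",
    seed: int = 0,
    individual_ids=None,
    burn_in_fraction: float = 0.2,
    rel_tol: float = 1e-4,
    abs_tol: float = 1e-7,
    map_fn=None,
) -> list[GeneProducts]:
    """Simulate every genotype's dynamics; per-genotype seeds derive from
    ``(seed, genotype index)`` so results are independent of scheduling."""
    if map_fn is None:
        map_fn = map
    m = M.shape[0]
    ids = individual_ids if individual_ids is not None else [f"ind{j + 1}" for j in range(m)]
    jobs = [
        (
            rates * M[j],
            kin,
            reg,
            net,
            mode,
            _genotype_seed(seed, j),
            ids[j],
            burn_in_fraction,
            rel_tol,
            abs_tol,
        )
        for j in range(m)
    ]
    return list(map_fn(_simulate_job, jobs))


def population_traits(
    pop: GenotypePopulation,
    net: RegulatoryNetwork,
    core: CoreGenes,
    reg: _dyn.RegulatoryParameters,
    kin: _dyn.KineticParameters,
    kappa: float,
    P: np.ndarray,
    mode: str = "deterministic",
    seed: int = 0,
    burn_in_fraction: float = 0.2,
    rel_tol: float = 1e-4,
    abs_tol: float = 1e-7,
    map_fn=None,
    base_rates: np.ndarray | None = None,
    ref_core_products: np.ndarray | None = None,
    return_products: bool = False,
):
    """Full trait pipeline for one population at a fixed kappa.

    ``base_rates`` overrides the sampled rates ``P`` (used by the G-by-E
    study).  The normalisation baseline is the reference genotype simulated
    with the same base rates and an all-ones marker-effect row, unless
    precomputed ``ref_core_products`` are supplied (the G-by-E study
    normalises all environments by the unperturbed reference).
    """
    rates = P if base_rates is None else base_rates
    ref = reference_genotype(pop)
    M = marker_effect_matrix(pop, ref, kappa)
    ref_products = None
    if ref_core_products is None:
        ref_products = _simulate_job(
            (
                rates,
                kin,
                reg,
                net,
                mode,
                np.random.SeedSequence([int(seed), _GENOTYPE_STREAM, -1 & 0xFFFFFFFF]),
                "reference",
                burn_in_fraction,
                rel_tol,
                abs_tol,
            )
        )
        ref_core_products = ref_products.mean_protein[core.indices]
    products = population_gene_products(
        rates,
        M,
        net,
        reg,
        kin,
        mode=mode,
        seed=seed,
        individual_ids=pop.individual_ids,
        burn_in_fraction=burn_in_fraction,
        rel_tol=rel_tol,
        abs_tol=abs_tol,
        map_fn=map_fn,
    )
    S = np.vstack([gp.mean_protein[core.indices] for gp in products])
    S_bar = normalize_products(S, ref_core_products)
    y = compute_trait(S_bar, core.weights)
    result = TraitResult(
        genotypic_values=y,
        weights=np.broadcast_to(core.weights, S_bar.shape).copy(),
        normalized_products=S_bar,
        kappa=kappa,
    )
    if return_products:
        return result, products, ref_products
    return result


def gxg_variance_curve(
    pop: GenotypePopulation,
    net: RegulatoryNetwork,
    core: CoreGenes,
    reg: _dyn.RegulatoryParameters,
    kin: _dyn.KineticParameters,
    kappa_grid,
    P_mu: float,
    seed: int = 0,
    burn_in_fraction: float = 0.2,
    rel_tol: float = 1e-4,
    abs_tol: float = 1e-7,
    map_fn=None,
) -> pd.DataFrame:
    """Genomic variance and trait mean across a kappa grid (deterministic).

    The expression-rate sample shares one seed stream across kappa values
    and the network/population are fixed, so only kappa varies.
    """
    if kin.gamma > 0:
        raise ValueError("G-by-G study requires deterministic dynamics (gamma=0)")
    records = []
    for kappa in kappa_grid:
        P = sample_expression_rates(
            P_mu, kappa, pop.n, np.random.SeedSequence([int(seed), _P_STREAM])
        )
        result = population_traits(
            pop,
            net,
            core,
            reg,
            kin,
            kappa,
            P,
            mode="deterministic",
            seed=seed,
            burn_in_fraction=burn_in_fraction,
            rel_tol=rel_tol,
            abs_tol=abs_tol,
            map_fn=map_fn,
        )
        y = result.genotypic_values
        var = float(np.var(y, ddof=1)) if y.size > 1 else 0.0
        records.append((float(kappa), var, float(y.mean())))
    return pd.DataFrame(records, columns=["kappa", "genomic_variance", "trait_mean"])


def _sample_environment_rates(
    mu_x: np.ndarray, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """Rates from ``Normal(mu_x, phi * mu_x^2)``, resampled to stay positive."""
    if phi == 0:
        return mu_x.copy()
    sd = np.sqrt(phi) * mu_x
    floor = 1e-6 * mu_x
    rates = rng.normal(mu_x, sd)
    while True:
        bad = rates < floor
        if not bad.any():
            return rates
        rates[bad] = rng.normal(mu_x[bad], sd[bad])


def gxe_simulate(
    pop: GenotypePopulation,
    net: RegulatoryNetwork,
    core: CoreGenes,
    reg: _dyn.RegulatoryParameters,
    kin: _dyn.KineticParameters,
    env: EnvironmentModel,
    kappa: float,
    seed: int = 0,
    burn_in_fraction: float = 0.2,
    rel_tol: float = 1e-4,
    abs_tol: float = 1e-7,
    map_fn=None,
) -> GxeResult:
    """Phenotype replicates under a virtual environment of harshness phi.

    Each replicate resamples the per-gene transcription-rate expectations
    from ``Normal(mu_x, phi * mu_x^2)``; genotype effects then act
    multiplicatively through the marker-effect matrix.  All replicates are
    normalised by the unperturbed reference genotype, so the environment
    main effect remains visible in the phenotypes.  With phi = 0 the
    replicates equal the genotypic values exactly.
    """
    geno_result, _, ref_products = population_traits(
        pop, net, core, reg, kin, kappa, env.mu_x,
        mode="deterministic", seed=seed, burn_in_fraction=burn_in_fraction,
        rel_tol=rel_tol, abs_tol=abs_tol, map_fn=map_fn, return_products=True,
    )
    genotypic = geno_result.genotypic_values
    ref_core = ref_products.mean_protein[core.indices]
    phenotypes = np.empty((pop.m, env.n_replicates))
    for r in range(env.n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), _ENV_STREAM, r]))
        rates = _sample_environment_rates(env.mu_x, env.phi, rng)
        phenotypes[:, r] = population_traits(
            pop, net, core, reg, kin, kappa, rates,
            mode="deterministic", seed=seed, burn_in_fraction=burn_in_fraction,
            rel_tol=rel_tol, abs_tol=abs_tol, map_fn=map_fn,
            ref_core_products=ref_core,
        ).genotypic_values
    return GxeResult(genotypic_values=genotypic, phenotypes=phenotypes, phi=env.phi)


def variance_components(phenotypes: np.ndarray, genotypic_values: np.ndarray):
    """Genomic and environmental variance components of a replicate study.

    ``sigma_g^2`` is the variance of the genotypic values; ``sigma_e^2`` is
    the variance of the deviation from the genotypic value across
    individuals, averaged over replicates.
    """
    phenotypes = np.asarray(phenotypes, dtype=float)
    genotypic_values = np.asarray(genotypic_values, dtype=float).ravel()
    if phenotypes.ndim == 1:
        phenotypes = phenotypes[:, None]
    if phenotypes.shape[0] != genotypic_values.size:
        raise ValueError("phenotype rows must match the number of individuals")
    sigma_g2 = float(np.var(genotypic_values, ddof=1)) if genotypic_values.size > 1 else 0.0
    deviations = phenotypes - genotypic_values[:, None]
    sigma_e2 = float(np.mean(np.var(deviations, axis=0, ddof=1)))
    return sigma_g2, sigma_e2
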
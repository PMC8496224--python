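"""End-to-end orchestration: network -> genotypes -> dynamics -> trait.

All outputs are deterministic functions of (config, master seed); the
per-genotype random streams are derived from the master seed and the
genotype index, so worker count and scheduling never change the results.
"""

from __future__ import annotations

import hashlib
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .config import SimulationConfig
from .dynamics import default_kinetic_params, default_regulatory_params
from .genotypes import (
    CoreGenes,
    read_core_genes,
    read_genotypes,
    sample_expression_rates,
    simulate_genotypes,
    write_genotypes,
)
from .network import (
    BasalGeometrySpec,
    RegulatoryNetwork,
    connectivity_report,
    generate_network,
    read_adjacency,
    write_adjacency,
)
from .traits import (
    EnvironmentModel,
    _simulate_job,
    gxe_simulate,
    gxg_variance_curve,
    population_traits,
    variance_components,
)

__all__ = [
    "RunManifest",
    "parallel_map_genotypes",
    "build_network",
    "load_population",
    "run_pipeline",
    "run_gxg_study",
    "run_gxe_study",
]

_NETWORK_STREAM = 4
_POPULATION_STREAM = 5
_P_STREAM = 1


@dataclass
class RunManifest:
    """Reproducibility record written once per pipeline run."""

    version: str
    master_seed: int
    config: dict
    stage_seconds: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)  # path -> sha256

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"version: {self.version}\n")
            fh.write(f"master_seed: {self.master_seed}\n")
            fh.write("[config]\n")
            for key, value in self.config.items():
                fh.write(f"  {key} = {value}\n")
            fh.write("[stages]\n")
            for key, value in self.stage_seconds.items():
                fh.write(f"  {key} = {value:.3f} s\n")
            fh.write("[files]\n")
            for key, value in self.files.items():
                fh.write(f"  {key} sha256={value}\n")


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def parallel_map_genotypes(jobs, workers: int = 1):
    """Run simulation jobs in input order; results are worker-count invariant.

    ``jobs`` are argument tuples for the per-genotype simulation worker.
    A failure in any worker propagates annotated with the genotype id.
    """
    jobs = list(jobs)
    if workers <= 1 or len(jobs) < 2:
        return [_simulate_job(job) for job in jobs]
    chunk = max(1, len(jobs) // (4 * workers))
    with ProcessPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(_simulate_job, jobs, chunksize=chunk))


def _make_map_fn(workers: int):
    if workers <= 1:
        return map

    def map_fn(fn, iterable):
        items = list(iterable)
        if len(items) < 2:
            return [fn(i) for i in items]
        chunk = max(1, len(items) // (4 * workers))
        with ProcessPoolExecutor(max_workers=workers) as pool:
            return list(pool.map(fn, items, chunksize=chunk))

    return map_fn


def build_network(cfg: SimulationConfig) -> RegulatoryNetwork:
    """Generate the geometry from config, or load .grm files when given."""
    if cfg.network_prefix:
        prefix = Path(cfg.network_prefix)
        A = read_adjacency(f"{prefix}.A.grm")
        R = read_adjacency(f"{prefix}.R.grm")
        net = RegulatoryNetwork(A=A, R=R)
        if net.n_genes != cfg.n_genes:
            raise ValueError(
                f"adjacency files describe {net.n_genes} genes, config says {cfg.n_genes}"
            )
        return net
    shapes = (cfg.basal_shape_d1, cfg.basal_shape_d2, cfg.basal_shape_d3)
    specs = [
        BasalGeometrySpec(dimension=d, gene_fraction=frac, shape_params=tuple(shape))
        for d, (frac, shape) in enumerate(zip(cfg.basal_fractions, shapes), start=1)
    ]
    return generate_network(
        cfg.n_genes,
        specs,
        edge_rate=cfg.edge_rate,
        iterations=cfg.merge_iterations,
        activation_fraction=cfg.activation_fraction,
        seed=np.random.SeedSequence([cfg.seed, _NETWORK_STREAM]),
        n_core=cfg.n_core,
    )


def load_population(cfg: SimulationConfig):
    if cfg.genotype_file:
        pop = read_genotypes(cfg.genotype_file)
        if pop.n != cfg.n_genes:
            raise ValueError(
                f"genotype file has {pop.n} loci, config says n_genes={cfg.n_genes}"
            )
    else:
        pop = simulate_genotypes(
            cfg.n_individuals,
            cfg.n_genes,
            seed=np.random.SeedSequence([cfg.seed, _POPULATION_STREAM]),
            allele_probs=cfg.allele_probs,
        )
    return pop


def _core_genes(cfg: SimulationConfig, net: RegulatoryNetwork) -> CoreGenes:
    if cfg.core_file:
        return read_core_genes(cfg.core_file, cfg.n_genes)
    if net.core_indices.size:
        return CoreGenes(indices=net.core_indices, weights=net.core_weights)
    if cfg.n_core > 0:
        # externally supplied network without a core file: pick at random
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 6]))
        idx = np.sort(rng.choice(cfg.n_genes, size=cfg.n_core, replace=False))
        return CoreGenes(indices=idx, weights=np.full(cfg.n_core, 1.0 / cfg.n_core))
    raise ValueError("no core genes: set n_core > 0 or provide core_file")


def _model_params(cfg: SimulationConfig):
    n = cfg.n_genes
    reg = default_regulatory_params(
        n,
        Gp=cfg.gp,
        H=cfg.h,
        GA=cfg.ga,
        GR=cfg.gr,
        Phi=cfg.phi_a,
        hA=cfg.h_a,
        hR=cfg.h_r,
        exponent_base=cfg.exponent_base if cfg.exponent_base >= 1 else n,
        binding_form=cfg.binding_form,
        per_gene_exponent=cfg.per_gene_exponent,
    )
    kin = default_kinetic_params(
        n,
        Kx=cfg.p_mu,  # placeholder; per-genotype rates replace Kx
        Ks=cfg.ks,
        Zx=cfg.zx,
        Zs=cfg.zs,
        tau=cfg.tau if cfg.mode == "delay" else 0.0,
        gamma=cfg.gamma if cfg.mode == "stochastic" else 0.0,
        sigma_q=cfg.sigma_q if cfg.mode == "stochastic" else 0.0,
        Tmax=cfg.tmax,
    )
    return reg, kin


def _write_products(path, products) -> None:
    n = products[0].mean_mrna.size
    header = (
        "id "
        + " ".join(f"xbar_{i + 1}" for i in range(n))
        + " "
        + " ".join(f"sbar_{i + 1}" for i in range(n))
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for gp in products:
            row = np.concatenate([gp.mean_mrna, gp.mean_protein])
            fh.write(gp.genotype_id + " " + " ".join(f"{v:.10g}" for v in row) + "\n")


def _write_traits(path, ids, genotypic, phenotypes=None) -> None:
    with open(path, "w") as fh:
        if phenotypes is None:
            fh.write("id genotypic_value\n")
            for gid, y in zip(ids, genotypic):
                fh.write(f"{gid} {y:.10g}\n")
        else:
            reps = phenotypes.shape[1]
            fh.write("id genotypic_value " + " ".join(f"rep{r + 1}" for r in range(reps)) + "\n")
            for j, (gid, y) in enumerate(zip(ids, genotypic)):
                row = " ".join(f"{v:.10g}" for v in phenotypes[j])
                fh.write(f"{gid} {y:.10g} {row}\n")


def run_pipeline(cfg: SimulationConfig, outdir=None) -> RunManifest:
    """Execute the full simulation workflow and write all output files."""
    cfg.validate()
    out = Path(outdir if outdir is not None else cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, master_seed=cfg.seed, config=asdict(cfg))
    map_fn = _make_map_fn(cfg.workers)

    t0 = time.perf_counter()
    net = build_network(cfg)
    core = _core_genes(cfg, net)
    manifest.stage_seconds["network"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pop = load_population(cfg)
    manifest.stage_seconds["population"] = time.perf_counter() - t0

    kappa_expr = None if cfg.kappa_expression == -1.0 else cfg.kappa_expression
    P = sample_expression_rates(
        cfg.p_mu,
        cfg.kappa if kappa_expr is None else kappa_expr,
        cfg.n_genes,
        np.random.SeedSequence([cfg.seed, _P_STREAM]),
    )
    reg, kin = _model_params(cfg)

    t0 = time.perf_counter()
    result, products, ref_products = population_traits(
        pop,
        net,
        core,
        reg,
        kin,
        cfg.kappa,
        P,
        mode=cfg.mode,
        seed=cfg.seed,
        burn_in_fraction=cfg.burn_in,
        rel_tol=cfg.rel_tol,
        abs_tol=cfg.abs_tol,
        map_fn=map_fn,
        return_products=True,
    )
    manifest.stage_seconds["dynamics"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    files = {}
    for name, matrix in (("N", net.N), ("A", net.A), ("R", net.R)):
        path = out / f"network.{name}.grm"
        write_adjacency(matrix, path)
        files[path.name] = path
    gpath = out / "genotypes.dat"
    write_genotypes(pop, gpath)
    files[gpath.name] = gpath
    cpath = out / "core_genes.dat"
    with open(cpath, "w") as fh:
        for idx, w in zip(core.indices, core.weights):
            fh.write(f"{idx + 1} {w:.10g}\n")
    files[cpath.name] = cpath
    ppath = out / "products.txt"
    _write_products(ppath, products)
    files[ppath.name] = ppath
    tpath = out / "traits.txt"
    _write_traits(tpath, pop.individual_ids, result.genotypic_values)
    files[tpath.name] = tpath
    manifest.stage_seconds["output"] = time.perf_counter() - t0

    for name, path in files.items():
        manifest.files[name] = _sha256(path)
    manifest.write(out / "manifest.txt")
    return manifest


def run_gxg_study(cfg: SimulationConfig, outdir=None):
    """Genomic-variance-vs-kappa study; writes gxg_curve.txt."""
    cfg.validate()
    out = Path(outdir if outdir is not None else cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    net = build_network(cfg)
    core = _core_genes(cfg, net)
    pop = load_population(cfg)
    reg, kin = _model_params(cfg)
    curve = gxg_variance_curve(
        pop,
        net,
        core,
        reg,
        kin,
        cfg.kappa_grid,
        cfg.p_mu,
        seed=cfg.seed,
        burn_in_fraction=cfg.burn_in,
        rel_tol=cfg.rel_tol,
        abs_tol=cfg.abs_tol,
        map_fn=_make_map_fn(cfg.workers),
    )
    curve.to_csv(out / "gxg_curve.txt", sep=" ", index=False, float_format="%.10g")
    return curve


def run_gxe_study(cfg: SimulationConfig, outdir=None):
    """Phenotype replicates and variance components across the phi grid."""
    cfg.validate()
    out = Path(outdir if outdir is not None else cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    net = build_network(cfg)
    core = _core_genes(cfg, net)
    pop = load_population(cfg)
    reg, kin = _model_params(cfg)
    kappa_expr = None if cfg.kappa_expression == -1.0 else cfg.kappa_expression
    P = sample_expression_rates(
        cfg.p_mu,
        cfg.kappa if kappa_expr is None else kappa_expr,
        cfg.n_genes,
        np.random.SeedSequence([cfg.seed, _P_STREAM]),
    )
    map_fn = _make_map_fn(cfg.workers)
    records = []
    for phi in cfg.phi_grid:
        env = EnvironmentModel(
            phi=float(phi),
            mu_x=P,
            n_replicates=cfg.n_replicates,
            sigma_env2=cfg.sigma_env2,
            omega=cfg.omega,
        )
        res = gxe_simulate(
            pop, net, core, reg, kin, env, cfg.kappa,
            seed=cfg.seed, burn_in_fraction=cfg.burn_in,
            rel_tol=cfg.rel_tol, abs_tol=cfg.abs_tol, map_fn=map_fn,
        )
        _write_traits(
            out / f"gxe_phi{phi:g}.txt", pop.individual_ids,
            res.genotypic_values, res.phenotypes,
        )
        sigma_g2, sigma_e2 = variance_components(res.phenotypes, res.genotypic_values)
        records.append((float(phi), sigma_g2, sigma_e2))
    with open(out / "gxe_variance.txt", "w") as fh:
        fh.write("phi sigma_g2 sigma_e2\n")
        for phi, sg, se in records:
            fh.write(f"{phi:.10g} {sg:.10g} {se:.10g}\n")
    return records


def network_report(cfg: SimulationConfig):
    net = build_network(cfg)
    return connectivity_report(net)
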
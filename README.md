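# grnsim

Mechanistic simulation of quantitative traits on gene regulatory networks.

`grnsim` grows scale-free regulatory-network geometries by gluing
d-dimensional simplexes, maps SNP allele counts (0/1/2) into per-genotype
transcription rates through a relative marker-effect matrix, integrates
coupled mRNA/protein dynamics under a statistical-thermodynamic model of
polymerase promoter binding (stochastic Euler–Maruyama or delay
Runge–Kutta 2(3) modes), and assembles omnigenic trait values as weighted,
reference-normalised core-gene products.  Population studies sweep the
gene-by-gene response parameter `kappa` (genomic variance curves) and the
gene-by-environment response parameter `phi` (phenotype replicates and
variance components).

## Layout

| module                | purpose |
|-----------------------|---------|
| `grnsim.network`      | simplicial-complex growth, basal-network merging, activator/repressor partition, `.grm` adjacency I/O, connectivity reports |
| `grnsim.powerlaw`     | discrete power-law tail MLE with KS-selected `xmin` |
| `grnsim.genotypes`    | genotype populations, reference genotype, marker-effect matrix, expression-rate sampling, genotype/core-gene file I/O |
| `grnsim.dynamics`     | binding-probability kernel, rate equations, Euler–Maruyama and delay RK(2,3) integrators |
| `grnsim.traits`       | time averaging, trait assembly, regulatory-edge correlations, G×G and G×E studies, variance components |
| `grnsim.config`       | `key = value` configuration files with exhaustive validation |
| `grnsim.pipeline`     | end-to-end orchestration, deterministic parallel execution, run manifests |
| `grnsim.cli`          | `grnsim` command-line entry point |

## CLI

```sh
grnsim generate-network --seed 4 --outdir out/net
grnsim simulate --config run.tsim --outdir out/run
grnsim gxg-study --config run.tsim
grnsim gxe-study --config run.tsim
grnsim report --config run.tsim --traits out/run/traits.txt
```

A configuration file is `key = value` lines (`#` comments, case-insensitive
keys); unknown keys and out-of-range values are rejected with the offending
line.  Example:

```ini
seed = 1
n_individuals = 5000
n_genes = 50
n_core = 12
kappa = 0.5
mode = deterministic
tmax = 200
```

Outputs per run: `network.{N,A,R}.grm` adjacency files, `genotypes.dat`,
`core_genes.dat`, `products.txt` (per-genotype time-averaged mRNA/protein),
`traits.txt`, and `manifest.txt` (config echo, seeds, stage timings, file
checksums).  Outputs are byte-identical for identical config and seed,
regardless of worker count.

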
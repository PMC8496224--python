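"""Genotype populations and the polymorphism-to-transcription map.

Allele counts (0/1/2 per locus) are turned into per-genotype transcription
rates in two steps: a relative marker-effect matrix
``M = 1 + (kappa/3) * (Mpop - Mref)`` measured against the population's
modal (reference) genotype, and a vector ``P`` of baseline expression
rates sampled once per simulation from ``Normal(P_mu, kappa * P_mu)``.
Gene ``i`` of genotype ``j`` then transcribes at rate ``P[i] * M[j, i]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeFormatError",
    "GenotypePopulation",
    "CoreGenes",
    "PolymorphismMap",
    "simulate_genotypes",
    "reference_genotype",
    "marker_effect_matrix",
    "sample_expression_rates",
    "genotype_transcription_rates",
    "read_genotypes",
    "write_genotypes",
    "read_core_genes",
    "build_polymorphism_map",
]

_CODES = (0, 1, 2)
RATE_FLOOR_FRACTION = 1e-6  # sampled rates are resampled while below this * P_mu


class GenotypeFormatError(ValueError):
    """Raised when a genotype or core-gene file cannot be parsed."""


@dataclass(eq=False)
class GenotypePopulation:
    """m individuals x n loci of allele counts in {0, 1, 2}."""

    matrix: np.ndarray
    individual_ids: list[str] = field(default_factory=list)
    locus_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.size == 0:
            raise ValueError("genotype matrix must be 2-D and nonempty")
        if not np.isin(self.matrix, _CODES).all():
            raise ValueError("allele counts must be in {0, 1, 2}")
        m, n = self.matrix.shape
        if not self.individual_ids:
            self.individual_ids = [f"ind{i + 1}" for i in range(m)]
        if not self.locus_ids:
            self.locus_ids = [f"snp{j + 1}" for j in range(n)]
        if len(self.individual_ids) != m or len(self.locus_ids) != n:
            raise ValueError("id lists must match matrix shape")
        if len(set(self.individual_ids)) != m or len(set(self.locus_ids)) != n:
            raise ValueError("ids must be unique")

    @property
    def m(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n(self) -> int:
        return int(self.matrix.shape[1])


@dataclass(eq=False)
class CoreGenes:
    """Ordered core-gene loci (0-based indices) with trait weights."""

    indices: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.indices.size != self.weights.size:
            raise ValueError("indices and weights must have equal length")
        if np.unique(self.indices).size != self.indices.size:
            raise ValueError("core gene indices must be unique")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise ValueError("core weights must be finite and nonnegative")

    @property
    def n_core(self) -> int:
        return int(self.indices.size)


@dataclass(eq=False)
class PolymorphismMap:
    """Everything needed to map genotypes into transcription rates."""

    Mref: np.ndarray
    kappa: float
    M: np.ndarray
    P_mu: float
    P: np.ndarray

    def __post_init__(self) -> None:
        self.Mref = np.asarray(self.Mref, dtype=np.int8).ravel()
        self.M = np.asarray(self.M, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError(f"kappa must be in [0, 1], got {self.kappa}")
        if not self.P_mu > 0:
            raise ValueError(f"P_mu must be positive, got {self.P_mu}")
        lo, hi = 1 - 2 * self.kappa / 3, 1 + 2 * self.kappa / 3
        if self.M.min() < lo - 1e-12 or self.M.max() > hi + 1e-12:
            raise ValueError("marker effects out of the [1-2k/3, 1+2k/3] range")
        if np.any(self.P <= 0):
            raise ValueError("expression rates must be positive")


def simulate_genotypes(
    m: int, n: int, seed=None, allele_probs=(1 / 3, 1 / 3, 1 / 3)
) -> GenotypePopulation:
    """Sample an m x n matrix of i.i.d. allele counts from ``allele_probs``."""
    if m < 1 or n < 1:
        raise ValueError(f"m and n must be >= 1, got {m}, {n}")
    probs = np.asarray(allele_probs, dtype=float)
    if probs.shape != (3,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"allele_probs must be 3 nonnegative reals summing to 1, got {allele_probs}")
    rng = np.random.default_rng(seed)
    matrix = rng.choice(np.array(_CODES, dtype=np.int8), size=(m, n), p=probs)
    return GenotypePopulation(matrix=matrix)


def reference_genotype(pop: GenotypePopulation) -> np.ndarray:
    """Per-locus modal allele count; ties break toward the smallest code."""
    counts = np.stack([(pop.matrix == c).sum(axis=0) for c in _CODES])
    return np.argmax(counts, axis=0).astype(np.int8)


def marker_effect_matrix(pop: GenotypePopulation, ref: np.ndarray, kappa: float) -> np.ndarray:
    """Relative marker effects ``M = 1 + (kappa/3) * (Mpop - Mref)``."""
    if not (0.0 <= kappa <= 1.0):
        raise ValueError(f"kappa must be in [0, 1], got {kappa}")
    ref = np.asarray(ref).ravel()
    if ref.shape != (pop.n,) or not np.isin(ref, _CODES).all():
        raise ValueError("reference genotype must be an n-vector with entries in {0, 1, 2}")
    return 1.0 + (kappa / 3.0) * (pop.matrix.astype(float) - ref.astype(float))


def sample_expression_rates(P_mu: float, kappa: float, n: int, seed=None) -> np.ndarray:
    """Draw n baseline rates from ``Normal(P_mu, var=kappa*P_mu)``.

    Draws below ``1e-6 * P_mu`` are resampled so every rate is strictly
    positive.  Sampled once per simulation and shared across genotypes.
    """
    if not P_mu > 0:
        raise ValueError(f"P_mu must be positive, got {P_mu}")
    if not (0.0 <= kappa <= 1.0):
        raise ValueError(f"kappa must be in [0, 1], got {kappa}")
    rng = np.random.default_rng(seed)
    sd = np.sqrt(kappa * P_mu)
    floor = RATE_FLOOR_FRACTION * P_mu
    P = rng.normal(P_mu, sd, size=n)
    while True:
        bad = P < floor
        if not bad.any():
            return P
        P[bad] = rng.normal(P_mu, sd, size=int(bad.sum()))


def genotype_transcription_rates(P: np.ndarray, M: np.ndarray, j: int) -> np.ndarray:
    """Transcription rates of genotype ``j``: entrywise ``P * M[j]``."""
    P = np.asarray(P, dtype=float)
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[1] != P.shape[0]:
        raise ValueError(f"shape mismatch: P has {P.shape[0]} loci, M is {M.shape}")
    if not (0 <= j < M.shape[0]):
        raise IndexError(f"individual index {j} out of range for {M.shape[0]} individuals")
    return P * M[j]


def write_genotypes(pop: GenotypePopulation, path) -> None:
    """One individual per line: id followed by n allele counts."""
    with open(path, "w") as fh:
        for ind, row in zip(pop.individual_ids, pop.matrix):
            fh.write(ind + " " + " ".join(str(int(v)) for v in row) + "\n")


def read_genotypes(path) -> GenotypePopulation:
    ids: list[str] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise GenotypeFormatError(f"{path}: line {lineno}: expected id and codes")
            row = []
            for tok in tokens[1:]:
                if tok not in ("0", "1", "2"):
                    raise GenotypeFormatError(
                        f"{path}: line {lineno}: invalid allele count {tok!r}"
                    )
                row.append(int(tok))
            if rows and len(row) != len(rows[0]):
                raise GenotypeFormatError(
                    f"{path}: line {lineno}: expected {len(rows[0])} codes, got {len(row)}"
                )
            ids.append(tokens[0])
            rows.append(row)
    if not rows:
        raise GenotypeFormatError(f"{path}: no genotype records found")
    return GenotypePopulation(matrix=np.asarray(rows, dtype=np.int8), individual_ids=ids)


def read_core_genes(path, n_loci: int) -> CoreGenes:
    """Read core loci (1-based in the file) with optional explicit weights.

    When no weights are present each core gene gets weight ``1 / n_core``.
    """
    indices: list[int] = []
    weights: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            tokens = line.split()
            try:
                idx = int(tokens[0])
            except ValueError:
                raise GenotypeFormatError(
                    f"{path}: line {lineno}: invalid locus index {tokens[0]!r}"
                ) from None
            if not (1 <= idx <= n_loci):
                raise GenotypeFormatError(
                    f"{path}: line {lineno}: locus index {idx} outside 1..{n_loci}"
                )
            if idx - 1 in indices:
                raise GenotypeFormatError(f"{path}: line {lineno}: duplicate locus index {idx}")
            indices.append(idx - 1)
            if len(tokens) > 1:
                try:
                    weights.append(float(tokens[1]))
                except ValueError:
                    raise GenotypeFormatError(
                        f"{path}: line {lineno}: invalid weight {tokens[1]!r}"
                    ) from None
            else:
                weights.append(np.nan)
    if not indices:
        raise GenotypeFormatError(f"{path}: no core genes listed")
    w = np.asarray(weights)
    if np.isnan(w).all():
        w = np.full(len(indices), 1.0 / len(indices))
    elif np.isnan(w).any():
        raise GenotypeFormatError(f"{path}: weights must be given for all loci or none")
    return CoreGenes(indices=np.asarray(indices), weights=w)


def build_polymorphism_map(
    pop: GenotypePopulation,
    kappa: float,
    P_mu: float,
    seed=None,
    ref: np.ndarray | None = None,
    kappa_expression: float | None = None,
) -> PolymorphismMap:
    """Assemble the reference genotype, marker effects and sampled rates.

    ``kappa_expression`` optionally decouples the variance of the sampled
    rates from the marker-effect response (both default to ``kappa``).
    """
    if ref is None:
        ref = reference_genotype(pop)
    M = marker_effect_matrix(pop, ref, kappa)
    k_expr = kappa if kappa_expression is None else kappa_expression
    P = sample_expression_rates(P_mu, k_expr, pop.n, seed)
    return PolymorphismMap(Mref=ref, kappa=kappa, M=M, P_mu=P_mu, P=P)
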
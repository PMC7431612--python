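"""Synthetic microbiome cohorts with planted phenotype and SCFA structure.

The generator emulates the design the analysis assumes: ~105 rabbits housed
in small cage blocks, zero-inflated compositional taxon abundances measured
at a sequencing depth of ~40,000 tags, a finishing-weight phenotype
receiving additive presence (beta1) and abundance (beta2) effects from a
subset of causal taxa on top of sex and cage effects and Gaussian noise,
and fecal SCFA concentrations in which butyrate tracks designated
producer taxa.

Counts arise from a latent log-normal basis: per-taxon Gaussian log
abundances (optionally correlated between designated pairs via a Gaussian
copula), a Bernoulli-style structural presence mask applied before closure,
then multinomial read sampling at Poisson library sizes — so zeros come
from both structural absence and undersampling, and log-scale basis
variances are well-defined, matching the model SparCC assumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .tables import CountTable, PhenotypeFrame
from .twopart import feature_matrices
from . import tables as _tables

__all__ = [
    "SimulationConfig",
    "SimulatedCounts",
    "gen_count_table",
    "gen_phenotype",
    "gen_scfa",
    "write_truth",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the emulated study design: 105 animals (53 male / 52
    female), sequencing depth 40,000, cages of 5, finishing weight in grams
    around 2,500.
    """

    n_samples: int = 105
    n_taxa: int = 200
    library_size_mean: int = 40_000
    prevalence_range: tuple[float, float] = (0.15, 1.0)
    n_causal_taxa: int = 0
    causal_taxa: list[int] | None = None
    causal_prevalence_range: tuple[float, float] = (0.25, 0.9)
    beta1_effects: np.ndarray | None = None
    beta2_effects: np.ndarray | None = None
    target_microbial_variance_fraction: float | None = None
    intercept: float = 2500.0
    sex_effect: float = 100.0
    cage_effect_sd: float = 50.0
    cage_block_size: int = 5
    noise_sd: float = 200.0
    basis_correlation_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    basis_log_mean_sd: float = 1.5
    basis_log_sd: float = 1.0
    abundance_prevalence_coupling: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_taxa <= 0:
            raise ValueError("n_samples and n_taxa must be positive")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be positive")
        lo, hi = self.prevalence_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("prevalence_range must satisfy 0 < lo <= hi <= 1")
        if int(np.ceil(lo * self.n_samples)) > int(np.floor(hi * self.n_samples)):
            raise ValueError(
                "prevalence_range admits no integer presence count at this n_samples"
            )
        if self.n_causal_taxa < 0 or self.n_causal_taxa > self.n_taxa:
            raise ValueError("n_causal_taxa must lie in [0, n_taxa]")
        if self.causal_taxa is not None:
            if len(self.causal_taxa) != self.n_causal_taxa:
                raise ValueError("causal_taxa length must equal n_causal_taxa")
            if any(j < 0 or j >= self.n_taxa for j in self.causal_taxa):
                raise ValueError("causal taxon index out of range")
        for i, j, rho in self.basis_correlation_pairs:
            if not (0 <= i < self.n_taxa and 0 <= j < self.n_taxa and i != j):
                raise ValueError(f"invalid correlation pair ({i}, {j})")
            if not (-1 < rho < 1):
                raise ValueError("pair correlation must lie in (-1, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.cage_effect_sd < 0:
            raise ValueError("cage_effect_sd must be non-negative")
        f = self.target_microbial_variance_fraction
        if f is not None and not (0 <= f < 1):
            raise ValueError("target_microbial_variance_fraction must lie in [0, 1)")

    def resolve_effects(
        self, rng: np.random.Generator, prevalences: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Causal indices and (beta1, beta2) arrays, defaulting to unit effects.

        Unless ``causal_taxa`` is given explicitly, causal taxa are drawn
        among taxa whose prevalence falls in ``causal_prevalence_range``,
        so both the presence and the abundance part of a planted effect
        carry signal (an effect on a nearly-ubiquitous or nearly-absent
        taxon degenerates to a single-part effect).
        """
        if self.n_causal_taxa == 0:
            return np.array([], int), np.array([]), np.array([])
        if self.causal_taxa is not None:
            idx = np.asarray(self.causal_taxa, int)
        else:
            pool = np.arange(self.n_taxa)
            if prevalences is not None:
                lo, hi = self.causal_prevalence_range
                eligible = pool[(prevalences >= lo) & (prevalences <= hi)]
                if len(eligible) >= self.n_causal_taxa:
                    pool = eligible
            idx = np.sort(rng.choice(pool, size=self.n_causal_taxa, replace=False))
        b1 = (
            np.full(self.n_causal_taxa, 1.0)
            if self.beta1_effects is None
            else np.asarray(self.beta1_effects, float)
        )
        b2 = (
            np.full(self.n_causal_taxa, 1.0)
            if self.beta2_effects is None
            else np.asarray(self.beta2_effects, float)
        )
        if b1.shape != (self.n_causal_taxa,) or b2.shape != (self.n_causal_taxa,):
            raise ValueError("effect arrays must match n_causal_taxa")
        return idx, b1, b2


@dataclass
class SimulatedCounts(CountTable):
    """Count table plus the generator's latent state, kept for assertions.

    ``latent_log_basis`` is the n x m Gaussian log-abundance matrix before
    the presence mask and closure; ``structural_presence`` the mask itself.
    """

    latent_log_basis: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    structural_presence: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    prevalences: np.ndarray = field(default_factory=lambda: np.empty(0))


def _pair_correlation_matrix(cfg: SimulationConfig) -> np.ndarray | None:
    if not cfg.basis_correlation_pairs:
        return None
    C = np.eye(cfg.n_taxa)
    for i, j, rho in cfg.basis_correlation_pairs:
        C[i, j] = C[j, i] = rho
    try:
        np.linalg.cholesky(C + 1e-10 * np.eye(cfg.n_taxa))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "basis_correlation_pairs do not form a positive-definite correlation matrix"
        ) from exc
    return C


def gen_count_table(config: SimulationConfig) -> SimulatedCounts:
    """Generate a zero-inflated compositional count table.

    Deterministic under ``config.seed``. Structural presence counts are
    drawn per taxon uniformly over the integers compatible with
    ``prevalence_range``, so every realized structural prevalence falls in
    the configured range.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_samples, cfg.n_taxa

    # latent correlated Gaussian log-abundances
    C = _pair_correlation_matrix(cfg)
    Z = rng.standard_normal((n, m))
    if C is not None:
        Z = Z @ np.linalg.cholesky(C + 1e-10 * np.eye(m)).T
    mu = rng.normal(0.0, cfg.basis_log_mean_sd, size=m)
    L = mu + cfg.basis_log_sd * Z

    # structural presence with exact counts inside prevalence_range
    lo, hi = cfg.prevalence_range
    k_lo = int(np.ceil(lo * n))
    k_hi = int(np.floor(hi * n))
    k = rng.integers(k_lo, k_hi + 1, size=m)
    if cfg.abundance_prevalence_coupling:
        # abundance-occupancy relationship: dominant taxa are ubiquitous,
        # rare taxa patchy; keeps each sample's log-total stable, as in
        # real communities where the core taxa are shared
        k_sorted = np.sort(k)[::-1]
        k = np.empty_like(k_sorted)
        k[np.argsort(-mu)] = k_sorted
    M = np.zeros((n, m), dtype=bool)
    for j in range(m):
        M[rng.choice(n, size=k[j], replace=False), j] = True

    W = np.exp(L) * M
    # guard: closure needs at least one present taxon per sample
    empty = ~M.any(axis=1)
    if empty.any():
        for i in np.flatnonzero(empty):
            M[i, int(np.argmax(L[i]))] = True
        W = np.exp(L) * M

    X = W / W.sum(axis=1, keepdims=True)
    sizes = rng.poisson(cfg.library_size_mean, size=n)
    sizes = np.maximum(sizes, 1)
    counts = rng.multinomial(sizes, X)

    return SimulatedCounts(
        sample_ids=[f"S{i:04d}" for i in range(n)],
        taxon_ids=[f"OTU{j:04d}" for j in range(m)],
        counts=counts,
        latent_log_basis=L,
        structural_presence=M,
        prevalences=k / n,
    )


@dataclass
class PhenotypeTruth:
    """Ground truth stored alongside a simulated phenotype."""

    causal_taxa: list[str]
    causal_indices: list[int]
    beta1: list[float]
    beta2: list[float]
    effect_scale: float
    microbial_variance_fraction: float
    seed: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def gen_phenotype(
    table: CountTable, config: SimulationConfig
) -> tuple[PhenotypeFrame, PhenotypeTruth]:
    """Generate a finishing-weight phenotype from a simulated count table.

    y_i = intercept + sex_effect * sex_i + cage_i
          + c * sum_causal (beta1 * b_ij + beta2 * q_ij) + eps_i

    where b/q are the two-part features of the realized counts and c
    rescales the microbial term so its realized share of total phenotypic
    variance equals ``target_microbial_variance_fraction`` (c = 1 when the
    target is unset). eps ~ Normal(0, noise_sd^2).
    """
    cfg = config
    n = table.n_samples
    if n != cfg.n_samples:
        raise ValueError("table/config sample count mismatch")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))

    idx, b1, b2 = cfg.resolve_effects(rng, prevalences=(table.counts > 0).mean(axis=0))

    abund = _tables.to_relative(table)
    Bmat, Qmat, _, _ = feature_matrices(abund)
    if len(idx):
        g = Bmat[:, idx] @ b1 + Qmat[:, idx] @ b2
    else:
        g = np.zeros(n)

    # covariates: near-balanced sexes, cages as consecutive blocks
    n_male = (n + 1) // 2
    sex_codes = np.zeros(n, int)
    sex_codes[rng.permutation(n)[:n_male]] = 1
    cage_ids = np.arange(n) // max(cfg.cage_block_size, 1)
    cage_fx = rng.normal(0.0, cfg.cage_effect_sd, size=cage_ids.max() + 1)
    eps = rng.normal(0.0, cfg.noise_sd, size=n)
    other = cfg.sex_effect * sex_codes + cage_fx[cage_ids] + eps

    scale = 1.0
    f = cfg.target_microbial_variance_fraction
    if f is not None and len(idx):
        vg, vo = np.var(g), np.var(other)
        if f == 0 or vg == 0:
            scale = 0.0
        else:
            scale = float(np.sqrt(f / (1 - f) * vo / vg))
    y = cfg.intercept + other + scale * g

    gv = np.var(scale * g)
    realized = float(gv / np.var(y)) if np.var(y) > 0 else 0.0
    truth = PhenotypeTruth(
        causal_taxa=[table.taxon_ids[j] for j in idx],
        causal_indices=[int(j) for j in idx],
        beta1=[float(v * scale) for v in b1],
        beta2=[float(v * scale) for v in b2],
        effect_scale=scale,
        microbial_variance_fraction=realized,
        seed=cfg.seed,
    )
    pheno = PhenotypeFrame(
        sample_ids=list(table.sample_ids),
        phenotype=y,
        sex=np.where(sex_codes == 1, "M", "F"),
        cage=np.array([f"C{c:03d}" for c in cage_ids]),
    )
    return pheno, truth


def gen_scfa(
    table: CountTable,
    producer_taxa: list[str],
    effect: float,
    seed: int,
    noise_sd: float = 0.25,
):
    """Fecal SCFA concentrations (mM) with butyrate tied to producer taxa.

    Butyrate is log-normal with log-mean shifted by ``effect`` times the
    standardized summed relative abundance of the producer taxa (so its
    association with the producer sum is monotone with the sign of
    ``effect``); acetate and propionate are independent log-normal noise at
    typical fecal concentrations.
    """
    from .groupstats import ScfaTable

    unknown = [t for t in producer_taxa if t not in table.taxon_ids]
    if unknown:
        raise ValueError(f"unknown producer taxa: {unknown}")
    rng = np.random.default_rng(seed)
    frac = _tables.to_relative(table).fractions
    cols = [table.taxon_ids.index(t) for t in producer_taxa]
    s = frac[:, cols].sum(axis=1) if cols else np.zeros(table.n_samples)
    sd = s.std()
    z = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
    n = table.n_samples
    butyrate = np.exp(np.log(5.0) + effect * z + noise_sd * rng.standard_normal(n))
    acetate = np.exp(np.log(30.0) + 0.3 * rng.standard_normal(n))
    propionate = np.exp(np.log(6.0) + 0.3 * rng.standard_normal(n))
    return ScfaTable(
        sample_ids=list(table.sample_ids),
        acetate=acetate,
        propionate=propionate,
        butyrate=butyrate,
    )


def write_truth(truth: PhenotypeTruth, path) -> None:
    """JSON sidecar with the true causal set, effects, and seed."""
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
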
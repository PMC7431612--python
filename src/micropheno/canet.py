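"""Co-abundance-group (CAG) networks from SparCC correlations.

SparCC estimates correlations of latent (basis) abundances from
compositional counts: for each pair the log-ratio variance
t_ij = var(log(x_i / x_j)) = w_i + w_j - 2*cov_ij is observable even though
the basis variances w are not. Under a sparsity assumption (most pairwise
covariances negligible) the row sums of t give a linear system for w, and

    rho_ij = (w_i + w_j - t_ij) / (2 * sqrt(w_i * w_j))

Strongly correlated pairs violate the sparsity assumption, so the pair with
the largest |rho| above an exclusion threshold is iteratively removed from
the system and the basis re-solved. Fraction uncertainty is handled by
repeated Dirichlet-posterior resampling, aggregated by the median.

CAGs are defined by Ward-linkage clustering of the distance 1 - rho and
validated by PERMANOVA on that distance matrix; each CAG's summed relative
abundance is correlated with the phenotype by Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .tables import AbundanceTable, CountTable, PhenotypeFrame
from .twopart import bh_adjust

__all__ = [
    "sparcc",
    "sparcc_pvalues",
    "build_network",
    "define_cags",
    "permanova",
    "cag_phenotype_corr",
    "CorrelationNetwork",
    "build_canet",
]


@dataclass
class CorrelationNetwork:
    """SparCC correlation matrix with significance, edges, and CAG labels."""

    taxon_ids: list[str]
    rho: np.ndarray
    pseudo_p: np.ndarray
    q: np.ndarray
    edges: pd.DataFrame
    cag_labels: np.ndarray
    permanova_F: float
    permanova_p: float
    cag_supported: bool


def _draw_fractions(
    counts: np.ndarray, scheme: str, rng: np.random.Generator
) -> np.ndarray:
    if scheme == "dirichlet":
        g = rng.standard_gamma(counts + 1.0)
        return g / g.sum(axis=1, keepdims=True)
    if scheme == "add_one":
        c = counts + 1.0
        return c / c.sum(axis=1, keepdims=True)
    if scheme == "none":
        if np.any(counts <= 0):
            raise ValueError("pseudocount scheme 'none' requires strictly positive counts")
        c = counts.astype(float)
        return c / c.sum(axis=1, keepdims=True)
    raise ValueError(f"unknown pseudocount scheme {scheme!r}")


def _basis_variances(t: np.ndarray, include: np.ndarray) -> np.ndarray:
    """Solve the sparsity-approximation linear system for basis variances.

    ``include[i, j]`` marks pairs whose covariance is assumed negligible;
    for each taxon, sum_{j in S_i} t_ij = |S_i| * w_i + sum_{j in S_i} w_j.
    Taxa excluded from every pair fall back to w_i = median of the solved
    variances. Non-positive solutions are clamped to a small floor.
    """
    m = t.shape[0]
    d = include.sum(axis=1).astype(float)
    A = include.astype(float) + np.diag(d)
    rhs = (t * include).sum(axis=1)
    solvable = d >= 1
    w = np.full(m, np.nan)
    if solvable.all():
        w = np.linalg.lstsq(A, rhs, rcond=None)[0]
    else:
        sub = np.ix_(solvable, solvable)
        if solvable.any():
            w[solvable] = np.linalg.lstsq(A[sub], rhs[solvable], rcond=None)[0]
        fallback = np.nanmedian(w[solvable]) if solvable.any() else 1.0
        w[~solvable] = fallback
    return np.maximum(w, 1e-10)


def _sparcc_once(
    logf: np.ndarray, exclusion_threshold: float, max_exclusions: int
) -> np.ndarray:
    m = logf.shape[1]
    V = np.cov(logf, rowvar=False)
    v = np.diag(V)
    t = v[:, None] + v[None, :] - 2.0 * V
    include = ~np.eye(m, dtype=bool)
    n_excluded = 0
    # each taxon may lose at most two partners: the refinement is meant to
    # drop a few genuinely correlated pairs, not to erode one taxon's row
    # sum until its basis variance collapses
    excl_per_taxon = np.zeros(m, dtype=int)
    max_per_taxon = 2
    for _ in range(max_exclusions + 1):
        w = _basis_variances(t, include)
        # a collapsed solved variance (non-positive, or far below the
        # typical scale) means the sparsity system broke down for that
        # taxon; its correlations are unidentifiable and are reported as 0
        # rather than as saturated +/-1 artifacts
        bad = w < max(1e-10, 1e-2 * float(np.median(w)))
        with np.errstate(invalid="ignore"):
            rho = (w[:, None] + w[None, :] - t) / (2.0 * np.sqrt(np.outer(w, w)))
        rho = np.clip(rho, -1.0, 1.0)
        rho[bad, :] = 0.0
        rho[:, bad] = 0.0
        np.fill_diagonal(rho, 1.0)
        if n_excluded >= max_exclusions:
            break
        cand = np.abs(rho).copy()
        cand[~include] = 0.0
        capped = excl_per_taxon >= max_per_taxon
        cand[capped, :] = 0.0
        cand[:, capped] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        include[i, j] = include[j, i] = False
        excl_per_taxon[i] += 1
        excl_per_taxon[j] += 1
        n_excluded += 1
    return rho


def _as_counts(counts) -> np.ndarray:
    if isinstance(counts, CountTable):
        return counts.counts
    return np.asarray(counts)


def sparcc(
    counts,
    n_outer: int = 20,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
    pseudocount: str = "dirichlet",
    seed: int | None = None,
) -> np.ndarray:
    """SparCC basis correlation matrix of a count table.

    ``pseudocount`` selects the zero-handling scheme: ``"dirichlet"``
    (posterior fraction resampling with a unit prior, median over
    ``n_outer`` draws — the default), ``"add_one"`` (fixed +1 pseudocount,
    a single deterministic estimate), or ``"none"`` (plain closure;
    requires strictly positive counts and is exactly invariant to
    per-sample count rescaling).
    """
    X = _as_counts(counts)
    n, m = X.shape
    if n < 4:
        raise ValueError("SparCC needs at least 4 samples")
    if m < 3:
        raise ValueError("SparCC needs at least 3 taxa (basis system underdetermined)")
    rng = np.random.default_rng(seed)
    if pseudocount != "dirichlet":
        frac = _draw_fractions(X, pseudocount, rng)
        return _sparcc_once(np.log(frac), exclusion_threshold, max_exclusions)
    rhos = np.empty((n_outer, m, m))
    for it in range(n_outer):
        frac = _draw_fractions(X, "dirichlet", rng)
        rhos[it] = _sparcc_once(np.log(frac), exclusion_threshold, max_exclusions)
    rho = np.median(rhos, axis=0)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return rho


def sparcc_pvalues(
    counts,
    n_perm: int = 100,
    seed: int | None = None,
    n_outer: int = 5,
    **sparcc_kw,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation pseudo-p (and observed rho) for SparCC correlations.

    Each permutation independently shuffles every taxon's counts across
    samples, destroying between-taxon association while keeping marginals;
    two-sided pseudo-p = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm),
    so the attainable floor is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = _as_counts(counts)
    rng = np.random.default_rng(seed)
    rho_obs = sparcc(X, n_outer=n_outer, seed=int(rng.integers(2**31 - 1)), **sparcc_kw)
    m = X.shape[1]
    exceed = np.zeros((m, m))
    for _ in range(n_perm):
        Xp = np.empty_like(X)
        for j in range(m):
            Xp[:, j] = X[rng.permutation(X.shape[0]), j]
        rho_p = sparcc(Xp, n_outer=n_outer, seed=int(rng.integers(2**31 - 1)), **sparcc_kw)
        exceed += np.abs(rho_p) >= np.abs(rho_obs)
    p = (1.0 + exceed) / (1.0 + n_perm)
    np.fill_diagonal(p, np.nan)
    return p, rho_obs


def build_network(
    rho: np.ndarray,
    q: np.ndarray,
    taxon_ids: list[str],
    r_threshold: float = 0.35,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Edge list of pairs with |rho| > r_threshold and FDR q < q_threshold."""
    m = rho.shape[0]
    rows = []
    for i in range(m):
        for j in range(i + 1, m):
            if np.isfinite(q[i, j]) and abs(rho[i, j]) > r_threshold and q[i, j] < q_threshold:
                rows.append(
                    {
                        "source": taxon_ids[i],
                        "target": taxon_ids[j],
                        "rho": rho[i, j],
                        "q": q[i, j],
                        "sign": "+" if rho[i, j] > 0 else "-",
                    }
                )
    return pd.DataFrame(rows, columns=["source", "target", "rho", "q", "sign"])


def qvalues_upper_triangle(p: np.ndarray) -> np.ndarray:
    """BH adjustment over the upper triangle, mirrored to a full matrix."""
    m = p.shape[0]
    iu = np.triu_indices(m, k=1)
    q_flat = bh_adjust(p[iu])
    q = np.full((m, m), np.nan)
    q[iu] = q_flat
    q.T[iu] = q_flat
    return q


def permanova(
    dist: np.ndarray, labels: np.ndarray, n_perm: int = 999, seed: int | None = None
) -> tuple[float, float]:
    """PERMANOVA pseudo-F of a distance matrix against group labels.

    F = ((SST - SSW) / (a - 1)) / (SSW / (N - a)) with sums of squared
    distances; significance by label permutation with the +1-corrected
    estimator, so the attainable floor is 1/(n_perm + 1).
    """
    D2 = np.asarray(dist, float) ** 2
    labels = np.asarray(labels)
    N = D2.shape[0]
    groups = np.unique(labels)
    a = len(groups)
    if a < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    iu = np.triu_indices(N, k=1)
    sst = D2[iu].sum() / N

    def _ssw(lab: np.ndarray) -> float:
        ssw = 0.0
        for g in groups:
            idx = np.flatnonzero(lab == g)
            if len(idx) > 1:
                sub = D2[np.ix_(idx, idx)]
                ssw += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
        return ssw

    def _f(lab: np.ndarray) -> float:
        ssw = _ssw(lab)
        return ((sst - ssw) / (a - 1)) / (ssw / (N - a))

    f_obs = _f(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _f(labels[rng.permutation(N)]) >= f_obs:
            hits += 1
    return float(f_obs), (1.0 + hits) / (1.0 + n_perm)


def define_cags(
    rho: np.ndarray,
    k: int = 2,
    n_perm: int = 999,
    seed: int | None = None,
    distance: str = "one_minus_rho",
) -> tuple[np.ndarray, float, float, bool]:
    """Ward-linkage CAGs from a correlation matrix, validated by PERMANOVA.

    Returns (labels 1..k, pseudo-F, p, supported) where ``supported`` is
    True when the PERMANOVA p < 0.05.
    """
    m = rho.shape[0]
    if k >= m:
        raise ValueError("k must be smaller than the number of taxa")
    if distance == "one_minus_rho":
        d = 1.0 - rho
    elif distance == "sqrt_two_one_minus_rho":
        d = np.sqrt(np.clip(2.0 * (1.0 - rho), 0.0, None))
    else:
        raise ValueError(f"unknown distance {distance!r}")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    Z = linkage(squareform(d, checks=False), method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    F, p = permanova(d, labels, n_perm=n_perm, seed=seed)
    return labels, F, p, p < 0.05


def cag_phenotype_corr(
    cag_labels: np.ndarray,
    abund: AbundanceTable,
    pheno: PhenotypeFrame,
) -> pd.DataFrame:
    """Spearman correlation of each CAG's summed abundance with the phenotype.

    The CAG abundance of a sample is the sum of its member taxa's
    fractions; correlation is against the residualized phenotype, with BH
    correction across CAGs.
    """
    if pheno.residual is None:
        raise ValueError("phenotype must be residualized first")
    if list(abund.sample_ids) != list(pheno.sample_ids):
        raise ValueError("abundance and phenotype sample ids must align")
    labels = np.asarray(cag_labels)
    rows = []
    for g in np.unique(labels):
        s = abund.fractions[:, labels == g].sum(axis=1)
        rho, p = stats.spearmanr(s, pheno.residual)
        rows.append({"cag": int(g), "n_taxa": int((labels == g).sum()), "rho": rho, "p": p})
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def build_canet(
    counts,
    taxon_ids: list[str] | None = None,
    n_outer: int = 20,
    n_perm_edges: int = 100,
    n_perm_cag: int = 999,
    r_threshold: float = 0.35,
    q_threshold: float = 0.05,
    k: int = 2,
    seed: int | None = None,
    pseudocount: str = "dirichlet",
) -> CorrelationNetwork:
    """Full co-abundance analysis: SparCC -> significance -> edges -> CAGs."""
    X = _as_counts(counts)
    if taxon_ids is None:
        taxon_ids = (
            list(counts.taxon_ids)
            if isinstance(counts, CountTable)
            else [f"T{j}" for j in range(X.shape[1])]
        )
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    s_edge, s_rho, s_cag = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(3))
    p, _ = sparcc_pvalues(
        X, n_perm=n_perm_edges, seed=s_edge, pseudocount=pseudocount
    )
    rho = sparcc(X, n_outer=n_outer, seed=s_rho, pseudocount=pseudocount)
    q = qvalues_upper_triangle(p)
    edges = build_network(rho, q, taxon_ids, r_threshold, q_threshold)
    labels, F, pp, ok = define_cags(rho, k=k, n_perm=n_perm_cag, seed=s_cag)
    return CorrelationNetwork(
        taxon_ids=taxon_ids,
        rho=rho,
        pseudo_p=p,
        q=q,
        edges=edges,
        cag_labels=labels,
        permanova_F=F,
        permanova_p=pp,
        cag_supported=ok,
    )
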
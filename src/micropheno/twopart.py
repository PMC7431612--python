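"""Two-part association model between taxa and a residualized phenotype.

Zero-inflated relative abundances are split into a binary feature b
(presence/absence) and a quantitative feature q (standardized log relative
abundance among the samples where the taxon is present; zero where absent).
Three analyses are run per taxon:

* binary   — OLS of the residual phenotype on b over all samples;
* quantitative — OLS of the residual phenotype on q over present samples;
* meta     — Stouffer weighted-Z combination of the two, weights sqrt(n).

The per-taxon association p-value is the minimum of the defined p-values.
Because taking a minimum is itself a selection, the scan corrects it (and
any residual skewness) empirically: the residual phenotype is permuted B
times, the min-p recomputed under each permutation with the same shuffles
reused across taxa, and p_perm = (1 + #{min-p_perm <= min-p_obs}) / (1 + B).
Benjamini-Hochberg FDR is then applied across taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable, PhenotypeFrame

__all__ = [
    "TwoPartFeatures",
    "make_features",
    "feature_matrices",
    "binary_assoc",
    "quant_assoc",
    "meta_combine",
    "two_part_scan",
    "bh_adjust",
]

#: minimum number of present samples for the quantitative analysis
MIN_PRESENT_QUANT = 4

_EPS = 1e-12


@dataclass
class TwoPartFeatures:
    """Binary and quantitative features of one taxon.

    ``q`` is the log relative abundance standardized (population SD) over
    present samples and set to 0 where absent, so q = 0 wherever b = 0.
    ``log_mean``/``log_sd`` are the standardization parameters, kept so a
    validation set can be featurized on a discovery set's scale.
    """

    taxon_id: str
    b: np.ndarray
    q: np.ndarray
    n_present: int
    log_mean: float
    log_sd: float

    @property
    def degenerate(self) -> bool:
        return self.n_present == 0


def feature_matrices(
    abund: AbundanceTable,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (B, Q, log_mean, log_sd) for all taxa at once.

    B is the n x m presence matrix; Q the matching standardized-log matrix
    (0 where absent). Taxa present in fewer than two samples, or with zero
    log variance among present samples, get sd = 0 and an all-zero Q column.
    """
    frac = abund.fractions
    B = (frac > 0).astype(float)
    n_present = B.sum(axis=0)
    with np.errstate(divide="ignore"):
        logf = np.where(frac > 0, np.log(frac), 0.0)
    denom = np.maximum(n_present, 1.0)
    mu = (logf * B).sum(axis=0) / denom
    var = ((logf - mu) ** 2 * B).sum(axis=0) / denom
    sd = np.sqrt(var)
    usable = (n_present >= 2) & (sd > _EPS)
    safe_sd = np.where(usable, sd, 1.0)
    Q = np.where(B > 0, (logf - mu) / safe_sd, 0.0)
    Q[:, ~usable] = 0.0
    sd = np.where(usable, sd, 0.0)
    return B, Q, mu, sd


def make_features(abund: AbundanceTable, taxon_id: str) -> TwoPartFeatures:
    """Two-part features of one taxon of an abundance table."""
    j = abund.taxon_ids.index(taxon_id)
    B, Q, mu, sd = feature_matrices(abund)
    return TwoPartFeatures(
        taxon_id=taxon_id,
        b=B[:, j],
        q=Q[:, j],
        n_present=int(B[:, j].sum()),
        log_mean=float(mu[j]),
        log_sd=float(sd[j]),
    )


def _simple_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, two-sided t-test p, and t of y ~ x; (nan, nan, nan) if degenerate."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sxx = ((x - x.mean()) ** 2).sum()
    if n < 3 or sxx < _EPS:
        return float("nan"), float("nan"), float("nan")
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    sse = ((y - y.mean()) ** 2).sum() - slope * sxy
    df = n - 2
    sigma2 = max(sse, 0.0) / df
    if sigma2 <= 0:
        t = np.inf * np.sign(slope) if slope != 0 else 0.0
    else:
        t = slope / np.sqrt(sigma2 / sxx)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(slope), float(p), float(t)


def binary_assoc(features: TwoPartFeatures, residual: np.ndarray) -> tuple[float, float]:
    """Effect (beta1) and p of presence/absence on the residual phenotype.

    Undefined (NaN) when the presence indicator is constant.
    """
    b = features.b
    if b.sum() == 0 or b.sum() == b.size:
        return float("nan"), float("nan")
    beta1, p, _ = _simple_ols(b, residual)
    return beta1, p


def quant_assoc(
    features: TwoPartFeatures,
    residual: np.ndarray,
    min_present: int = MIN_PRESENT_QUANT,
) -> tuple[float, float]:
    """Effect (beta2) and p of abundance-when-present on the residual.

    Only present samples enter; undefined (NaN) below ``min_present``
    present samples or for constant q.
    """
    mask = features.b > 0
    if mask.sum() < min_present:
        return float("nan"), float("nan")
    beta2, p, _ = _simple_ols(features.q[mask], np.asarray(residual, float)[mask])
    return beta2, p


def meta_combine(
    z_binary: float, z_quant: float, n_binary: float, n_quant: float
) -> float:
    """Stouffer weighted-Z meta p (weights sqrt(n)); NaN unless both defined."""
    if not (np.isfinite(z_binary) and np.isfinite(z_quant)):
        return float("nan")
    w_b, w_q = np.sqrt(n_binary), np.sqrt(n_quant)
    z = (w_b * z_binary + w_q * z_quant) / np.sqrt(w_b**2 + w_q**2)
    return float(2.0 * stats.norm.sf(abs(z)))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN entries are left out of m."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _scan_stats(
    B_mat: np.ndarray,
    Q_mat: np.ndarray,
    Y: np.ndarray,
    min_present: int = MIN_PRESENT_QUANT,
) -> dict[str, np.ndarray]:
    """All per-taxon statistics for every phenotype column of Y at once.

    Y is n x k (observed residual plus permuted copies); returns m x k
    arrays. Closed-form simple regression via masked sufficient statistics
    keeps the permutation loop to a handful of matrix products.
    """
    n, m = B_mat.shape
    k = Y.shape[1]
    nb = B_mat.sum(axis=0)  # n_present per taxon
    Sy = Y.sum(axis=0)  # (k,)
    Syy = (Y**2).sum(axis=0)
    SbY = B_mat.T @ Y  # (m, k): sum of y over present samples
    SbYY = B_mat.T @ (Y**2)

    out: dict[str, np.ndarray] = {"n_present": nb}

    # binary part: y ~ b over all n samples
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx_b = nb - nb**2 / n  # (m,)
        sxy_b = SbY - np.outer(nb, Sy) / n
        sst = Syy - Sy**2 / n  # (k,)
        slope_b = sxy_b / sxx_b[:, None]
        sse_b = sst[None, :] - slope_b * sxy_b
        df_b = n - 2
        se2 = np.maximum(sse_b, 0.0) / df_b / sxx_b[:, None]
        t_b = np.where(se2 > 0, slope_b / np.sqrt(se2), np.inf * np.sign(slope_b))
    valid_b = (nb > 0) & (nb < n)
    p_b = 2.0 * stats.t.sf(np.abs(t_b), df_b)
    p_b[~valid_b, :] = np.nan
    slope_b[~valid_b, :] = np.nan
    t_b[~valid_b, :] = np.nan

    # quantitative part: y ~ q over present samples only (q is 0 off-mask,
    # so masked sums of q reduce to plain sums)
    Sq = Q_mat.sum(axis=0)
    Sqq = (Q_mat**2).sum(axis=0)
    SqY = Q_mat.T @ Y
    with np.errstate(divide="ignore", invalid="ignore"):
        nb_safe = np.maximum(nb, 1.0)
        sxx_q = Sqq - Sq**2 / nb_safe
        sxy_q = SqY - np.outer(Sq / nb_safe, np.ones(k)) * SbY
        syy_q = SbYY - SbY**2 / nb_safe[:, None]
        slope_q = sxy_q / sxx_q[:, None]
        sse_q = syy_q - slope_q * sxy_q
        df_q = nb - 2
        se2q = np.maximum(sse_q, 0.0) / np.maximum(df_q, 1.0)[:, None] / sxx_q[:, None]
        t_q = np.where(se2q > 0, slope_q / np.sqrt(se2q), np.inf * np.sign(slope_q))
    valid_q = (nb >= min_present) & (sxx_q > _EPS)
    with np.errstate(invalid="ignore"):
        p_q = 2.0 * stats.t.sf(np.abs(t_q), np.maximum(df_q, 1.0)[:, None])
    p_q[~valid_q, :] = np.nan
    slope_q[~valid_q, :] = np.nan
    t_q[~valid_q, :] = np.nan

    # meta: Stouffer weighted-Z, weights sqrt(sample size of each part
    # (z recovered from p to keep heavy-tailed t statistics on normal scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_b = np.sign(t_b) * stats.norm.isf(np.clip(p_b, 1e-300, 1.0) / 2.0)
        z_q = np.sign(t_q) * stats.norm.isf(np.clip(p_q, 1e-300, 1.0) / 2.0)
        w_b, w_q = np.sqrt(float(n)), np.sqrt(nb)
        z_m = (w_b * z_b + w_q[:, None] * z_q) / np.sqrt(w_b**2 + nb)[:, None]
    valid_m = valid_b[:, None] & valid_q[:, None] & np.isfinite(z_b) & np.isfinite(z_q)
    p_m = np.where(valid_m, 2.0 * stats.norm.sf(np.abs(z_m)), np.nan)
    z_m = np.where(valid_m, z_m, np.nan)

    with warnings_ignore_all_nan():
        p_final = np.nanmin(np.stack([p_b, p_q, p_m]), axis=0)

    out.update(
        p_binary=p_b, p_quant=p_q, p_meta=p_m, p_final=p_final,
        beta1=slope_b, beta2=slope_q, z_binary=z_b, z_quant=z_q, z_meta=z_m,
    )
    return out


class warnings_ignore_all_nan:
    """Context silencing numpy's all-NaN-slice warning (expected for
    all-degenerate taxa, which are flagged downstream)."""

    def __enter__(self):
        import warnings

        self._cm = warnings.catch_warnings()
        self._cm.__enter__()
        import warnings as w

        w.filterwarnings("ignore", message="All-NaN slice encountered")
        return self

    def __exit__(self, *exc):
        return self._cm.__exit__(*exc)


def two_part_scan(
    abund: AbundanceTable,
    pheno: PhenotypeFrame,
    B: int = 1000,
    seed: int | None = None,
    min_present: int = MIN_PRESENT_QUANT,
) -> pd.DataFrame:
    """Scan every taxon for association with the residualized phenotype.

    Permutation correction shuffles the residual phenotype B times (the
    identical shuffles are reused for every taxon, making the scan
    deterministic under ``seed`` and preserving the between-taxon
    correlation structure); ``p_perm = (1 + #{min-p_perm <= min-p_obs}) /
    (1 + B)``. BH q-values are computed across taxa on p_perm; taxa
    degenerate in all three analyses are flagged and excluded from the FDR
    family. ``B=0`` skips the permutation correction (p_perm = NaN) — used
    by fast cross-validation.

    Returns one row per taxon with columns: taxon_id, n_present, beta1,
    beta2, p_binary, p_quant, p_meta, p_final, source, direction, p_perm,
    q_value, degenerate, log_mean, log_sd.
    """
    if B < 0:
        raise ValueError("B must be >= 0")
    ids = list(pheno.sample_ids)
    if list(abund.sample_ids) != ids:
        order = {s: i for i, s in enumerate(abund.sample_ids)}
        if set(ids) != set(abund.sample_ids):
            raise ValueError("abundance and phenotype sample ids do not match")
        idx = [order[s] for s in ids]
        abund = AbundanceTable(
            [abund.sample_ids[i] for i in idx], abund.taxon_ids, abund.fractions[idx]
        )
    if pheno.residual is None:
        raise ValueError("phenotype must be residualized first (run residualize)")

    y = np.asarray(pheno.residual, float)
    n = y.size
    Bmat, Qmat, mu, sd = feature_matrices(abund)
    m = Bmat.shape[1]

    rng = np.random.default_rng(seed)
    cols = [y]
    for _ in range(B):
        cols.append(y[rng.permutation(n)])
    Y = np.column_stack(cols)

    s = _scan_stats(Bmat, Qmat, Y, min_present=min_present)
    p_final_obs = s["p_final"][:, 0]
    degenerate = ~np.isfinite(p_final_obs)

    if B > 0:
        perm_min = s["p_final"][:, 1:]
        with warnings_ignore_all_nan():
            hits = np.nansum(perm_min <= p_final_obs[:, None], axis=1)
        p_perm = (1.0 + hits) / (1.0 + B)
        p_perm[degenerate] = np.nan
    else:
        p_perm = np.full(m, np.nan)

    # which analysis supplied p_final, and the direction of its effect
    stacked = np.stack(
        [s["p_binary"][:, 0], s["p_quant"][:, 0], s["p_meta"][:, 0]]
    )
    zs = np.stack([s["z_binary"][:, 0], s["z_quant"][:, 0], s["z_meta"][:, 0]])
    names = np.array(["binary", "quantitative", "meta"])
    with warnings_ignore_all_nan():
        safe = np.where(np.isfinite(stacked), stacked, np.inf)
        src_idx = np.argmin(safe, axis=0)
    source = np.where(degenerate, "degenerate", names[src_idx])
    z_sel = zs[src_idx, np.arange(m)]
    direction = np.where(
        degenerate, 0, np.sign(np.where(np.isfinite(z_sel), z_sel, 0))
    ).astype(int)

    q = bh_adjust(p_perm if B > 0 else p_final_obs)

    return pd.DataFrame(
        {
            "taxon_id": abund.taxon_ids,
            "n_present": s["n_present"].astype(int),
            "beta1": s["beta1"][:, 0],
            "beta2": s["beta2"][:, 0],
            "p_binary": s["p_binary"][:, 0],
            "p_quant": s["p_quant"][:, 0],
            "p_meta": s["p_meta"][:, 0],
            "p_final": p_final_obs,
            "source": source,
            "direction": direction,
            "p_perm": p_perm,
            "q_value": q,
            "degenerate": degenerate,
            "log_mean": mu,
            "log_sd": sd,
        }
    )
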
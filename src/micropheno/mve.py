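"""Phenotypic variance explained by the microbiome (microbiability).

The estimator repeatedly splits the cohort into an 80% discovery and a 20%
validation set. On discovery data the two-part scan supplies per-taxon
effect sizes (beta1, beta2) and p-values; at each p-value threshold the
selected taxa define an additive microbial predictor

    r_m,i = sum_j ( beta1_j * b_ij + beta2_j * q_ij )

evaluated on the validation samples, with the q standardization frozen at
the discovery set's per-taxon log mean/SD. Variance explained at a
threshold is the squared Pearson correlation between r_m and the
residualized phenotype on validation samples, averaged over repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AbundanceTable, PhenotypeFrame
from .twopart import two_part_scan

__all__ = ["VarianceExplainedResult", "predict_rm", "cross_validate", "DEFAULT_THRESHOLDS"]

#: p-value grid spanning the conventional sweep from 1e-5 to 0.1
DEFAULT_THRESHOLDS: tuple[float, ...] = (1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1)


@dataclass
class VarianceExplainedResult:
    thresholds: np.ndarray
    mean_r2: np.ndarray
    sd_r2: np.ndarray
    mean_n_selected: np.ndarray
    n_repeats: int
    train_fraction: float
    seed: int | None = None
    r2_matrix: np.ndarray = field(repr=False, default=None)  # repeats x thresholds

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "mean_R2": self.mean_r2,
                "sd_R2": self.sd_r2,
                "mean_n_selected": self.mean_n_selected,
            }
        )


def _validation_features(
    abund: AbundanceTable, assoc: pd.DataFrame, rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """b and q for validation rows on the discovery standardization scale.

    Taxa degenerate in discovery (log_sd = 0) contribute zero through q.
    """
    frac = abund.fractions[rows]
    B = (frac > 0).astype(float)
    mu = assoc["log_mean"].to_numpy()
    sd = assoc["log_sd"].to_numpy()
    safe_sd = np.where(sd > 0, sd, 1.0)
    with np.errstate(divide="ignore"):
        logf = np.where(frac > 0, np.log(frac), 0.0)
    Q = np.where(B > 0, (logf - mu) / safe_sd, 0.0)
    Q[:, sd <= 0] = 0.0
    return B, Q


def predict_rm(
    assoc: pd.DataFrame,
    abund: AbundanceTable,
    threshold: float,
    rows: np.ndarray | None = None,
    select_on: str = "p_final",
) -> np.ndarray:
    """Additive microbial predictor for (validation) samples.

    ``assoc`` is a two-part scan result on discovery data; taxa with
    ``select_on`` p <= threshold contribute beta1*b + beta2*q. Returns all
    zeros (an empty selection) when nothing passes.
    """
    if rows is None:
        rows = np.arange(abund.n_samples)
    p = assoc[select_on].to_numpy()
    sel = np.isfinite(p) & (p <= threshold) & ~assoc["degenerate"].to_numpy()
    if not sel.any():
        return np.zeros(len(rows))
    B, Q = _validation_features(abund, assoc, rows)
    b1 = np.nan_to_num(assoc["beta1"].to_numpy())
    b2 = np.nan_to_num(assoc["beta2"].to_numpy())
    return B[:, sel] @ b1[sel] + Q[:, sel] @ b2[sel]


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation; 0 when either vector is constant."""
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def cross_validate(
    abund: AbundanceTable,
    pheno: PhenotypeFrame,
    thresholds=DEFAULT_THRESHOLDS,
    n_repeats: int = 100,
    train_fraction: float = 0.8,
    B_inner: int = 0,
    seed: int | None = None,
) -> VarianceExplainedResult:
    """Repeated 80/20 cross-validated variance explained per threshold.

    Each repeat draws a fresh random split, runs the two-part scan on the
    discovery portion (``B_inner`` permutations; 0 = fast mode selecting on
    p_final, the default; >0 selects on the permutation-corrected p), and
    scores R^2 = corr(r_m, residual phenotype)^2 on validation. Repeats
    with empty selections score R^2 = 0 rather than being dropped.
    Deterministic under ``seed``.
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must lie in (0, 1)")
    thresholds = np.sort(np.asarray(thresholds, float))
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie in (0, 1)")
    if pheno.residual is None:
        raise ValueError("phenotype must be residualized first")
    if list(abund.sample_ids) != list(pheno.sample_ids):
        raise ValueError("abundance and phenotype sample ids must align")
    select_on = "p_perm" if B_inner > 0 else "p_final"

    n = abund.n_samples
    n_train = int(round(train_fraction * n))
    if not (0 < n_train < n):
        raise ValueError("train_fraction leaves an empty discovery or validation set")
    rng = np.random.default_rng(seed)
    y = np.asarray(pheno.residual, float)

    r2 = np.zeros((n_repeats, len(thresholds)))
    nsel = np.zeros((n_repeats, len(thresholds)))
    for rep in range(n_repeats):
        perm = rng.permutation(n)
        train, val = perm[:n_train], perm[n_train:]
        ab_train = AbundanceTable(
            [abund.sample_ids[i] for i in train], abund.taxon_ids, abund.fractions[train]
        )
        ph_train = PhenotypeFrame(
            [pheno.sample_ids[i] for i in train],
            pheno.phenotype[train],
            pheno.sex[train],
            pheno.cage[train],
            residual=y[train],
        )
        assoc = two_part_scan(
            ab_train, ph_train, B=B_inner,
            seed=int(rng.integers(2**31 - 1)) if B_inner else None,
        )
        p = assoc[select_on].to_numpy()
        ok = np.isfinite(p) & ~assoc["degenerate"].to_numpy()
        for t_i, thr in enumerate(thresholds):
            sel = ok & (p <= thr)
            nsel[rep, t_i] = sel.sum()
            if sel.any():
                rm = predict_rm(assoc, abund, thr, rows=val, select_on=select_on)
                r2[rep, t_i] = _r2(rm, y[val])

    return VarianceExplainedResult(
        thresholds=thresholds,
        mean_r2=r2.mean(axis=0),
        sd_r2=r2.std(axis=0, ddof=1) if n_repeats > 1 else np.zeros(len(thresholds)),
        mean_n_selected=nsel.mean(axis=0),
        n_repeats=n_repeats,
        train_fraction=train_fraction,
        seed=seed,
        r2_matrix=r2,
    )
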
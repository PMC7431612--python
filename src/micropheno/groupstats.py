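"""High/low group contrasts and SCFA correlation statistics.

The design mirrors extreme-phenotype sampling: the top and bottom n
animals by finishing weight form the high and low groups. Feature tables
(species, CAZyme, GO, KO, pathway abundances) are contrasted by the
Wilcoxon rank-sum test, SCFA concentrations by the two-sided unpaired
t-test, and species-SCFA relationships by Spearman rank correlation — each
with Benjamini-Hochberg FDR correction over its own family.

For the tiny group sizes typical of this design (5 vs 5) the Wilcoxon test
uses the exact null distribution; Spearman p-values are exact (full
permutation enumeration) for n <= 9 without ties and use the
t-approximation otherwise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable, PhenotypeFrame
from .twopart import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "GroupDesign",
    "ScfaTable",
    "select_extremes",
    "wilcoxon_fdr",
    "ttest_fdr",
    "spearman_fdr",
]

ANALYTES = ("acetate", "propionate", "butyrate")


@dataclass
class GroupDesign:
    """High/low extreme-phenotype group membership."""

    high: list[str]
    low: list[str]

    def __post_init__(self) -> None:
        if set(self.high) & set(self.low):
            raise ValueError("high and low groups must be disjoint")

    @property
    def n_per_group(self) -> int:
        return len(self.high)


@dataclass
class ScfaTable:
    """Per-sample fecal SCFA concentrations in mM (positive reals)."""

    sample_ids: list[str]
    acetate: np.ndarray
    propionate: np.ndarray
    butyrate: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for name in ANALYTES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per sample")
            if np.any(arr < 0):
                raise ValueError(f"negative {name} concentration")
            setattr(self, name, arr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {name: getattr(self, name) for name in ANALYTES}, index=self.sample_ids
        )


def select_extremes(pheno: PhenotypeFrame, n_per_group: int = 5) -> GroupDesign:
    """Top/bottom ``n_per_group`` samples by phenotype.

    Boundary ties are broken by sample id order (deterministic, logged).
    """
    n = pheno.n_samples
    if 2 * n_per_group > n:
        raise ValueError("2 * n_per_group exceeds the number of samples")
    order = sorted(range(n), key=lambda i: (pheno.phenotype[i], pheno.sample_ids[i]))
    values = np.asarray(pheno.phenotype, float)
    svals = values[order]
    for cut in (n_per_group - 1, n - n_per_group):
        if 0 < cut < n and svals[cut] == svals[cut - 1]:
            logger.info("phenotype tie at a group boundary; broken by sample id order")
    low = [pheno.sample_ids[i] for i in order[:n_per_group]]
    high = [pheno.sample_ids[i] for i in order[-n_per_group:]]
    return GroupDesign(high=high, low=low)


def _group_rows(sample_ids: list[str], design: GroupDesign) -> tuple[list[int], list[int]]:
    pos = {s: i for i, s in enumerate(sample_ids)}
    missing = [s for s in design.high + design.low if s not in pos]
    if missing:
        raise ValueError(f"samples in design absent from table: {missing}")
    return [pos[s] for s in design.high], [pos[s] for s in design.low]


def _mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact null for combined n <= 20 without
    ties, normal approximation with tie correction otherwise."""
    exact = (len(x) + len(y) <= 20) and (len(np.unique(np.concatenate([x, y]))) == len(x) + len(y))
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def wilcoxon_fdr(features: AbundanceTable, design: GroupDesign) -> pd.DataFrame:
    """Wilcoxon rank-sum contrast of every feature between high and low.

    Returns per feature: W (U statistic of the high group), p, BH q across
    features, and direction (the group with the higher median; 'equal' on
    a tie).
    """
    hi, lo = _group_rows(features.sample_ids, design)
    rows = []
    for j, taxon in enumerate(features.taxon_ids):
        x, y = features.fractions[hi, j], features.fractions[lo, j]
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            w, p = float(len(x) * len(y) / 2), 1.0
        else:
            w, p = _mwu(x, y)
        mx, my = np.median(x), np.median(y)
        direction = "high" if mx > my else ("low" if my > mx else "equal")
        rows.append({"feature": taxon, "W": w, "p": p, "direction": direction})
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df[["feature", "W", "p", "q", "direction"]]


def ttest_fdr(
    scfa: ScfaTable, design: GroupDesign, equal_var: bool = True
) -> pd.DataFrame:
    """Two-sided unpaired t-test of each SCFA between high and low groups.

    Classical equal-variance Student's t by default (``equal_var=False``
    gives Welch); BH correction across the analytes.
    """
    hi, lo = _group_rows(scfa.sample_ids, design)
    rows = []
    for name in ANALYTES:
        v = getattr(scfa, name)
        x, y = v[hi], v[lo]
        if np.all(np.concatenate([x, y]) == x[0]):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(x, y, equal_var=equal_var)
        rows.append({"analyte": name, "t": float(t), "p": float(p)})
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df


@lru_cache(maxsize=8)
def _exact_spearman_null(n: int) -> np.ndarray:
    """Null distribution of |rho| over all n! rank permutations (no ties)."""
    r = np.arange(1, n + 1, dtype=float)
    rc = r - r.mean()
    denom = (rc**2).sum()
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (rc[perms] * rc).sum(axis=1) / denom
    return np.abs(rhos)


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Average-rank Spearman rho with exact p for n <= 9 (no ties)."""
    n = len(x)
    rho, p_approx = stats.spearmanr(x, y)
    if not np.isfinite(rho):
        return float("nan"), float("nan")
    no_ties = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n <= 9 and no_ties:
        null = _exact_spearman_null(n)
        p = float(np.mean(null >= abs(rho) - 1e-12))
        return float(rho), p
    return float(rho), float(p_approx)


def spearman_fdr(features: AbundanceTable, scfa: ScfaTable) -> pd.DataFrame:
    """Spearman correlation of every feature with every SCFA analyte.

    BH correction runs jointly across all feature x analyte pairs; the
    long-format result backs a correlation heat map (feature rows, analyte
    columns).
    """
    if list(features.sample_ids) != list(scfa.sample_ids):
        pos = {s: i for i, s in enumerate(scfa.sample_ids)}
        if set(features.sample_ids) != set(scfa.sample_ids):
            raise ValueError("feature and SCFA tables cover different samples")
        idx = [pos[s] for s in features.sample_ids]
        scfa = ScfaTable(
            [scfa.sample_ids[i] for i in idx],
            scfa.acetate[idx],
            scfa.propionate[idx],
            scfa.butyrate[idx],
        )
    rows = []
    for j, taxon in enumerate(features.taxon_ids):
        for name in ANALYTES:
            rho, p = _spearman(features.fractions[:, j], getattr(scfa, name))
            rows.append({"feature": taxon, "analyte": name, "rho": rho, "p": p})
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df
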
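"""Count-table containers, I/O, and preprocessing.

Tables are tab-delimited text: header row of taxon (or column) names, first
column holds sample identifiers. Preprocessing mirrors a standard 16S
workflow: rarefaction to a common depth, closure to relative abundances,
low-abundance / low-prevalence taxon filtering, and residualization of the
phenotype on categorical covariates (sex, cage) before association testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountTable",
    "AbundanceTable",
    "PhenotypeFrame",
    "FilterReport",
    "read_count_table",
    "write_count_table",
    "read_phenotype",
    "write_phenotype",
    "to_relative",
    "filter_taxa",
    "rarefy",
    "residualize",
]


def _check_ids(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")


@dataclass
class CountTable:
    """Samples x taxa matrix of non-negative integer counts."""

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.taxon_ids = list(map(str, self.taxon_ids))
        _check_ids(self.sample_ids, "sample")
        _check_ids(self.taxon_ids, "taxon")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.mod(self.counts, 1) == 0):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)


@dataclass
class AbundanceTable:
    """Samples x taxa matrix of relative abundances; rows sum to one."""

    sample_ids: list[str]
    taxon_ids: list[str]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.taxon_ids = list(map(str, self.taxon_ids))
        _check_ids(self.sample_ids, "sample")
        _check_ids(self.taxon_ids, "taxon")
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError("fraction matrix shape does not match id lists")
        if np.any(self.fractions < 0) or np.any(self.fractions > 1):
            raise ValueError("fractions must lie in [0, 1]")
        sums = self.fractions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each sample's fractions must sum to 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fractions, index=self.sample_ids, columns=self.taxon_ids
        )


@dataclass
class PhenotypeFrame:
    """Per-sample phenotype (finishing weight, g) with sex/cage covariates.

    ``residual`` holds the phenotype after removal of sex and cage fixed
    effects (filled by :func:`residualize`); association tests downstream
    operate on the residual.
    """

    sample_ids: list[str]
    phenotype: np.ndarray
    sex: np.ndarray
    cage: np.ndarray
    residual: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        _check_ids(self.sample_ids, "sample")
        n = len(self.sample_ids)
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        self.sex = np.asarray(self.sex)
        self.cage = np.asarray(self.cage)
        for name, arr in (("phenotype", self.phenotype), ("sex", self.sex), ("cage", self.cage)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per sample")
        if self.residual is not None:
            self.residual = np.asarray(self.residual, dtype=float)
            if self.residual.shape != (n,):
                raise ValueError("residual must have one entry per sample")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        d = {"phenotype": self.phenotype, "sex": self.sex, "cage": self.cage}
        if self.residual is not None:
            d["residual"] = self.residual
        return pd.DataFrame(d, index=self.sample_ids)


@dataclass
class FilterReport:
    kept: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)
    min_mean_abundance: float = 0.0
    min_prevalence: float = 0.0

    def to_dict(self) -> dict:
        return {
            "kept": self.kept,
            "dropped": self.dropped,
            "min_mean_abundance": self.min_mean_abundance,
            "min_prevalence": self.min_prevalence,
        }


# ---------------------------------------------------------------------------
# I/O


def read_count_table(path) -> CountTable:
    """Read a tab-delimited count table (header = taxa, first column = samples).

    Raises ``ValueError`` naming the offending cell for negative or
    non-integer entries.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    bad = ~np.isfinite(values.astype(float)) | (values.astype(float) % 1 != 0) | (values.astype(float) < 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid count {values[i, j]!r} at sample {df.index[i]!r}, "
            f"taxon {df.columns[j]!r}"
        )
    return CountTable(list(df.index), list(df.columns), values.astype(np.int64))


def write_count_table(table: CountTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_phenotype(path) -> PhenotypeFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    residual = df["residual"].to_numpy() if "residual" in df.columns else None
    return PhenotypeFrame(
        list(df.index),
        df["phenotype"].to_numpy(),
        df["sex"].astype(str).to_numpy(),
        df["cage"].astype(str).to_numpy(),
        residual=residual,
    )


def write_phenotype(pheno: PhenotypeFrame, path) -> None:
    pheno.to_frame().to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Preprocessing


def to_relative(table: CountTable) -> AbundanceTable:
    """Row-wise closure of counts to relative abundances.

    A sample with zero total counts cannot be closed and raises
    ``ValueError``.
    """
    totals = table.library_sizes
    if np.any(totals == 0):
        bad = [table.sample_ids[i] for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"samples with zero total counts cannot be closed: {bad}")
    return AbundanceTable(
        table.sample_ids, table.taxon_ids, table.counts / totals[:, None]
    )


def filter_taxa(
    table: AbundanceTable,
    min_mean_abundance: float = 0.001,
    min_prevalence: float = 0.01,
    abundance_stat: str = "mean",
) -> tuple[AbundanceTable, FilterReport]:
    """Drop rare taxa: mean relative abundance < 0.1% or prevalence < 1%.

    Presence is a strictly positive fraction; the prevalence rule requires
    presence in at least ``ceil(min_prevalence * n_samples)`` samples.
    ``abundance_stat`` selects mean (default) or max relative abundance as
    the abundance screen. The sample set is unchanged; after dropping taxa
    the rows are re-closed so fractions again sum to one.
    """
    if abundance_stat not in ("mean", "max"):
        raise ValueError("abundance_stat must be 'mean' or 'max'")
    stat = table.fractions.mean(axis=0) if abundance_stat == "mean" else table.fractions.max(axis=0)
    n_present = (table.fractions > 0).sum(axis=0)
    need = int(np.ceil(min_prevalence * table.n_samples))
    keep = (stat >= min_mean_abundance) & (n_present >= max(need, 1))
    report = FilterReport(
        kept=[t for t, k in zip(table.taxon_ids, keep) if k],
        dropped=[t for t, k in zip(table.taxon_ids, keep) if not k],
        min_mean_abundance=min_mean_abundance,
        min_prevalence=min_prevalence,
    )
    if not keep.any():
        warnings.warn("all taxa removed by filtering", stacklevel=2)
        return AbundanceTable(table.sample_ids, [], np.zeros((table.n_samples, 0))), report
    frac = table.fractions[:, keep]
    frac = frac / frac.sum(axis=1, keepdims=True)
    return AbundanceTable(table.sample_ids, report.kept, frac), report


def rarefy(table: CountTable, depth: int, seed: int | None = None) -> CountTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples whose library size is below ``depth`` are dropped with a logged
    warning. Subsampling is multivariate hypergeometric (read subsampling
    semantics), deterministic under ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    sizes = table.library_sizes
    keep = sizes >= depth
    if not keep.all():
        dropped = [table.sample_ids[i] for i in np.flatnonzero(~keep)]
        logger.warning(
            "dropping %d sample(s) below rarefaction depth %d: %s",
            len(dropped), depth, dropped,
        )
    rows = []
    for i in np.flatnonzero(keep):
        row = table.counts[i]
        if sizes[i] == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    kept_ids = [table.sample_ids[i] for i in np.flatnonzero(keep)]
    return CountTable(kept_ids, table.taxon_ids, np.array(rows, dtype=np.int64))


def residualize(pheno: PhenotypeFrame) -> PhenotypeFrame:
    """Remove sex and cage fixed effects from the phenotype by OLS.

    Sex and cage enter as categorical indicators; the fit uses the
    pseudo-inverse, so rank-deficient designs (e.g. a cage nested in one
    sex) are handled. A categorical level observed once absorbs its own
    residual to zero, which is logged.
    """
    sex = pd.Series(pheno.sex, dtype="category")
    cage = pd.Series(pheno.cage, dtype="category")
    for name, s in (("sex", sex), ("cage", cage)):
        singletons = s.value_counts()
        lonely = singletons[singletons == 1]
        if len(lonely):
            logger.warning(
                "%s level(s) with a single observation absorb their residual: %s",
                name, list(lonely.index),
            )
    X = np.column_stack(
        [np.ones(pheno.n_samples)]
        + [pd.get_dummies(s, drop_first=True).to_numpy(dtype=float) for s in (sex, cage)]
    )
    beta = np.linalg.pinv(X) @ pheno.phenotype
    residual = pheno.phenotype - X @ beta
    return replace(pheno, residual=residual)
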
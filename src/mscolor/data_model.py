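"""Core data containers shared by the solver, baselines and evaluation harness.

A longitudinal imaging-genetics study is represented as an ordered list of
*stages*.  Each stage is a contiguous window of visits modeled with its own
intercept/slope pair, which lets a multi-phase disease trajectory deviate from
a single monotone line.  A stage holds an aligned genotype matrix (subjects x
SNPs, standardized minor-allele dosages), a tensor of imaging quantitative
traits (QTs) with one slice per visit, and the visit times in months.

Subjects may appear in several stages; population aging effects are indexed by
a *subject registry* (the union of subject ids) so that models with shared
aging parameters can select the rows present in each stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StageData",
    "LongitudinalDataset",
    "Standardization",
    "standardize",
    "residualize_covariates",
    "DatasetScalers",
    "fit_dataset_scalers",
    "apply_dataset_scalers",
]


class Standardization(NamedTuple):
    """Result of column standardization (z-scoring with ``ddof=1``)."""

    values: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    kept: np.ndarray  # column indices retained (all, unless drop_constant)

    def transform(self, other: np.ndarray) -> np.ndarray:
        other = np.asarray(other, dtype=float)
        return (other[:, self.kept] - self.mean) / self.scale

    def inverse(self, values: np.ndarray | None = None) -> np.ndarray:
        if values is None:
            values = self.values
        return values * self.scale + self.mean


def standardize(matrix: np.ndarray, *, drop_constant: bool = False) -> Standardization:
    """Column-standardize ``matrix`` to mean 0 and unit sample sd (n-1 denominator).

    Parameters
    ----------
    matrix
        Real matrix with at least two rows.
    drop_constant
        If True, zero-variance columns are dropped (their indices are absent
        from ``kept``); otherwise such a column raises ``ValueError`` naming it.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 2:
        raise ValueError("standardize requires at least 2 rows")
    mean = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    zero = scale == 0
    if zero.any():
        if not drop_constant:
            idx = int(np.flatnonzero(zero)[0])
            raise ValueError(
                f"column {idx} has zero variance; pass drop_constant=True to drop it"
            )
        kept = np.flatnonzero(~zero)
    else:
        kept = np.arange(x.shape[1])
    mean = mean[kept]
    scale = scale[kept]
    values = (x[:, kept] - mean) / scale
    return Standardization(values, mean, scale, kept)


def residualize_covariates(
    qts: pd.DataFrame, covariates: pd.DataFrame, names: Sequence[str]
) -> pd.DataFrame:
    """Replace each QT column by its OLS residual on the named covariates.

    The design matrix is an intercept plus ``covariates[names]`` aligned to the
    index of ``qts``.  Residuals are orthogonal to every covariate column,
    which removes confounding by e.g. gender, education or handedness before
    genetic modeling.

    Raises
    ------
    ValueError
        If any subject lacks covariates or the design matrix is rank deficient.
    """
    missing = qts.index.difference(covariates.index)
    if len(missing):
        raise ValueError(f"covariates missing for subjects: {list(missing)[:5]}")
    cov = covariates.loc[qts.index, list(names)].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(qts)), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate design matrix is rank deficient")
    y = qts.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return pd.DataFrame(resid, index=qts.index, columns=qts.columns)


@dataclass
class StageData:
    """One disease stage: aligned genotypes, QT tensor over visits, and times.

    Attributes
    ----------
    stage_index : int
        1-based position of this stage in the trajectory.
    subject_ids : list of str
    genotype : (n_s, d) ndarray
        Standardized minor-allele dosages.
    qts : (m, n_s, c) ndarray
        One slice per visit time.
    times : (m,) ndarray
        Visit times in months (stage-local by convention: first visit at 0).
    qt_names, snp_ids : lists of str
    """

    stage_index: int
    subject_ids: list[str]
    genotype: np.ndarray
    qts: np.ndarray
    times: np.ndarray
    qt_names: list[str]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype, dtype=float)
        self.qts = np.asarray(self.qts, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        n = len(self.subject_ids)
        m = len(self.times)
        c = len(self.qt_names)
        if self.genotype.shape[0] != n:
            raise ValueError("genotype row count != number of subjects")
        if self.genotype.shape[1] != len(self.snp_ids):
            raise ValueError("genotype column count != number of snp_ids")
        if self.qts.shape != (m, n, c):
            raise ValueError(
                f"qts must have shape (m, n, c)=({m}, {n}, {c}); got {self.qts.shape}"
            )
        if m > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("visit times must be strictly increasing")
        if not (np.isfinite(self.genotype).all() and np.isfinite(self.qts).all()):
            raise ValueError("missing/non-finite values must be resolved upstream")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_visits(self) -> int:
        return len(self.times)

    def subset(self, subject_ids: Sequence[str]) -> "StageData":
        """Row-subset to ``subject_ids`` (kept in this stage's row order)."""
        keep = set(subject_ids)
        idx = [i for i, s in enumerate(self.subject_ids) if s in keep]
        return replace(
            self,
            subject_ids=[self.subject_ids[i] for i in idx],
            genotype=self.genotype[idx],
            qts=self.qts[:, idx, :],
        )


@dataclass
class LongitudinalDataset:
    """Ordered stages plus the subject registry and optional covariate table."""

    stages: list[StageData]
    covariates: pd.DataFrame | None = None
    registry: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("at least one stage is required")
        ref = self.stages[0].snp_ids
        for st in self.stages[1:]:
            if st.snp_ids != ref:
                raise ValueError("snp_ids must be identical and identically ordered across stages")
        # sorted union -> registry order independent of stage row order
        self.registry = sorted({s for st in self.stages for s in st.subject_ids})

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def snp_ids(self) -> list[str]:
        return self.stages[0].snp_ids

    @property
    def qt_names(self) -> list[str]:
        return self.stages[0].qt_names

    def registry_rows(self, stage: StageData) -> np.ndarray:
        """Indices into the registry for the subjects of ``stage``."""
        pos = {s: i for i, s in enumerate(self.registry)}
        return np.array([pos[s] for s in stage.subject_ids], dtype=int)

    def presence(self) -> pd.DataFrame:
        """Boolean registry x stage table of subject availability."""
        table = pd.DataFrame(
            False, index=self.registry, columns=[st.stage_index for st in self.stages]
        )
        for st in self.stages:
            table.loc[st.subject_ids, st.stage_index] = True
        return table

    def subset(self, subject_ids: Sequence[str]) -> "LongitudinalDataset":
        stages = [st.subset(subject_ids) for st in self.stages]
        stages = [st for st in stages if st.n_subjects > 0]
        cov = None
        if self.covariates is not None:
            keep = [s for s in self.covariates.index if s in set(subject_ids)]
            cov = self.covariates.loc[keep]
        return LongitudinalDataset(stages=stages, covariates=cov)


class DatasetScalers(NamedTuple):
    """Standardization parameters fit on a training subset.

    QT scaling is global (one mean/sd per QT pooled over stages and visits);
    genotype scaling is per SNP over the union of training subjects.
    """

    qt_mean: np.ndarray
    qt_scale: np.ndarray
    geno_mean: np.ndarray
    geno_scale: np.ndarray


def fit_dataset_scalers(data: LongitudinalDataset) -> DatasetScalers:
    qt_rows = np.concatenate(
        [st.qts.reshape(-1, len(st.qt_names)) for st in data.stages], axis=0
    )
    qt_mean = qt_rows.mean(axis=0)
    qt_scale = qt_rows.std(axis=0, ddof=1)
    # one genotype row per unique subject
    seen: dict[str, np.ndarray] = {}
    for st in data.stages:
        for i, s in enumerate(st.subject_ids):
            seen.setdefault(s, st.genotype[i])
    geno = np.array([seen[s] for s in sorted(seen)])
    geno_mean = geno.mean(axis=0)
    geno_scale = geno.std(axis=0, ddof=1)
    if (qt_scale == 0).any() or (geno_scale == 0).any():
        raise ValueError("zero-variance QT or SNP in the training data")
    return DatasetScalers(qt_mean, qt_scale, geno_mean, geno_scale)


def apply_dataset_scalers(
    data: LongitudinalDataset, scalers: DatasetScalers
) -> LongitudinalDataset:
    stages = [
        replace(
            st,
            genotype=(st.genotype - scalers.geno_mean) / scalers.geno_scale,
            qts=(st.qts - scalers.qt_mean) / scalers.qt_scale,
        )
        for st in data.stages
    ]
    return LongitudinalDataset(stages=stages, covariates=data.covariates)
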
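"""GWAS summary statistics, reference-panel LD, and joint-effect transforms.

A genome-wide association study reports, for each SNP g and phenotype y, the
marginal effect size beta_g = x_g' y / (n - 1) on standardized data.  The
multivariate (joint) effects solve Sigma_XX u = beta, where Sigma_XX is the
SNP correlation matrix.  Individual-level GWAS genotypes are rarely available,
so Sigma_XX is estimated from a reference panel of the same ancestry.  These
quantities let the longitudinal solver borrow power from cohorts orders of
magnitude larger than any longitudinal imaging study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .data_model import standardize

__all__ = [
    "GwasSummary",
    "LdPanel",
    "HarmonizedSummary",
    "marginal_effects",
    "estimate_ld",
    "joint_effects",
    "harmonize",
]

_VALID_ALLELES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class GwasSummary:
    """Per-SNP marginal effect sizes with allele metadata and cohort size."""

    snp_ids: list[str]
    effect_allele: list[str]
    other_allele: list[str]
    beta: np.ndarray
    n_gwas: int

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        d = len(self.snp_ids)
        if d == 0:
            raise ValueError("summary statistics are empty")
        if not (len(self.effect_allele) == len(self.other_allele) == len(self.beta) == d):
            raise ValueError("summary fields have inconsistent lengths")
        if not np.isfinite(self.beta).all():
            raise ValueError("beta contains non-finite values")
        for a in (*self.effect_allele, *self.other_allele):
            if a not in _VALID_ALLELES:
                raise ValueError(f"invalid allele code {a!r}")


@dataclass
class LdPanel:
    """Reference-panel SNP correlation matrix (the scaled covariance Sigma_XX)."""

    snp_ids: list[str]
    sigma: np.ndarray
    n_ref: int
    effect_allele: list[str] | None = None
    other_allele: list[str] | None = None

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        d = len(self.snp_ids)
        if self.sigma.shape != (d, d):
            raise ValueError("sigma must be d x d")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        if (np.diag(self.sigma) <= 0).any():
            raise ValueError("sigma diagonal must be positive")


@dataclass
class HarmonizedSummary:
    """Summary statistics and LD restricted to a target SNP set, sign-aligned.

    ``beta`` and ``sigma`` share the target's SNP ordering; ``flip_count`` and
    ``drop_count`` record how many SNPs were sign-flipped or discarded.
    """

    snp_ids: list[str]
    effect_allele: list[str]
    other_allele: list[str]
    beta: np.ndarray
    sigma: np.ndarray
    n_gwas: int
    n_ref: int
    flip_count: int = 0
    drop_count: int = 0


def marginal_effects(x_g: np.ndarray, y_p: np.ndarray) -> float:
    """Marginal effect size beta = x' y / (n - 1) for standardized vectors.

    Both inputs must already be z-scored (mean 0, sample sd 1); the result is
    then the sample correlation and lies in [-1, 1].
    """
    x = np.asarray(x_g, dtype=float).ravel()
    y = np.asarray(y_p, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x_g and y_p must have the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    return float(x @ y / (len(x) - 1))


def estimate_ld(
    panel: np.ndarray,
    snp_ids: list[str] | None = None,
    *,
    effect_allele: list[str] | None = None,
    other_allele: list[str] | None = None,
) -> LdPanel:
    """Estimate the SNP correlation matrix from a reference genotype matrix.

    Columns are standardized internally; monomorphic SNPs are dropped with a
    warning.  The result has a unit diagonal.
    """
    x = np.asarray(panel, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("reference panel needs at least 2 subjects")
    d = x.shape[1]
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(d)]
    std = standardize(x, drop_constant=True)
    if len(std.kept) < d:
        dropped = [snp_ids[i] for i in range(d) if i not in set(std.kept)]
        warnings.warn(f"dropping {len(dropped)} monomorphic SNP(s): {dropped[:5]}")
    kept = list(std.kept)
    z = std.values
    sigma = z.T @ z / (x.shape[0] - 1)
    # exact symmetry / unit diagonal despite float round-off
    sigma = (sigma + sigma.T) / 2.0
    np.fill_diagonal(sigma, 1.0)
    return LdPanel(
        snp_ids=[snp_ids[i] for i in kept],
        sigma=sigma,
        n_ref=x.shape[0],
        effect_allele=[effect_allele[i] for i in kept] if effect_allele else None,
        other_allele=[other_allele[i] for i in kept] if other_allele else None,
    )


def joint_effects(beta: np.ndarray, sigma: np.ndarray, ridge: float = 1e-3) -> np.ndarray:
    """Solve (sigma + ridge*I) u = beta for the joint SNP effects.

    ``ridge`` (default 1e-3) keeps the system invertible when the reference
    panel has fewer subjects than SNPs.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    sigma = np.asarray(sigma, dtype=float)
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    m = sigma + ridge * np.eye(len(beta)) if ridge > 0 else sigma
    try:
        u = scipy.linalg.solve(m, beta, assume_a="sym")
    except scipy.linalg.LinAlgError as err:  # pragma: no cover - degenerate input
        raise np.linalg.LinAlgError(
            "LD system is singular; increase the ridge parameter"
        ) from err
    if not np.isfinite(u).all():
        raise np.linalg.LinAlgError(
            "joint effects are non-finite; increase the ridge parameter"
        )
    return u


def harmonize(
    summary: GwasSummary,
    panel: LdPanel,
    target_snp_ids: list[str],
    target_alleles: pd.DataFrame,
    *,
    drop_ambiguous: bool = True,
) -> HarmonizedSummary:
    """Align summary statistics and LD to the target genotype's SNPs/alleles.

    For each target SNP present in both sources, beta is sign-flipped when the
    summary's effect allele is the target's other allele, and the LD matrix
    rows/columns are flipped likewise when the panel carries allele metadata.
    Strand-ambiguous SNPs (A/T, C/G) are dropped by default because their
    orientation cannot be resolved without strand information.

    Parameters
    ----------
    target_alleles
        DataFrame indexed by snp_id with columns ``a1`` (effect) and ``a2``.
    """
    s_idx = {s: i for i, s in enumerate(summary.snp_ids)}
    p_idx = {s: i for i, s in enumerate(panel.snp_ids)}

    keep_t: list[int] = []
    keep_s: list[int] = []
    keep_p: list[int] = []
    beta_sign: list[float] = []
    ld_sign: list[float] = []
    flip_count = 0
    drop_count = 0

    def _orientation(a1: str, a2: str, t1: str, t2: str) -> float | None:
        if (a1, a2) == (t1, t2):
            return 1.0
        if (a1, a2) == (t2, t1):
            return -1.0
        return None

    for ti, snp in enumerate(target_snp_ids):
        if snp not in s_idx or snp not in p_idx:
            continue
        t1 = str(target_alleles.loc[snp, "a1"]).upper()
        t2 = str(target_alleles.loc[snp, "a2"]).upper()
        if drop_ambiguous and (t1, t2) in _AMBIGUOUS_PAIRS:
            drop_count += 1
            continue
        si = s_idx[snp]
        sgn = _orientation(summary.effect_allele[si], summary.other_allele[si], t1, t2)
        if sgn is None:
            drop_count += 1
            continue
        pi = p_idx[snp]
        if panel.effect_allele is not None and panel.other_allele is not None:
            psgn = _orientation(panel.effect_allele[pi], panel.other_allele[pi], t1, t2)
            if psgn is None:
                drop_count += 1
                continue
        else:
            psgn = 1.0
        if sgn < 0:
            flip_count += 1
        keep_t.append(ti)
        keep_s.append(si)
        keep_p.append(pi)
        beta_sign.append(sgn)
        ld_sign.append(psgn)

    if not keep_t:
        raise ValueError("no SNPs shared between summary, panel and target")

    beta = summary.beta[keep_s] * np.array(beta_sign)
    flips = np.array(ld_sign)
    sigma = panel.sigma[np.ix_(keep_p, keep_p)] * np.outer(flips, flips)
    snps = [target_snp_ids[i] for i in keep_t]
    return HarmonizedSummary(
        snp_ids=snps,
        effect_allele=[str(target_alleles.loc[s, "a1"]).upper() for s in snps],
        other_allele=[str(target_alleles.loc[s, "a2"]).upper() for s in snps],
        beta=beta,
        sigma=sigma,
        n_gwas=summary.n_gwas,
        n_ref=panel.n_ref,
        flip_count=flip_count,
        drop_count=drop_count,
    )
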
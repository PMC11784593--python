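"""Synthetic multi-stage imaging-genetics cohorts with known ground truth.

The generator emulates the data a staged neurodegeneration study collects:

* a longitudinal cohort observed in ``L`` overlapping stage windows (visits
  every six months by default), with per-subject aging intercepts/slopes,
  row-sparse genetic effects on both the baseline level and the rate of
  change of ``c`` imaging QTs, and stage-varying slope magnitudes following
  the classic three-phase pattern (subtle early change, rapid middle stage,
  slower late stage);
* a much larger independent GWAS cohort phenotyped on a composite of the same
  genetic effects, from which per-SNP marginal effect sizes are computed; and
* a reference genotype panel for LD estimation.

Everything is driven by a single seed, and the generating parameters are
returned in a :class:`SimTruth` for recovery scoring.  SNPs are independent
by default (draws are binomial dosages per SNP); an AR(1) correlation option
adds simple short-range LD but no haplotype structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_model import LongitudinalDataset, StageData, standardize
from .gwas import GwasSummary, HarmonizedSummary, LdPanel, estimate_ld

__all__ = ["SimConfig", "SimTruth", "simulate_genotypes", "simulate_multistage",
           "simulate_gwas", "simulate_study", "SimulatedStudy"]

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                 ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]


@dataclass
class SimConfig:
    """Generator settings.  Defaults describe the reference study conditions.

    Notes on units: visit times are months; slope-type parameters
    (``slope_effect_sd``, ``aging_slope_sd``) are per month, so over a
     12-month window the default genetic slope effects move a QT by about
    0.6 standardized units per causal allele at the fastest stage.
    """

    n_per_stage: list[int] = field(default_factory=lambda: [200, 200, 200])
    d: int = 100
    c: int = 4
    m: int = 3
    n_causal: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_sd: float = 0.3          # genetic intercept effects, per sd of dosage
    slope_effect_sd: float = 0.05   # genetic slope effects, per month
    stage_slope_profile: list[float] = field(default_factory=lambda: [1.0, 1.8, 0.7])
    aging_intercept_sd: float = 1.0
    aging_slope_mean: float = -0.05  # per month: normal aging is a decline
    aging_slope_sd: float = 0.05    # per month
    noise_sd: float = 0.5
    overlap_fraction: float = 1.0
    n_gwas: int = 20000
    n_ref: int = 2000
    gwas_h2: float = 0.3
    gamma_true: float = 0.5
    visit_interval: float = 6.0     # months between visits and between stage starts
    ar1_rho: float = 0.0            # optional AR(1) LD between adjacent SNPs
    seed: int = 0

    def __post_init__(self) -> None:
        L = len(self.n_per_stage)
        if len(self.stage_slope_profile) != L:
            raise ValueError("stage_slope_profile length must equal the number of stages")
        if not 0 < self.n_causal <= self.d:
            raise ValueError("n_causal must be in 1..d")
        low, high = self.maf_range
        if not (0 < low <= high <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if not 0.0 <= self.gwas_h2 < 1.0:
            raise ValueError("gwas_h2 must lie in [0, 1)")
        for name in ("effect_sd", "slope_effect_sd", "aging_intercept_sd",
                     "aging_slope_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_stages(self) -> int:
        return len(self.n_per_stage)

    def stage_offsets(self) -> list[float]:
        """Global start month of each stage window (consecutive windows overlap)."""
        return [self.visit_interval * s for s in range(self.n_stages)]


@dataclass
class SimTruth:
    """Generating parameters and causal support, for recovery scoring."""

    true_A: pd.DataFrame
    true_B: pd.DataFrame
    true_W: list[np.ndarray]
    true_V: list[np.ndarray]
    true_u: np.ndarray
    causal_support: np.ndarray
    noise_sd: float
    gamma: float
    config_echo: dict

    def __post_init__(self) -> None:
        if self.causal_support.sum() == 0:
            raise ValueError("causal support must be nonempty")
        nz = np.zeros_like(self.causal_support)
        for w in (*self.true_W, *self.true_V):
            nz |= np.abs(w).max(axis=1) > 0
        if (nz & ~self.causal_support).any():
            raise ValueError("nonzero effect rows outside the causal support")


def simulate_genotypes(
    n: int, d: int, maf_range: tuple[float, float], seed: int,
    *, ar1_rho: float = 0.0, avoid_ambiguous: bool = True,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Draw an (n, d) dosage matrix in {0,1,2} plus allele metadata.

    Per-SNP minor-allele frequencies are uniform in ``maf_range``; dosages are
    Binomial(2, MAF).  With ``ar1_rho``>0, adjacent SNPs are correlated via a
    shared latent Gaussian (AR(1)) thresholded at the MAF quantiles.
    Monomorphic columns are redrawn.  Returns (dosages, allele table, mafs).
    """
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(*maf_range, size=d)
    if ar1_rho > 0:
        geno = np.empty((n, d))
        for hap in range(2):  # two independent haplotypes per subject
            z = np.empty((n, d))
            z[:, 0] = rng.standard_normal(n)
            for j in range(1, d):
                z[:, j] = ar1_rho * z[:, j - 1] + np.sqrt(1 - ar1_rho**2) * rng.standard_normal(n)
            from scipy.stats import norm
            thresh = norm.ppf(mafs)
            carriers = z < thresh
            geno = carriers.astype(float) if hap == 0 else geno + carriers
    else:
        geno = rng.binomial(2, mafs, size=(n, d)).astype(float)
    for j in range(d):
        tries = 0
        while geno[:, j].std() == 0:
            geno[:, j] = rng.binomial(2, mafs[j], size=n)
            tries += 1
            if tries > 100:  # pragma: no cover - MAF bounded away from 0
                raise RuntimeError("could not draw a polymorphic column")
    pairs = _ALLELE_PAIRS if avoid_ambiguous else _ALLELE_PAIRS + [("A", "T"), ("C", "G")]
    pick = rng.integers(0, len(pairs), size=d)
    alleles = pd.DataFrame(
        {"a1": [pairs[i][0] for i in pick], "a2": [pairs[i][1] for i in pick]},
        index=[f"rs{j:05d}" for j in range(d)],
    )
    return geno, alleles, mafs


def _stage_subjects(cfg: SimConfig) -> list[list[str]]:
    """Subject id lists per stage; consecutive stages share overlap_fraction."""
    ids: list[list[str]] = []
    next_id = 0
    for s, n_s in enumerate(cfg.n_per_stage):
        if s == 0:
            cur = [f"S{next_id + i:05d}" for i in range(n_s)]
            next_id += n_s
        else:
            n_keep = int(round(cfg.overlap_fraction * min(n_s, len(ids[-1]))))
            cur = ids[-1][:n_keep]
            n_new = n_s - n_keep
            cur = cur + [f"S{next_id + i:05d}" for i in range(n_new)]
            next_id += n_new
        ids.append(cur)
    return ids


def simulate_multistage(cfg: SimConfig) -> tuple[LongitudinalDataset, SimTruth]:
    """Generate the longitudinal cohort.

    For stage s with stage-local visit times t the QT slice at time t is

        Z = gamma*(X W*_s + X V*_s t) + (1-gamma)*(A* + B* t) + N(0, noise_sd),

    with X the registry-standardized dosages, W*_s row-sparse on the causal
    support (stage-invariant in the default design), V*_s = V_base scaled by
    the stage slope profile, and per-subject aging effects A*, B* shared
    across the stages a subject appears in.
    """
    rng = np.random.default_rng(cfg.seed)
    stage_ids = _stage_subjects(cfg)
    registry = sorted({s for ids in stage_ids for s in ids})
    N = len(registry)
    pos = {s: i for i, s in enumerate(registry)}

    geno_raw, alleles, mafs = simulate_genotypes(
        N, cfg.d, cfg.maf_range, int(rng.integers(1 << 31)), ar1_rho=cfg.ar1_rho
    )
    snp_ids = list(alleles.index)
    qt_names = [f"QT{j + 1}" for j in range(cfg.c)]
    geno_std = standardize(geno_raw).values

    support = np.zeros(cfg.d, dtype=bool)
    support[rng.choice(cfg.d, size=cfg.n_causal, replace=False)] = True

    W_base = np.zeros((cfg.d, cfg.c))
    V_base = np.zeros((cfg.d, cfg.c))
    W_base[support] = rng.standard_normal((cfg.n_causal, cfg.c)) * cfg.effect_sd
    V_base[support] = rng.standard_normal((cfg.n_causal, cfg.c)) * cfg.slope_effect_sd
    true_W = [W_base.copy() for _ in range(cfg.n_stages)]
    true_V = [V_base * prof for prof in cfg.stage_slope_profile]

    A_star = rng.standard_normal((N, cfg.c)) * cfg.aging_intercept_sd
    B_star = cfg.aging_slope_mean + rng.standard_normal((N, cfg.c)) * cfg.aging_slope_sd

    g = cfg.gamma_true
    times = np.arange(cfg.m) * cfg.visit_interval
    stages = []
    for s, ids in enumerate(stage_ids):
        rows = np.array([pos[i] for i in ids])
        x = geno_std[rows]
        xw = x @ true_W[s]
        xv = x @ true_V[s]
        z = np.stack([
            g * (xw + t * xv) + (1 - g) * (A_star[rows] + t * B_star[rows])
            + rng.standard_normal((len(ids), cfg.c)) * cfg.noise_sd
            for t in times
        ])
        stages.append(StageData(s + 1, list(ids), x, z, times.copy(),
                                qt_names, snp_ids))

    # GWAS composite effects: average QT intercept effect per causal SNP
    true_u = W_base.mean(axis=1)

    data = LongitudinalDataset(stages=stages)
    truth = SimTruth(
        true_A=pd.DataFrame(A_star, index=registry, columns=qt_names),
        true_B=pd.DataFrame(B_star, index=registry, columns=qt_names),
        true_W=true_W,
        true_V=true_V,
        true_u=true_u,
        causal_support=support,
        noise_sd=cfg.noise_sd,
        gamma=g,
        config_echo={**asdict(cfg), "mafs": mafs.tolist(),
                     "alleles": alleles.to_dict("index")},
    )
    return data, truth


def simulate_gwas(cfg: SimConfig, truth: SimTruth) -> tuple[GwasSummary, LdPanel]:
    """Independent GWAS cohort and reference panel matching the cohort's SNPs.

    The GWAS phenotype is y = X u* + e with u* = ``truth.true_u`` and the
    noise scaled so the SNP heritability equals ``gwas_h2``; marginal effect
    sizes are x_g' y / (n - 1) on standardized data.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    mafs = np.array(truth.config_echo["mafs"])
    alleles = pd.DataFrame.from_dict(truth.config_echo["alleles"], orient="index")
    snp_ids = list(alleles.index)

    xg = rng.binomial(2, mafs, size=(cfg.n_gwas, cfg.d)).astype(float)
    xg = standardize(xg).values
    u_star = truth.true_u
    signal = xg @ u_star
    var_sig = float(signal.var(ddof=1))
    if cfg.gwas_h2 > 0 and var_sig > 0:
        noise_var = var_sig * (1 - cfg.gwas_h2) / cfg.gwas_h2
    else:
        noise_var = 1.0
        signal = np.zeros(cfg.n_gwas)
    y = signal + rng.standard_normal(cfg.n_gwas) * np.sqrt(noise_var)
    ys = (y - y.mean()) / y.std(ddof=1)
    beta = xg.T @ ys / (cfg.n_gwas - 1)

    summary = GwasSummary(
        snp_ids=snp_ids,
        effect_allele=list(alleles["a1"]),
        other_allele=list(alleles["a2"]),
        beta=beta,
        n_gwas=cfg.n_gwas,
    )
    panel_raw = rng.binomial(2, mafs, size=(cfg.n_ref, cfg.d)).astype(float)
    panel = estimate_ld(panel_raw, snp_ids,
                        effect_allele=list(alleles["a1"]),
                        other_allele=list(alleles["a2"]))
    return summary, panel


@dataclass
class SimulatedStudy:
    """Everything one run of the generator produces."""

    data: LongitudinalDataset
    truth: SimTruth
    summary: GwasSummary
    panel: LdPanel
    harmonized: HarmonizedSummary
    covariates: pd.DataFrame
    config: SimConfig


def simulate_study(cfg: SimConfig | None = None, seed: int | None = None) -> SimulatedStudy:
    """Generate the full study: cohort, GWAS, panel, harmonized summary, covariates.

    The covariate table carries synthetic age/gender/education/handedness, a
    numeric diagnosis and cognitive-score columns correlated with each
    subject's true aging slope (declining subjects score worse), so the
    statistical-validation procedures have realistic inputs.
    """
    from .gwas import harmonize

    cfg = cfg or SimConfig()
    if seed is not None:
        cfg = SimConfig(**{**asdict(cfg), "seed": seed})
    data, truth = simulate_multistage(cfg)
    summary, panel = simulate_gwas(cfg, truth)
    alleles = pd.DataFrame.from_dict(truth.config_echo["alleles"], orient="index")
    hs = harmonize(summary, panel, data.snp_ids, alleles)

    rng = np.random.default_rng(cfg.seed + 2)
    registry = data.registry
    mean_slope = truth.true_B.mean(axis=1).to_numpy()
    # worse (more negative) slopes -> lower cognition, higher diagnosis grade
    zslope = (mean_slope - mean_slope.mean()) / (mean_slope.std(ddof=1) + 1e-12)
    n = len(registry)
    cov = pd.DataFrame(
        {
            "age": rng.normal(75.0, 6.0, n).round(1),
            "gender": rng.integers(0, 2, n),
            "education": rng.normal(16.0, 3.0, n).round(0),
            "handedness": (rng.random(n) < 0.9).astype(int),
            "diagnosis": np.clip(np.round(1.0 - zslope + rng.normal(0, 0.7, n)), 0, 2),
            "MMSE": 27.0 + 2.0 * zslope + rng.normal(0, 1.5, n),
            "ADAS": 12.0 - 4.0 * zslope + rng.normal(0, 3.0, n),
            "RAVLT": 35.0 + 5.0 * zslope + rng.normal(0, 6.0, n),
        },
        index=registry,
    )
    data = LongitudinalDataset(stages=data.stages, covariates=cov)
    return SimulatedStudy(data=data, truth=truth, summary=summary, panel=panel,
                          harmonized=hs, covariates=cov, config=cfg)
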
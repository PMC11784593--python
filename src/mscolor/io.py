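"""File formats and (de)serialization for study inputs and fitted models.

Text formats (all tab-separated with headers unless noted):

* genotype matrix — subjects x SNPs dosages, first column ``subject``;
  optional allele sidecar with columns ``SNP``, ``A1``, ``A2``;
* PLINK 1 binary triplet (``.bed``/``.bim``/``.fam``, SNP-major) — read-only;
* QT long table — columns ``subject``, ``stage``, ``time`` then one column
  per QT;
* covariates — first column ``subject``, numeric columns after;
* GWAS summary statistics — columns ``SNP``, ``A1``, ``A2``, ``BETA``, ``N``;
* LD matrix — SNPs x SNPs with ids as header and first column, ``n_ref``
  carried in a ``# n_ref=...`` comment on the first line;
* fitted models — one TSV per coefficient block plus a JSON metadata record.

Readers raise ``ValueError`` naming the offending file/column/line; writers
round-trip values to 1e-12 and ordering exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .baselines import SmtrFit
from .data_model import LongitudinalDataset, StageData
from .gwas import GwasSummary, LdPanel
from .solver import MscolorFit, SolverConfig

__all__ = [
    "read_genotype_matrix", "write_genotype_matrix",
    "read_alleles", "write_alleles",
    "read_plink", "read_qt_long", "write_qt_long",
    "read_covariates", "write_covariates",
    "read_sumstats", "write_sumstats",
    "read_ld", "write_ld",
    "build_dataset", "dataset_to_frames",
    "write_fit", "read_fit",
]


def _read_table(path, what: str, index_col: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValueError(f"{what} file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as err:
        raise ValueError(f"could not parse {what} file {path}: {err}") from err
    if index_col is not None:
        if index_col not in df.columns:
            raise ValueError(
                f"{what} file {path}: missing required column {index_col!r} "
                f"(line 1; found {list(df.columns)[:6]})"
            )
        df = df.set_index(index_col)
        df.index = df.index.astype(str)
    return df


def _require(df: pd.DataFrame, cols: list[str], path, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file {path}: missing column(s) {missing} (line 1)")


# ---------------------------------------------------------------------------
# genotype matrices and alleles
# ---------------------------------------------------------------------------

def read_genotype_matrix(path) -> pd.DataFrame:
    """Subjects x SNPs dosage/standardized matrix keyed by ``subject``."""
    df = _read_table(path, "genotype", index_col="subject")
    try:
        df = df.astype(float)
    except ValueError as err:
        raise ValueError(f"genotype file {path}: non-numeric entries: {err}") from err
    if df.isna().any().any():
        bad = df.columns[df.isna().any()][0]
        raise ValueError(f"genotype file {path}: missing values in column {bad!r}")
    return df


def write_genotype_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="subject", float_format="%.17g")


def read_alleles(path) -> pd.DataFrame:
    """Allele sidecar: index SNP id, columns ``a1`` (effect), ``a2``."""
    df = _read_table(path, "alleles", index_col="SNP")
    _require(df, ["A1", "A2"], path, "alleles")
    return pd.DataFrame({"a1": df["A1"].astype(str), "a2": df["A2"].astype(str)},
                        index=df.index)


def write_alleles(alleles: pd.DataFrame, path) -> None:
    out = pd.DataFrame({"A1": alleles["a1"], "A2": alleles["a2"]}, index=alleles.index)
    out.to_csv(path, sep="\t", index_label="SNP")


# ---------------------------------------------------------------------------
# PLINK 1 binary triplet (read-only)
# ---------------------------------------------------------------------------

def read_plink(prefix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read ``prefix``.bed/.bim/.fam into (dosages, alleles).

    Dosages count the A1 allele (0/1/2) with subjects x SNPs orientation;
    missing genotypes raise.  Only the SNP-major v1.00 layout is supported.
    """
    prefix = Path(prefix)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for p in (bed, bim, fam):
        if not p.exists():
            raise ValueError(f"PLINK file not found: {p}")
    bim_df = pd.read_csv(bim, sep=r"\s+", header=None,
                         names=["chrom", "SNP", "cm", "pos", "A1", "A2"],
                         dtype={"SNP": str, "A1": str, "A2": str})
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None,
                         names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                         dtype={"iid": str})
    n = len(fam_df)
    d = len(bim_df)
    raw = np.fromfile(bed, dtype=np.uint8)
    if len(raw) < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise ValueError(f"{bed}: not a PLINK .bed file (bad magic bytes)")
    if raw[2] != 0x01:
        raise ValueError(f"{bed}: only SNP-major .bed files are supported")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_snp * d:
        raise ValueError(
            f"{bed}: size mismatch ({len(body)} data bytes, expected "
            f"{bytes_per_snp * d} for {n} subjects x {d} SNPs)"
        )
    codes = body.reshape(d, bytes_per_snp)
    # unpack the four 2-bit genotypes per byte, little-endian within the byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (codes[:, :, None] >> shifts) & 0b11          # (d, bytes, 4)
    two_bit = two_bit.reshape(d, -1)[:, :n]
    # 00 -> 2 copies of A1, 10 -> 1, 11 -> 0, 01 -> missing
    dose = np.select([two_bit == 0, two_bit == 2, two_bit == 3], [2.0, 1.0, 0.0],
                     default=np.nan)
    if np.isnan(dose).any():
        j = int(np.argwhere(np.isnan(dose))[0][0])
        raise ValueError(
            f"{bed}: missing genotype calls (first at SNP "
            f"{bim_df['SNP'].iloc[j]!r}); impute or filter before loading"
        )
    geno = pd.DataFrame(dose.T, index=fam_df["iid"].tolist(),
                        columns=bim_df["SNP"].tolist())
    geno.index.name = "subject"
    alleles = pd.DataFrame({"a1": bim_df["A1"].tolist(), "a2": bim_df["A2"].tolist()},
                           index=bim_df["SNP"].tolist())
    return geno, alleles


# ---------------------------------------------------------------------------
# QT long table, covariates
# ---------------------------------------------------------------------------

def write_qt_long(data: LongitudinalDataset, path) -> None:
    rows = []
    for st in data.stages:
        for k, t in enumerate(st.times):
            for i, sid in enumerate(st.subject_ids):
                rows.append({"subject": sid, "stage": st.stage_index,
                             "time": float(t),
                             **dict(zip(st.qt_names, st.qts[k, i]))})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_qt_long(path) -> pd.DataFrame:
    df = _read_table(path, "QT long table")
    _require(df, ["subject", "stage", "time"], path, "QT long table")
    df["subject"] = df["subject"].astype(str)
    return df


def read_covariates(path) -> pd.DataFrame:
    return _read_table(path, "covariates", index_col="subject")


def write_covariates(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, sep="\t", index_label="subject", float_format="%.17g")


def build_dataset(
    genotype: pd.DataFrame,
    qt_long: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> LongitudinalDataset:
    """Assemble a :class:`LongitudinalDataset` from loaded tables.

    Stages come from the distinct ``stage`` values (ascending); each stage
    keeps the subjects that have every one of its visits, with genotype rows
    matched by subject id.
    """
    qt_cols = [c for c in qt_long.columns if c not in ("subject", "stage", "time")]
    if not qt_cols:
        raise ValueError("QT long table has no QT value columns")
    snp_ids = [str(c) for c in genotype.columns]
    stages = []
    for stage_val in sorted(qt_long["stage"].unique()):
        block = qt_long[qt_long["stage"] == stage_val]
        times = np.array(sorted(block["time"].unique()), dtype=float)
        pivots = []
        subj: list[str] | None = None
        for t in times:
            sl = block[block["time"] == t].set_index("subject")
            if sl.index.duplicated().any():
                dup = sl.index[sl.index.duplicated()][0]
                raise ValueError(
                    f"duplicate QT rows for subject {dup!r} at stage "
                    f"{stage_val}, time {t}"
                )
            ids = set(sl.index)
            subj = ids if subj is None else subj & ids
            pivots.append(sl)
        subj = sorted(subj)
        if not subj:
            raise ValueError(f"stage {stage_val}: no subject has all visits")
        missing = [s for s in subj if s not in genotype.index]
        if missing:
            raise ValueError(
                f"stage {stage_val}: subjects missing from the genotype "
                f"matrix: {missing[:5]}"
            )
        qts = np.stack([p.loc[subj, qt_cols].to_numpy(dtype=float) for p in pivots])
        geno = genotype.loc[subj].to_numpy(dtype=float)
        stages.append(StageData(int(stage_val), list(subj), geno, qts, times,
                                [str(c) for c in qt_cols], snp_ids))
    return LongitudinalDataset(stages=stages, covariates=covariates)


def dataset_to_frames(data: LongitudinalDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(genotype matrix, QT long table) views of a dataset, for writing."""
    seen: dict[str, np.ndarray] = {}
    for st in data.stages:
        for i, sid in enumerate(st.subject_ids):
            seen.setdefault(sid, st.genotype[i])
    geno = pd.DataFrame(np.array([seen[s] for s in data.registry]),
                        index=data.registry, columns=data.snp_ids)
    geno.index.name = "subject"
    rows = []
    for st in data.stages:
        for k, t in enumerate(st.times):
            for i, sid in enumerate(st.subject_ids):
                rows.append({"subject": sid, "stage": st.stage_index,
                             "time": float(t),
                             **dict(zip(st.qt_names, st.qts[k, i]))})
    return geno, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GWAS summary statistics and LD
# ---------------------------------------------------------------------------

def read_sumstats(path) -> GwasSummary:
    df = _read_table(path, "summary statistics")
    _require(df, ["SNP", "A1", "A2", "BETA", "N"], path, "summary statistics")
    n_vals = df["N"].unique()
    if len(n_vals) != 1:
        raise ValueError(f"summary statistics file {path}: N must be constant")
    return GwasSummary(
        snp_ids=[str(s) for s in df["SNP"]],
        effect_allele=[str(a) for a in df["A1"]],
        other_allele=[str(a) for a in df["A2"]],
        beta=df["BETA"].to_numpy(dtype=float),
        n_gwas=int(n_vals[0]),
    )


def write_sumstats(summary: GwasSummary, path) -> None:
    pd.DataFrame({
        "SNP": summary.snp_ids,
        "A1": summary.effect_allele,
        "A2": summary.other_allele,
        "BETA": summary.beta,
        "N": summary.n_gwas,
    }).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_ld(panel: LdPanel, path) -> None:
    path = Path(path)
    df = pd.DataFrame(panel.sigma, index=panel.snp_ids, columns=panel.snp_ids)
    with open(path, "w") as fh:
        fh.write(f"# n_ref={panel.n_ref}\n")
        df.to_csv(fh, sep="\t", index_label="SNP", float_format="%.17g")


def read_ld(path, alleles: pd.DataFrame | None = None) -> LdPanel:
    path = Path(path)
    if not path.exists():
        raise ValueError(f"LD file not found: {path}")
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("# n_ref="):
        raise ValueError(f"LD file {path}: line 1 must be '# n_ref=<int>'")
    n_ref = int(first.split("=", 1)[1])
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    snp_ids = [str(s) for s in df.index]
    if [str(c) for c in df.columns] != snp_ids:
        raise ValueError(f"LD file {path}: row and column SNP ids differ")
    eff = oth = None
    if alleles is not None:
        sub = alleles.loc[snp_ids]
        eff, oth = list(sub["a1"]), list(sub["a2"])
    return LdPanel(snp_ids=snp_ids, sigma=df.to_numpy(dtype=float), n_ref=n_ref,
                   effect_allele=eff, other_allele=oth)


# ---------------------------------------------------------------------------
# fitted models
# ---------------------------------------------------------------------------

def _write_block(arr: np.ndarray, index, columns, path) -> None:
    pd.DataFrame(arr, index=index, columns=columns).to_csv(
        path, sep="\t", index_label="id", float_format="%.17g")


def write_fit(fit: MscolorFit | SmtrFit, out_dir) -> None:
    """Serialize a fitted model to ``out_dir`` (TSV blocks + metadata JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"format_version": 1, "software_version": __version__,
            "method": fit.method, "snp_ids": fit.snp_ids,
            "qt_names": fit.qt_names, "subject_ids": fit.subject_ids,
            "converged": bool(fit.converged), "n_iter": int(fit.n_iter),
            "objective_trace": [float(v) for v in fit.objective_trace],
            "final_objective": float(fit.objective_trace[-1])}
    if isinstance(fit, SmtrFit):
        meta.update({"lam": fit.lam, "times": [float(t) for t in fit.times],
                     "n_blocks": len(fit.W)})
        for k, wk in enumerate(fit.W):
            _write_block(wk, fit.snp_ids, fit.qt_names, out / f"W_time{k + 1}.tsv")
    else:
        meta.update({
            "config": asdict(fit.config),
            "true_objective_trace": [float(v) for v in fit.true_objective_trace],
            "n_stages": len(fit.W),
            "has_u": fit.u is not None,
            "share_aging": fit.A_s is None,
        })
        meta["config"]["lambda_p"] = np.asarray(fit.config.lambda_p).tolist()
        meta["config"]["lambda_q"] = np.asarray(fit.config.lambda_q).tolist()
        for s, (w, v) in enumerate(zip(fit.W, fit.V)):
            _write_block(w, fit.snp_ids, fit.qt_names, out / f"W_stage{s + 1}.tsv")
            _write_block(v, fit.snp_ids, fit.qt_names, out / f"V_stage{s + 1}.tsv")
            if fit.u is not None:
                _write_block(fit.u[s][:, None], fit.snp_ids, ["u"],
                             out / f"u_stage{s + 1}.tsv")
        if fit.A_s is None:
            _write_block(fit.A, fit.subject_ids, fit.qt_names, out / "A.tsv")
            _write_block(fit.B, fit.subject_ids, fit.qt_names, out / "B.tsv")
        else:
            meta["stage_subject_counts"] = [a.shape[0] for a in fit.A_s]
            for s, (a, b) in enumerate(zip(fit.A_s, fit.B_s)):
                _write_block(a, range(a.shape[0]), fit.qt_names, out / f"A_stage{s + 1}.tsv")
                _write_block(b, range(b.shape[0]), fit.qt_names, out / f"B_stage{s + 1}.tsv")
    with open(out / "fit_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def _read_block(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=float)


def read_fit(fit_dir) -> MscolorFit | SmtrFit:
    """Load a fit serialized by :func:`write_fit`."""
    out = Path(fit_dir)
    meta_path = out / "fit_meta.json"
    if not meta_path.exists():
        raise ValueError(f"fit metadata not found: {meta_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    if meta.get("format_version") != 1:
        raise ValueError(f"{meta_path}: unsupported fit format version")
    if meta["method"] == "smtr":
        W = [_read_block(out / f"W_time{k + 1}.tsv") for k in range(meta["n_blocks"])]
        return SmtrFit(subject_ids=meta["subject_ids"], snp_ids=meta["snp_ids"],
                       qt_names=meta["qt_names"], W=W,
                       times=np.array(meta["times"]), lam=meta["lam"],
                       objective_trace=np.array(meta["objective_trace"]),
                       converged=meta["converged"], n_iter=meta["n_iter"])
    cfg_kwargs = dict(meta["config"])
    for key in ("lambda_p", "lambda_q"):
        val = cfg_kwargs[key]
        cfg_kwargs[key] = val if np.isscalar(val) else list(val)
    config = SolverConfig(**cfg_kwargs)
    L = meta["n_stages"]
    W = [_read_block(out / f"W_stage{s + 1}.tsv") for s in range(L)]
    V = [_read_block(out / f"V_stage{s + 1}.tsv") for s in range(L)]
    u = ([_read_block(out / f"u_stage{s + 1}.tsv")[:, 0] for s in range(L)]
         if meta["has_u"] else None)
    if meta["share_aging"]:
        A = _read_block(out / "A.tsv")
        B = _read_block(out / "B.tsv")
        A_s = B_s = None
    else:
        A_s = [_read_block(out / f"A_stage{s + 1}.tsv") for s in range(L)]
        B_s = [_read_block(out / f"B_stage{s + 1}.tsv") for s in range(L)]
        n_reg = len(meta["subject_ids"])
        A = np.zeros((n_reg, len(meta["qt_names"])))
        B = np.zeros_like(A)
    return MscolorFit(method=meta["method"], subject_ids=meta["subject_ids"],
                      snp_ids=meta["snp_ids"], qt_names=meta["qt_names"],
                      A=A, B=B, W=W, V=V, u=u, A_s=A_s, B_s=B_s, config=config,
                      objective_trace=np.array(meta["objective_trace"]),
                      true_objective_trace=np.array(meta["true_objective_trace"]),
                      converged=meta["converged"], n_iter=meta["n_iter"])
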
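"""Unit tests for GWAS summary statistics, LD estimation and harmonization."""

import numpy as np
import pandas as pd
import pytest

from mscolor.data_model import standardize
from mscolor.gwas import (
    GwasSummary,
    LdPanel,
    estimate_ld,
    harmonize,
    joint_effects,
    marginal_effects,
)


def _std_cols(x):
    return standardize(x).values


def test_marginal_effects_equals_sample_correlation():
    rng = np.random.default_rng(0)
    x = _std_cols(rng.standard_normal((200, 1)))[:, 0]
    y = _std_cols(rng.standard_normal((200, 1)))[:, 0]
    beta = marginal_effects(x, y)
    assert beta == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)
    assert -1.0 <= beta <= 1.0


def test_marginal_effects_validation():
    with pytest.raises(ValueError, match="same length"):
        marginal_effects(np.zeros(5), np.zeros(4))
    with pytest.raises(ValueError, match="at least 3"):
        marginal_effects(np.zeros(2), np.zeros(2))


def test_estimate_ld_unit_diagonal_and_symmetry():
    rng = np.random.default_rng(1)
    panel = rng.binomial(2, 0.3, size=(300, 10)).astype(float)
    ld = estimate_ld(panel)
    assert np.allclose(np.diag(ld.sigma), 1.0)
    assert np.allclose(ld.sigma, ld.sigma.T)
    # off-diagonals are the sample correlations
    z = _std_cols(panel)
    assert np.allclose(ld.sigma, z.T @ z / (panel.shape[0] - 1), atol=1e-12)


def test_estimate_ld_drops_monomorphic_with_warning():
    rng = np.random.default_rng(2)
    panel = rng.binomial(2, 0.4, size=(50, 4)).astype(float)
    panel[:, 2] = 1.0
    with pytest.warns(UserWarning, match="monomorphic"):
        ld = estimate_ld(panel, ["a", "b", "c", "d"])
    assert ld.snp_ids == ["a", "b", "d"]
    assert ld.sigma.shape == (3, 3)


def test_joint_effects_matches_ols_on_same_cohort():
    rng = np.random.default_rng(3)
    n, d = 500, 8
    x = _std_cols(rng.binomial(2, rng.uniform(0.1, 0.5, d), size=(n, d)).astype(float))
    y = _std_cols((x @ rng.standard_normal(d) + rng.standard_normal(n))[:, None])[:, 0]
    sigma = estimate_ld(x).sigma
    beta = x.T @ y / (n - 1)
    u = joint_effects(beta, sigma, ridge=0.0)
    ols, *_ = np.linalg.lstsq(x, y, rcond=None)
    assert np.allclose(u, ols, atol=1e-8)


def test_joint_effects_ridge_validation():
    with pytest.raises(ValueError, match="nonnegative"):
        joint_effects(np.ones(2), np.eye(2), ridge=-1.0)


def test_summary_and_panel_validation():
    with pytest.raises(ValueError, match="allele"):
        GwasSummary(["s1"], ["X"], ["A"], np.array([0.1]), 100)
    with pytest.raises(ValueError, match="symmetric"):
        LdPanel(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]]), 10)


def _fixture_for_harmonize():
    snps = ["rs1", "rs2", "rs3", "rs4"]
    sigma = np.array([
        [1.0, 0.3, 0.1, 0.0],
        [0.3, 1.0, 0.2, 0.1],
        [0.1, 0.2, 1.0, 0.4],
        [0.0, 0.1, 0.4, 1.0],
    ])
    # summary reports rs2 on the opposite orientation; rs4 is strand-ambiguous
    summary = GwasSummary(
        snp_ids=snps,
        effect_allele=["A", "T", "C", "A"],
        other_allele=["G", "C", "T", "T"],
        beta=np.array([0.10, -0.20, 0.05, 0.30]),
        n_gwas=1000,
    )
    panel = LdPanel(snps, sigma, 200,
                    effect_allele=["A", "C", "C", "A"],
                    other_allele=["G", "T", "T", "T"])
    target = pd.DataFrame({"a1": ["A", "C", "C", "A"],
                           "a2": ["G", "T", "T", "T"]}, index=snps)
    return summary, panel, target, sigma


def test_harmonize_sign_flips_beta_and_ld():
    summary, panel, target, sigma = _fixture_for_harmonize()
    hs = harmonize(summary, panel, list(target.index), target)
    # rs4 (A/T) dropped as ambiguous; rs2 flipped (summary effect allele = target a2)
    assert hs.snp_ids == ["rs1", "rs2", "rs3"]
    assert hs.drop_count == 1
    assert hs.flip_count == 1
    assert np.allclose(hs.beta, [0.10, 0.20, 0.05])
    # panel alleles match the target, so LD signs are unchanged
    assert np.allclose(hs.sigma, sigma[:3, :3])
    assert hs.n_gwas == 1000 and hs.n_ref == 200


def test_harmonize_flips_ld_when_panel_orientation_differs():
    summary, panel, target, sigma = _fixture_for_harmonize()
    panel.effect_allele = ["G", "C", "C", "A"]  # rs1 swapped in the panel
    panel.other_allele = ["A", "T", "T", "T"]
    hs = harmonize(summary, panel, list(target.index), target)
    flips = np.array([-1.0, 1.0, 1.0])
    assert np.allclose(hs.sigma, sigma[:3, :3] * np.outer(flips, flips))


def test_harmonize_keeps_ambiguous_when_asked():
    summary, panel, target, _ = _fixture_for_harmonize()
    hs = harmonize(summary, panel, list(target.index), target, drop_ambiguous=False)
    assert hs.snp_ids == ["rs1", "rs2", "rs3", "rs4"]
    assert hs.beta[3] == pytest.approx(0.30)


def test_harmonize_drops_mismatched_alleles_and_errors_when_empty():
    summary, panel, target, _ = _fixture_for_harmonize()
    target2 = target.copy()
    target2.loc["rs3"] = ["A", "G"]  # alleles incompatible with the summary
    hs = harmonize(summary, panel, list(target2.index), target2)
    assert "rs3" not in hs.snp_ids
    with pytest.raises(ValueError, match="no SNPs shared"):
        harmonize(summary, panel, ["rs99"], pd.DataFrame({"a1": ["A"], "a2": ["G"]},
                                                         index=["rs99"]))
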
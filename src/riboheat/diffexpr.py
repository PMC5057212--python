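"""Two-condition negative-binomial differential testing and three-way
transcriptional/translational classification.

The test follows the DESeq lineage: median-of-ratios size factors, an
NB variance model ``var = mu + alpha * mu^2``, and information sharing
across genes for the dispersion. Per-gene method-of-moments dispersion
estimates from a 2 x 2 design carry only two residual degrees of freedom
and make a Wald test wildly anti-conservative, so the working dispersion
is a mean-dispersion trend ``alpha(mu) = a0 + a1 / mu`` fitted across all
genes by least squares on the per-gene moment estimates (floored at
``alpha_floor``). The Wald z statistic on log2 fold change with a
delta-method standard error is then well calibrated (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA_FLOOR = 1e-8

#: regulation classes (mRNA-only == transcriptional change with unchanged
#: ribosome footprints; RPF-only == purely translational change)
CLASSES = (
    "both_up",
    "both_down",
    "mrna_only_up",
    "mrna_only_down",
    "rpf_only_up",
    "rpf_only_down",
    "discordant",
    "unchanged",
    "below_detection",
)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample j, factor_j = median over genes (nonzero in every
    sample) of count_ij / geometric-mean_i(counts).
    """
    arr = counts.to_numpy(dtype=float)
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; filter or merge samples"
        )
    sub = arr[all_nonzero]
    log_gm = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_gm[:, None], axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _moment_dispersion(
    norm: np.ndarray, cond_a: np.ndarray, cond_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene pooled within-condition MoM dispersion and overall mean."""
    va = norm[:, cond_a].var(axis=1, ddof=1)
    vb = norm[:, cond_b].var(axis=1, ddof=1)
    s2 = (va + vb) / 2.0
    mu = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - mu) / np.maximum(mu, 1e-12) ** 2
    return raw, mu


def fit_dispersion_trend(mu: np.ndarray, raw_alpha: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha(mu) = a0 + a1/mu to per-gene moment estimates.

    Returns the fitted (floored) dispersion per gene. Genes with zero mean
    get the floor. With fewer than 10 usable genes the pooled mean of the
    raw estimates is used instead of a two-parameter fit.
    """
    ok = mu > 0
    if ok.sum() < 10:
        pooled = float(np.nanmean(np.clip(raw_alpha[ok], 0, None))) if ok.any() else 0.0
        fitted = np.full_like(mu, max(pooled, ALPHA_FLOOR))
        fitted[~ok] = ALPHA_FLOOR
        return fitted
    x = 1.0 / mu[ok]
    y = raw_alpha[ok]
    design = np.column_stack([np.ones(ok.sum()), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    with np.errstate(divide="ignore"):
        fitted = coef[0] + coef[1] / np.maximum(mu, 1e-12)
    return np.maximum(fitted, ALPHA_FLOOR)


def nb_test(
    counts: pd.DataFrame,
    sf: pd.Series,
    conditions: Sequence[str],
    alpha_floor: float = ALPHA_FLOOR,
) -> pd.DataFrame:
    """Per-gene Wald test of heat vs control on NB counts.

    ``conditions`` labels each sample ``"control"`` or ``"heat"`` (order
    matching the count columns). Fold changes are heat over control with a
    0.5 pseudocount on the normalized condition means. Genes with zero
    counts everywhere get (log2FC 0, p 1).

    Returns a DataFrame indexed by gene with columns ``log2fc``,
    ``pvalue``, ``base_mean`` and ``dispersion``.
    """
    conditions = np.asarray(conditions)
    if set(conditions) != {"control", "heat"}:
        raise ValueError("conditions must contain both 'control' and 'heat'")
    cond_a = conditions == "control"
    cond_b = conditions == "heat"
    arr = counts.to_numpy(dtype=float)
    sf_v = sf.reindex(counts.columns).to_numpy(dtype=float)
    norm = arr / sf_v[None, :]

    raw_alpha, mu = _moment_dispersion(norm, cond_a, cond_b)
    alpha = np.maximum(fit_dispersion_trend(mu, raw_alpha), alpha_floor)

    m_a = norm[:, cond_a].mean(axis=1)
    m_b = norm[:, cond_b].mean(axis=1)
    log2fc = np.log2((m_b + 0.5) / (m_a + 0.5))

    ln2_sq = np.log(2.0) ** 2

    def var_log2_mean(m: np.ndarray, cond: np.ndarray) -> np.ndarray:
        # Var(K_ij / s_j) = mu/s_j + alpha mu^2 for NB counts
        inv_s = (1.0 / sf_v[cond]).sum()
        n = cond.sum()
        var_mean = (m * inv_s / n + alpha * m**2) / n
        return var_mean / ((m + 0.5) ** 2 * ln2_sq)

    se = np.sqrt(var_log2_mean(m_a, cond_a) + var_log2_mean(m_b, cond_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / np.maximum(se, 1e-12)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))

    all_zero = (arr == 0).all(axis=1)
    log2fc[all_zero] = 0.0
    pvalue[all_zero] = 1.0

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvalue,
            "base_mean": mu,
            "dispersion": alpha,
        },
        index=counts.index,
    )


def classify_genes(
    mrna_results: pd.DataFrame,
    rpf_results: pd.DataFrame,
    fdr: float = 0.1,
    detected: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Three-way regulation classes at a given FDR.

    BH adjustment is applied separately within each assay; a gene is
    significant when its adjusted p <= ``fdr``. Classes: significant in
    both assays and co-directional -> both_up / both_down; mRNA only ->
    mrna_only_*; RPF only -> rpf_only_*; significant in both with opposite
    signs -> discordant; nothing significant -> unchanged. An optional
    boolean ``detected`` mask routes undetected genes to below_detection
    without testing them.
    """
    if set(mrna_results.index) != set(rpf_results.index):
        diff = set(mrna_results.index) ^ set(rpf_results.index)
        raise ValueError(
            f"mRNA and RPF result sets differ by {len(diff)} genes"
        )
    rpf_results = rpf_results.reindex(mrna_results.index)
    idx = mrna_results.index
    if detected is None:
        detected = pd.Series(True, index=idx)
    detected = detected.reindex(idx).fillna(False).astype(bool)

    out = pd.DataFrame(index=idx)
    out["log2fc_mrna"] = mrna_results["log2fc"]
    out["pvalue_mrna"] = mrna_results["pvalue"]
    out["log2fc_rpf"] = rpf_results["log2fc"]
    out["pvalue_rpf"] = rpf_results["pvalue"]
    for assay in ("mrna", "rpf"):
        padj = pd.Series(np.nan, index=idx)
        tested = detected.to_numpy()
        if tested.any():
            padj.iloc[tested] = multipletests(
                out[f"pvalue_{assay}"].to_numpy()[tested], method="fdr_bh"
            )[1]
        out[f"padj_{assay}"] = padj

    sig_m = (out["padj_mrna"] <= fdr) & detected
    sig_r = (out["padj_rpf"] <= fdr) & detected
    up_m = out["log2fc_mrna"] > 0
    up_r = out["log2fc_rpf"] > 0

    cls = pd.Series("unchanged", index=idx, dtype=object)
    cls[sig_m & sig_r & (up_m == up_r) & up_m] = "both_up"
    cls[sig_m & sig_r & (up_m == up_r) & ~up_m] = "both_down"
    cls[sig_m & sig_r & (up_m != up_r)] = "discordant"
    cls[sig_m & ~sig_r & up_m] = "mrna_only_up"
    cls[sig_m & ~sig_r & ~up_m] = "mrna_only_down"
    cls[~sig_m & sig_r & up_r] = "rpf_only_up"
    cls[~sig_m & sig_r & ~up_r] = "rpf_only_down"
    cls[~detected] = "below_detection"
    out["class"] = cls
    return out
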
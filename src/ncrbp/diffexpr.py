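"""Minimal differential-expression and translation-efficiency layer.

Normalization uses median-of-ratios size factors (the reference is the
per-gene geometric mean over genes detected in every sample). Per-gene
log2 fold changes come from size-factor-normalized means with a 0.5
pseudocount; p-values from Welch's unequal-variance t-test on
log2-normalized counts; multiple testing by Benjamini-Hochberg. This is a
deliberately small, fully specified stand-in for a full count-model
framework: the downstream stabilization and TE statistics only consume
per-gene log fold changes.

Also implements relative qPCR quantification (2^-ddCt against a reference
gene) and the RNC/total translation-efficiency contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "size_factors",
    "normalized_counts",
    "differential_expression",
    "ddct",
    "translation_efficiency",
]

PSEUDOCOUNT = 0.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (column).

    factor_s = median over reference genes of count_gs / geomean_g, where
    the reference set is the genes with a nonzero count in every sample.
    """
    mat = counts.to_numpy(dtype=float)
    reference = (mat > 0).all(axis=1)
    if not reference.any():
        raise ValueError(
            "no gene is detected in every sample; median-of-ratios is undefined "
            "(consider total-count normalization)"
        )
    ref = mat[reference]
    log_geomean = np.log(ref).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(ref) - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def differential_expression(
    counts: pd.DataFrame, meta: pd.DataFrame, group_col: str = "group",
    contrast: tuple = ("knockdown", "control"),
) -> pd.DataFrame:
    """Per-gene log2 fold change (numerator over denominator of ``contrast``),
    Welch p-value on log2-normalized counts, and BH-adjusted p.

    Samples are selected by ``meta[group_col]``; with a single sample in a
    group the fold change is still reported and p is NA.
    """
    num_label, den_label = contrast
    meta = meta.set_index("sample") if "sample" in meta.columns else meta
    num_samples = meta.index[meta[group_col] == num_label]
    den_samples = meta.index[meta[group_col] == den_label]
    if len(num_samples) == 0 or len(den_samples) == 0:
        raise ValueError(f"contrast {contrast} has an empty group")
    sub = counts[list(num_samples) + list(den_samples)]
    norm = normalized_counts(sub)
    log_norm = np.log2(norm + PSEUDOCOUNT)

    num_mean = norm[num_samples].mean(axis=1)
    den_mean = norm[den_samples].mean(axis=1)
    log2fc = np.log2(num_mean + PSEUDOCOUNT) - np.log2(den_mean + PSEUDOCOUNT)

    if len(num_samples) >= 2 and len(den_samples) >= 2:
        t, p = stats.ttest_ind(
            log_norm[num_samples], log_norm[den_samples], axis=1, equal_var=False
        )
        p = np.where(np.isnan(p), 1.0, p)
        padj = multipletests(p, method="fdr_bh")[1]
    else:
        p = np.full(len(counts), np.nan)
        padj = np.full(len(counts), np.nan)
    return pd.DataFrame(
        {"gene_id": counts.index, "log2fc": log2fc.values, "p": p, "padj": padj}
    ).set_index("gene_id")


def ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference within each of sample and calibrator;
    ddCt = dCt_sample - dCt_calibrator; returns 2^-ddCt.
    """
    cts = [ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator]
    if any(c is None or (isinstance(c, float) and np.isnan(c)) for c in cts):
        raise ValueError("missing Ct value")
    dct_sample = ct_target_sample - ct_ref_sample
    dct_cal = ct_target_calibrator - ct_ref_calibrator
    return float(2.0 ** -(dct_sample - dct_cal))


def translation_efficiency(
    counts: pd.DataFrame, meta: pd.DataFrame,
    contrast: tuple = ("knockdown", "control"),
) -> pd.DataFrame:
    """Per-gene translation efficiency (RNC over total) and its knockdown shift.

    Within each group, TE_g = (normalized RNC mean + pc) / (normalized
    total mean + pc); delta_log2_te = log2 TE_kd - log2 TE_control. The
    p-value applies Welch's test to per-replicate log2 TE (replicate i of
    the RNC fraction paired with replicate i of the total fraction by sort
    order within the group).
    """
    meta = meta.set_index("sample") if "sample" in meta.columns else meta
    kd_label, ctrl_label = contrast

    def _group_te(label: str) -> tuple[pd.Series, pd.DataFrame]:
        rnc = sorted(meta.index[(meta["group"] == label) & (meta["fraction"] == "RNC")])
        tot = sorted(meta.index[(meta["group"] == label) & (meta["fraction"] == "total")])
        if not rnc or not tot:
            raise ValueError(f"group {label!r} lacks an RNC or total fraction")
        norm = normalized_counts(counts[rnc + tot])
        te = (norm[rnc].mean(axis=1) + PSEUDOCOUNT) / (norm[tot].mean(axis=1) + PSEUDOCOUNT)
        n = min(len(rnc), len(tot))
        rep_te = np.log2(
            (norm[rnc[:n]].to_numpy() + PSEUDOCOUNT) / (norm[tot[:n]].to_numpy() + PSEUDOCOUNT)
        )
        return te, rep_te

    te_kd, rep_kd = _group_te(kd_label)
    te_ctrl, rep_ctrl = _group_te(ctrl_label)
    delta = np.log2(te_kd) - np.log2(te_ctrl)
    if rep_kd.shape[1] >= 2 and rep_ctrl.shape[1] >= 2:
        _, p = stats.ttest_ind(rep_kd, rep_ctrl, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
    else:
        p = np.full(len(counts), np.nan)
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "te_control": te_ctrl.values,
            "te_kd": te_kd.values,
            "delta_log2_te": delta.values,
            "p": p,
        }
    ).set_index("gene_id")
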
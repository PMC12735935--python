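"""Group and outcome statistics over IC scores, ROI features and voxel maps.

Covers the statistical surface of the analysis: demographics comparisons
(chi-squared sex table, Shapiro-Wilk normality, Wilcoxon rank-sum),
per-component two-sample t-tests with Benjamini-Hochberg FDR control,
Spearman correlations between IC subject scores and ROI features (with
top-|rho| region ranking), voxelwise group t-tests inside an ROI, and
Spearman correlations of IC scores / ROI metrics with the GOS-E outcome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_fdr",
    "compare_groups",
    "correlate_components_rois",
    "top_regions",
    "voxelwise_group_ttest",
    "correlate_gose",
    "correlate_gose_rois",
    "demographics",
]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(
    ic_scores: pd.DataFrame,
    group_labels,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test per IC column between the two groups, with BH-FDR
    across ICs, group means and the 95% CI of the mean difference.

    Pooled-variance t by default; set ``equal_var=False`` for Welch.
    """
    groups = pd.unique(np.asarray(group_labels))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    g1 = np.asarray(group_labels) == groups[0]
    g2 = np.asarray(group_labels) == groups[1]
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("each group needs n >= 2")
    rows = []
    for col in ic_scores.columns:
        x = ic_scores[col].to_numpy(dtype=float)
        a, b = x[g1], x[g2]
        degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
        if degenerate and np.mean(a) == np.mean(b):
            t, p, lo, hi = 0.0, 1.0, 0.0, 0.0
        else:
            res = sps.ttest_ind(a, b, equal_var=equal_var)
            t, p = float(res.statistic), float(res.pvalue)
            ci = res.confidence_interval(0.95)
            lo, hi = float(ci.low), float(ci.high)
        rows.append({
            "ic": col, "t": t, "p": p,
            f"mean_{groups[0]}": float(np.mean(a)),
            f"mean_{groups[1]}": float(np.mean(b)),
            "diff": float(np.mean(a) - np.mean(b)),
            "ci_low": lo, "ci_high": hi,
            "degenerate": bool(degenerate),
        })
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p"].to_numpy())
    return out


def _spearman_table(y: np.ndarray, features: pd.DataFrame, label: str) -> pd.DataFrame:
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({label: col, "rho": np.nan, "p": np.nan,
                         "degenerate": True})
            continue
        rho, p = sps.spearmanr(y, x)
        rows.append({label: col, "rho": float(rho), "p": float(p),
                     "degenerate": False})
    out = pd.DataFrame(rows)
    ok = ~out["degenerate"]
    out["p_fdr"] = np.nan
    if ok.any():
        out.loc[ok, "p_fdr"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    return out


def correlate_components_rois(
    ic_scores: pd.DataFrame,
    zblocks: dict,
) -> pd.DataFrame:
    """Spearman rho between every IC score column and every ROI column of
    every z-scored modality block; BH-FDR applied within each IC x modality
    family (the block's ROI count, typically 90 tests).

    ``zblocks`` maps modality name to a subject x ROI DataFrame (or
    BlockMatrix) aligned with ``ic_scores``.
    """
    frames = []
    for modality, block in zblocks.items():
        data = block.data if hasattr(block, "data") else block
        if len(data) != len(ic_scores):
            raise ValueError(f"block {modality!r} subject count mismatch")
        for ic in ic_scores.columns:
            tab = _spearman_table(
                ic_scores[ic].to_numpy(dtype=float), data, "roi"
            )
            tab.insert(0, "modality", modality)
            tab.insert(0, "ic", ic)
            frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def top_regions(corr_table: pd.DataFrame, m: int = 5) -> pd.DataFrame:
    """Per IC x modality, the ``m`` ROIs with largest |rho| (ties broken by
    ascending ROI id)."""
    if corr_table.empty:
        raise ValueError("empty correlation table")
    tab = corr_table.copy()
    tab["abs_rho"] = tab["rho"].abs()
    tab = tab.sort_values(
        ["ic", "modality", "abs_rho", "roi"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    out = tab.groupby(["ic", "modality"], sort=False).head(m).reset_index(drop=True)
    out["rank"] = out.groupby(["ic", "modality"], sort=False).cumcount() + 1
    return out.drop(columns="abs_rho")


def voxelwise_group_ttest(
    maps: np.ndarray,
    roi_mask: np.ndarray,
    group_labels,
    equal_var: bool = True,
) -> dict:
    """Voxelwise two-sample t-test inside an ROI, BH-FDR over its voxels.

    ``maps`` is (n_subjects, \\*grid); returns volumes of t, p and FDR-adjusted
    p (NaN outside the ROI) plus a flag volume for degenerate voxels.
    """
    maps = np.asarray(maps, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI mask")
    groups = pd.unique(np.asarray(group_labels))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    g1 = np.asarray(group_labels) == groups[0]
    g2 = ~g1
    a = maps[g1][:, roi_mask]
    b = maps[g2][:, roi_mask]
    degenerate = (a.std(axis=0, ddof=1) == 0) & (b.std(axis=0, ddof=1) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(a, b, axis=0, equal_var=equal_var)
    same = degenerate & (a.mean(axis=0) == b.mean(axis=0))
    t = np.where(same, 0.0, t)
    p = np.where(same, 1.0, p)
    ok = np.isfinite(p)
    p_fdr = np.full_like(p, np.nan)
    if ok.any():
        p_fdr[ok] = bh_fdr(p[ok])
    out = {}
    for name, vals in (("t", t), ("p", p), ("p_fdr", p_fdr)):
        vol = np.full(roi_mask.shape, np.nan)
        vol[roi_mask] = vals
        out[name] = vol
    flag = np.zeros(roi_mask.shape, dtype=bool)
    flag[roi_mask] = degenerate
    out["degenerate"] = flag
    return out


def correlate_gose(ic_scores: pd.DataFrame, gose) -> pd.DataFrame:
    """Spearman rho of each IC score column with the GOS-E outcome
    (injured-group subjects only), BH-FDR across ICs."""
    gose = np.asarray(gose, dtype=float)
    if gose.size != len(ic_scores):
        raise ValueError("GOS-E vector must match the subject count")
    if gose.size < 5:
        raise ValueError("need n >= 5 subjects with GOS-E")
    return _spearman_table(gose, ic_scores, "ic")


def correlate_gose_rois(zblocks: dict, gose) -> pd.DataFrame:
    """Spearman rho of every ROI column of every modality with GOS-E;
    BH-FDR within each modality's ROI family."""
    gose = np.asarray(gose, dtype=float)
    if gose.size < 5:
        raise ValueError("need n >= 5 subjects with GOS-E")
    frames = []
    for modality, block in zblocks.items():
        data = block.data if hasattr(block, "data") else block
        if len(data) != gose.size:
            raise ValueError(f"block {modality!r} subject count mismatch")
        tab = _spearman_table(gose, data, "roi")
        tab.insert(0, "modality", modality)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def demographics(subject_table: pd.DataFrame, continuous=("age",)) -> dict:
    """Demographics report: Pearson chi-squared (no continuity correction) on
    the sex x group table, Shapiro-Wilk normality per group and Wilcoxon
    rank-sum group comparison for each continuous variable.
    """
    tab = pd.crosstab(subject_table["group"], subject_table["sex"])
    if tab.shape[0] != 2:
        raise ValueError("exactly two groups required")
    chi2, p_chi2, dof, expected = sps.chi2_contingency(
        tab.to_numpy(), correction=False
    )
    report = {
        "sex_table": tab,
        "chi2": float(chi2),
        "chi2_p": float(p_chi2),
        "chi2_dof": int(dof),
        "chi2_warning": bool((expected < 5).any()),
        "continuous": {},
    }
    groups = list(tab.index)
    for var in continuous:
        x = subject_table.loc[subject_table["group"] == groups[0], var].dropna()
        y = subject_table.loc[subject_table["group"] == groups[1], var].dropna()
        sw = {
            g: tuple(map(float, sps.shapiro(v)))
            for g, v in ((groups[0], x), (groups[1], y))
            if len(v) >= 3
        }
        w, p_w = sps.ranksums(x, y)
        report["continuous"][var] = {
            "shapiro": sw,
            "ranksum_stat": float(w),
            "ranksum_p": float(p_w),
        }
    return report
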
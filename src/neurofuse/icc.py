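"""Test-retest reliability via two-way intraclass correlation coefficients.

From the two-way ANOVA mean squares of an n-subjects x k-visits table
(rows = subjects, columns = visits):

    ICC(3,1) consistency        = (MS_R - MS_E) / (MS_R + (k-1) MS_E)
    ICC(2,1) absolute agreement = (MS_R - MS_E) /
                                  (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

where MS_R, MS_C and MS_E are the subject, visit and residual mean squares.
The consistency form ignores a systematic between-visit offset; the
agreement form penalises it.  ``icc_map`` applies the estimator voxelwise to
two-visit map stacks and summarises the in-mask distribution as mean +/- SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["IccResult", "icc_two_way", "icc_map"]


@dataclass
class IccResult:
    """Voxelwise ICC volume with its in-mask summary."""

    icc: np.ndarray
    variant: str
    mean: float
    sd: float
    degenerate: np.ndarray  # zero-total-variance voxels, excluded from summary


def _mean_squares(x: np.ndarray):
    """Two-way ANOVA mean squares; ``x`` is (..., n_subjects, k_visits)."""
    n, k = x.shape[-2], x.shape[-1]
    grand = x.mean(axis=(-2, -1), keepdims=True)
    row_mean = x.mean(axis=-1, keepdims=True)
    col_mean = x.mean(axis=-2, keepdims=True)
    ss_rows = k * ((row_mean - grand) ** 2).sum(axis=(-2, -1))
    ss_cols = n * ((col_mean - grand) ** 2).sum(axis=(-2, -1))
    ss_err = ((x - row_mean - col_mean + grand) ** 2).sum(axis=(-2, -1))
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return ms_r, ms_c, ms_e


def icc_two_way(
    measurements: np.ndarray,
    variant: str = "consistency",
    floor: float = -1.0,
):
    """ICC of an (..., n_subjects, k_visits) table.

    ``variant`` is ``"consistency"`` (ICC(3,1)) or ``"agreement"``
    (ICC(2,1)).  Estimates below ``floor`` are clipped.  Zero total variance
    yields NaN.  Returns a scalar for a 2-D table, an array otherwise.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim < 2:
        raise ValueError("measurements must be (n_subjects, k_visits)")
    n, k = x.shape[-2], x.shape[-1]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if k < 2:
        raise ValueError("need at least 2 visits")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells are not supported")
    ms_r, ms_c, ms_e = _mean_squares(x)
    if variant == "consistency":
        denom = ms_r + (k - 1) * ms_e
    elif variant == "agreement":
        denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(denom != 0, (ms_r - ms_e) / denom, np.nan)
    icc = np.where(np.isnan(icc), icc, np.maximum(icc, floor))
    return float(icc) if icc.ndim == 0 else icc


def icc_map(
    visit1: np.ndarray,
    visit2: np.ndarray,
    mask: np.ndarray | None = None,
    variant: str = "consistency",
    floor: float = -1.0,
) -> IccResult:
    """Voxelwise ICC from two visit stacks of shape (n_subjects, \\*grid).

    Degenerate voxels (zero total variance across subjects and visits) are
    flagged and excluded from the in-mask mean +/- SD summary.
    """
    v1 = np.asarray(visit1, dtype=float)
    v2 = np.asarray(visit2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("visit stacks must share shape")
    if v1.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    grid = v1.shape[1:]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    # (voxels, subjects, visits)
    stack = np.stack([v1[:, mask], v2[:, mask]], axis=-1).transpose(1, 0, 2)
    vals = icc_two_way(stack, variant=variant, floor=floor)
    degenerate_flat = ~np.isfinite(vals)
    icc_vol = np.full(grid, np.nan)
    icc_vol[mask] = vals
    degenerate = np.zeros(grid, dtype=bool)
    degenerate[mask] = degenerate_flat
    good = vals[~degenerate_flat]
    return IccResult(
        icc=icc_vol,
        variant=variant,
        mean=float(good.mean()) if good.size else float("nan"),
        sd=float(good.std(ddof=1)) if good.size > 1 else 0.0,
        degenerate=degenerate,
    )
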
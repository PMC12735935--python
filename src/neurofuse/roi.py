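"""Atlas ROI feature extraction: voxel maps -> subject x region block matrices.

Parameter maps are reduced to per-region means over a 90-region integer
atlas, stacked into one subject x ROI matrix per modality and z-scored
across subjects (the form the multimodal fusion consumes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BlockMatrix", "extract_roi_means", "assemble_block", "zscore_block"]

logger = logging.getLogger(__name__)


@dataclass
class BlockMatrix:
    """Subject x feature matrix for one modality.

    ``data`` is a DataFrame with subject ids as index and feature (ROI) ids
    as columns.  ``zscored`` records whether columns were standardised;
    ``degenerate_features`` lists zero-variance columns that were set to 0.
    """

    modality: str
    data: pd.DataFrame
    zscored: bool = False
    degenerate_features: list = field(default_factory=list)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def subjects(self) -> list:
        return list(self.data.index)


def extract_roi_means(
    volume: np.ndarray,
    atlas: np.ndarray,
    mask: np.ndarray | None = None,
    n_regions: int | None = None,
) -> np.ndarray:
    """Mean of in-region, in-mask, finite voxels per atlas label.

    Returns a vector ordered by ascending label (1..n_regions); a region with
    no valid voxel yields NaN with a warning.
    """
    volume = np.asarray(volume, dtype=float)
    atlas = np.asarray(atlas)
    if volume.shape != atlas.shape:
        raise ValueError("map and atlas must share the same grid")
    valid = np.isfinite(volume)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    if n_regions is None:
        n_regions = int(atlas.max())
    out = np.full(n_regions, np.nan)
    for label in range(1, n_regions + 1):
        sel = (atlas == label) & valid
        if sel.any():
            out[label - 1] = volume[sel].mean()
        else:
            logger.warning("region %d has no valid voxels", label)
    return out


def assemble_block(
    maps: dict,
    atlas: np.ndarray,
    modality: str,
    subjects: list | None = None,
    mask: np.ndarray | None = None,
    n_regions: int | None = None,
) -> BlockMatrix:
    """Stack per-subject ROI mean vectors into one subject x ROI block.

    ``maps`` maps subject id to a 3D volume; rows follow ``subjects`` order
    (default: ``maps`` insertion order), columns ascending atlas label.
    """
    if subjects is None:
        subjects = list(maps)
    missing = [s for s in subjects if s not in maps]
    if missing:
        raise ValueError(f"missing subject map(s): {', '.join(map(str, missing))}")
    if n_regions is None:
        n_regions = int(np.asarray(atlas).max())
    rows = [extract_roi_means(maps[s], atlas, mask=mask, n_regions=n_regions)
            for s in subjects]
    data = pd.DataFrame(
        np.vstack(rows), index=pd.Index(subjects, name="subject"),
        columns=[f"roi{label:02d}" for label in range(1, n_regions + 1)],
    )
    return BlockMatrix(modality=modality, data=data, zscored=False)


def zscore_block(block: BlockMatrix) -> BlockMatrix:
    """Standardise each column across subjects (sample sd, n-1 denominator).

    Zero-variance columns are set to 0 and flagged rather than dropped, so
    the ROI-column contract is preserved.  Idempotent on already-standardised
    input.
    """
    x = block.values
    if x.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 subjects")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    degenerate = np.where(sd == 0)[0]
    z = np.zeros_like(x)
    ok = sd > 0
    z[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
    return BlockMatrix(
        modality=block.modality,
        data=pd.DataFrame(z, index=block.data.index, columns=block.data.columns),
        zscored=True,
        degenerate_features=[block.data.columns[i] for i in degenerate],
    )
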
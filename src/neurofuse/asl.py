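"""Cerebral blood flow quantification from pseudo-continuous ASL.

The control - label difference signal dM is converted to CBF with the
single-compartment kinetic model in its consensus form::

    CBF = 6000 * lambda * dM * exp(PLD / T1b)
          / (2 * alpha * T1b * M0 * (1 - exp(-tau / T1b)))

in mL/100 g/min, where lambda is the blood-tissue water partition
coefficient, alpha the labeling efficiency, tau the labeling duration, PLD
the post-labeling delay and T1b the longitudinal relaxation time of arterial
blood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ASLConstants",
    "ASLSeries",
    "split_and_subtract",
    "mean_baseline",
    "quantify_cbf",
    "delta_m_for_cbf",
]

logger = logging.getLogger(__name__)


@dataclass
class ASLConstants:
    """Quantification constants of the single-compartment kinetic model.

    Defaults: labeling duration 1.8 s, post-labeling delay 2.0 s, partition
    coefficient 0.9 mL/g, labeling efficiency 0.85, blood T1 1.650 s.
    """

    label_duration: float = 1.8  # s
    post_label_delay: float = 2.0  # s
    partition_coefficient: float = 0.9  # mL/g
    label_efficiency: float = 0.85
    t1_blood: float = 1.650  # s

    def __post_init__(self) -> None:
        for name in ("label_duration", "post_label_delay",
                     "partition_coefficient", "label_efficiency", "t1_blood"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.label_efficiency > 1:
            raise ValueError("label_efficiency must be in (0, 1]")

    def scaling(self) -> float:
        """The factor c such that CBF = c * dM / M0."""
        return (
            6000.0
            * self.partition_coefficient
            * np.exp(self.post_label_delay / self.t1_blood)
            / (
                2.0
                * self.label_efficiency
                * self.t1_blood
                * (1.0 - np.exp(-self.label_duration / self.t1_blood))
            )
        )


@dataclass
class ASLSeries:
    """Interleaved control/label pCASL time series with its M0 reference."""

    data: np.ndarray  # 4D, (x, y, z, volume)
    m0: np.ndarray  # 3D
    constants: ASLConstants
    label_order: str = "control-first"  # or "label-first"

    def __post_init__(self) -> None:
        if self.data.shape[-1] % 2 != 0:
            raise ValueError("ASL series must contain an even volume count")
        if self.label_order not in ("control-first", "label-first"):
            raise ValueError(f"unknown label order {self.label_order!r}")


def split_and_subtract(series: ASLSeries) -> np.ndarray:
    """Perfusion-weighted difference dM = mean(control) - mean(label)."""
    data = np.asarray(series.data, dtype=float)
    if data.shape[-1] % 2 != 0:
        raise ValueError("ASL series must contain an even volume count")
    if series.label_order == "control-first":
        control, label = data[..., 0::2], data[..., 1::2]
    else:
        control, label = data[..., 1::2], data[..., 0::2]
    return control.mean(axis=-1) - label.mean(axis=-1)


def mean_baseline(series: np.ndarray | ASLSeries) -> np.ndarray:
    """Voxelwise arithmetic mean over all volumes of the time series."""
    data = series.data if isinstance(series, ASLSeries) else series
    data = np.asarray(data, dtype=float)
    if data.ndim < 1 or data.shape[-1] < 1:
        raise ValueError("need at least one volume")
    return data.mean(axis=-1)


def quantify_cbf(
    dm: np.ndarray,
    m0: np.ndarray,
    constants: ASLConstants | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """CBF map (mL/100 g/min) from the difference signal and the M0 volume.

    Voxels with non-positive M0 are masked out (NaN) and counted in the log.
    """
    constants = constants or ASLConstants()
    dm = np.asarray(dm, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    valid = m0 > 0
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    n_bad = int(np.sum(~valid)) if mask is None else int(np.sum(mask & (m0 <= 0)))
    if n_bad:
        logger.info("quantify_cbf: %d voxels with non-positive M0 masked out", n_bad)
    cbf = np.full(dm.shape, np.nan)
    cbf[valid] = constants.scaling() * dm[valid] / m0[valid]
    return cbf


def delta_m_for_cbf(
    cbf: np.ndarray, m0: np.ndarray, constants: ASLConstants | None = None
) -> np.ndarray:
    """Invert the kinetic model: the dM that quantifies to the given CBF."""
    constants = constants or ASLConstants()
    return np.asarray(cbf, dtype=float) * np.asarray(m0, dtype=float) / constants.scaling()
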
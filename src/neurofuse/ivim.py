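"""Tri-exponential intravoxel incoherent motion (IVIM) model fitting.

The diffusion-weighted signal is modelled as a mixture of three mono-exponential
decays::

    S(b) / S0 = F_p exp(-b D_p) + F_f exp(-b D_f) + F_s exp(-b D_s)

with non-negative signal fractions summing to one: a fast, perfusion-related
pseudo-diffusion pool (``F_p``, ``D_p``), an intermediate free-water-like pool
(``F_f``, ``D_f``) and a slow pool of restricted tissue diffusion
(``F_s``, ``D_s``).

Fitting is a two-step constrained procedure:

1.  ``D_s`` is seeded from a log-linear mono-exponential fit restricted to
    high b-values (b >= 1000 s/mm^2), where the faster pools have decayed away.
2.  The full model is fitted to all b-value shells by bounded nonlinear least
    squares with ``D_f`` fixed at the free-water diffusivity (3e-3 mm^2/s) and
    the simplex constraint enforced exactly through the reparameterisation
    ``F_s = 1 - F_p - F_f``.

Shells are direction-averaged before fitting; the decay is treated as
isotropic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TriExpFitConfig",
    "TriExpParamMap",
    "triexp_signal",
    "shell_average",
    "fit_monoexp_ds",
    "fit_triexp_voxel",
    "fit_triexp_volume",
]

logger = logging.getLogger(__name__)


@dataclass
class TriExpFitConfig:
    """Bounds, initial values and options for the two-step tri-exponential fit.

    Diffusivities are in mm^2/s.  The defaults encode the physiologically
    plausible ranges used for brain tissue: slow (tissue) diffusion in
    [1e-5, 3e-3], pseudo-diffusion in [3e-3, 0.2], and the free-water
    diffusivity fixed at 3e-3.
    """

    ds_bounds: tuple[float, float] = (1e-5, 3e-3)
    ds_init: float = 1e-3
    dp_bounds: tuple[float, float] = (3e-3, 0.2)
    dp_init: float = 1e-2
    df_fixed: float = 3e-3
    high_b_threshold: float = 1000.0
    fractions_init: tuple[float, float] = (0.1, 0.1)  # (F_p, F_f); F_s = 0.8
    #: keep D_s free in step 2 (initialised at the step-1 estimate); if True,
    #: D_s is clamped to the step-1 value instead.
    fix_ds_to_step1: bool = False
    #: refit S0 as a free scale factor; by default S0 is fixed to the b0 mean.
    refit_s0: bool = False
    max_iter: int = 400
    tol: float = 1e-14
    #: b0 dropout threshold = dropout_factor * estimated noise floor.
    dropout_factor: float = 5.0

    def __post_init__(self) -> None:
        if not (self.ds_bounds[1] <= self.df_fixed <= self.dp_bounds[0]):
            raise ValueError(
                "compartment ordering violated: require "
                "ds_upper <= df_fixed <= dp_lower"
            )


@dataclass
class TriExpParamMap:
    """Voxelwise tri-exponential parameter maps plus fit diagnostics.

    All arrays share the spatial grid.  ``excluded`` marks voxels outside the
    mask or rejected for signal dropout; ``converged`` is False where the
    optimiser failed (parameters are NaN there, never silently wrong).
    """

    f_p: np.ndarray
    f_f: np.ndarray
    f_s: np.ndarray
    d_p: np.ndarray
    d_f: np.ndarray
    d_s: np.ndarray
    s0: np.ndarray
    residual_rms: np.ndarray
    converged: np.ndarray
    excluded: np.ndarray
    ds_clipped: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.f_p.shape

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "F_p": self.f_p,
            "F_f": self.f_f,
            "F_s": self.f_s,
            "D_p": self.d_p,
            "D_f": self.d_f,
            "D_s": self.d_s,
        }


def triexp_signal(b, f_p, f_f, f_s, d_p, d_f, d_s):
    """Relative signal S(b)/S0 of the tri-exponential decay.

    Broadcasts over ``b`` and the parameters; at b=0 the value is the sum of
    the fractions (1 on the simplex).
    """
    b = np.asarray(b, dtype=float)
    return (
        f_p * np.exp(-b * d_p)
        + f_f * np.exp(-b * d_f)
        + f_s * np.exp(-b * d_s)
    )


def shell_average(signal: np.ndarray, b_per_volume: np.ndarray):
    """Average the signal over the directions of each b-value shell.

    Parameters
    ----------
    signal : array, shape (..., n_volumes)
        Signal with volumes on the last axis.
    b_per_volume : array, shape (n_volumes,)
        The b-value of each volume (0 for unweighted volumes).

    Returns
    -------
    shell_b : array, shape (n_shells,)
        Distinct b-values in ascending order (b=0 included).
    shell_mean : array, shape (..., n_shells)
        Arithmetic mean over each shell's volumes.
    """
    b_per_volume = np.asarray(b_per_volume, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if signal.shape[-1] != b_per_volume.size:
        raise ValueError(
            f"signal has {signal.shape[-1]} volumes but b table has "
            f"{b_per_volume.size} entries"
        )
    shell_b = np.unique(b_per_volume)
    means = np.empty(signal.shape[:-1] + (shell_b.size,), dtype=float)
    for i, b in enumerate(shell_b):
        sel = b_per_volume == b
        if not sel.any():  # pragma: no cover - unique() guarantees non-empty
            raise ValueError(f"empty shell at b={b}")
        means[..., i] = signal[..., sel].mean(axis=-1)
    return shell_b, means


def fit_monoexp_ds(shell_signal, shell_b, config: TriExpFitConfig | None = None):
    """Step 1: log-linear mono-exponential fit over the high-b shells.

    Fits ``ln S = ln S0_high - b D_s`` by ordinary least squares on the shells
    with ``b >= high_b_threshold``.  The slope estimate is clipped into the
    configured D_s bounds.

    Returns
    -------
    d_s : float
        Slow diffusivity estimate (clipped into bounds), NaN if the voxel is
        unusable (non-positive signal in the high-b subset).
    s0_high : float
        Intercept of the high-b decay (extrapolated signal at b=0).
    clipped : bool
        True if the raw slope fell outside the bounds.
    ok : bool
        False if the voxel was excluded.
    """
    config = config or TriExpFitConfig()
    shell_b = np.asarray(shell_b, dtype=float)
    shell_signal = np.asarray(shell_signal, dtype=float)
    sel = shell_b >= config.high_b_threshold
    if sel.sum() < 2:
        raise ValueError(
            f"need >= 2 shells with b >= {config.high_b_threshold}, "
            f"got {int(sel.sum())}"
        )
    y = shell_signal[sel]
    if np.any(y <= 0) or not np.all(np.isfinite(y)):
        return np.nan, np.nan, False, False
    slope, intercept = np.polyfit(shell_b[sel], np.log(y), 1)
    d_s_raw = -slope
    d_s = float(np.clip(d_s_raw, *config.ds_bounds))
    clipped = not (config.ds_bounds[0] <= d_s_raw <= config.ds_bounds[1])
    return d_s, float(np.exp(intercept)), clipped, True


def _triexp_residual_factory(shell_b, y, d_f, w):
    """Weighted residual and Jacobian for the free vector (F_p, F_f, D_p, D_s).

    ``w`` weights each shell's residual; shell means of n directions have
    variance sigma^2/n, so w = sqrt(n) is the generalized-least-squares
    weighting.
    """
    b = shell_b

    def resid(x):
        f_p, f_f, d_p, d_s = x
        e_p = np.exp(-b * d_p)
        e_f = np.exp(-b * d_f)
        e_s = np.exp(-b * d_s)
        return w * (f_p * e_p + f_f * e_f + (1.0 - f_p - f_f) * e_s - y)

    def jac(x):
        f_p, f_f, d_p, d_s = x
        e_p = np.exp(-b * d_p)
        e_f = np.exp(-b * d_f)
        e_s = np.exp(-b * d_s)
        f_s = 1.0 - f_p - f_f
        return w[:, None] * np.stack(
            [e_p - e_s, e_f - e_s, -b * f_p * e_p, -b * f_s * e_s], axis=-1
        )

    return resid, jac


def _boundary_residual_factory(shell_b, y, d_f, w):
    """Residual/Jacobian on the F_s = 0 face: model F_p e^-bDp + (1-F_p) e^-bDf."""
    b = shell_b

    def resid(x):
        f_p, d_p = x
        return w * (f_p * np.exp(-b * d_p) + (1.0 - f_p) * np.exp(-b * d_f) - y)

    def jac(x):
        f_p, d_p = x
        e_p = np.exp(-b * d_p)
        return w[:, None] * np.stack(
            [e_p - np.exp(-b * d_f), -b * f_p * e_p], axis=-1
        )

    return resid, jac


def fit_triexp_voxel(
    shell_signal,
    shell_b,
    ds_seed: float,
    config: TriExpFitConfig | None = None,
    shell_weights=None,
) -> dict:
    """Step 2: bounded nonlinear least squares of the full model on all shells.

    The signal is normalised by the b0 shell mean; ``D_f`` is fixed and the
    simplex is enforced exactly via ``F_s = 1 - F_p - F_f``.  If the optimum
    implies a negative ``F_s`` the voxel is re-solved on the simplex boundary
    (``F_s = 0``).  ``shell_weights`` (default: uniform) weight the shell
    residuals; passing sqrt(directions-per-shell) gives each acquired volume
    equal influence.

    Returns a record with keys ``F_p, F_f, F_s, D_p, D_f, D_s, S0,
    residual_rms, converged, ds_clipped, boundary``.
    """
    config = config or TriExpFitConfig()
    shell_b = np.asarray(shell_b, dtype=float)
    shell_signal = np.asarray(shell_signal, dtype=float)
    b0_sel = shell_b == 0
    if not b0_sel.any():
        raise ValueError("no b=0 shell present")
    s0 = float(shell_signal[b0_sel].mean())
    if not (s0 > 0 and np.isfinite(s0)):
        raise ValueError("non-positive b0 signal")
    y = shell_signal / s0

    nan_rec = {
        "F_p": np.nan, "F_f": np.nan, "F_s": np.nan,
        "D_p": np.nan, "D_f": config.df_fixed, "D_s": np.nan,
        "S0": s0, "residual_rms": np.nan,
        "converged": False, "ds_clipped": False, "boundary": False,
    }

    if not np.isfinite(ds_seed):
        ds_seed = config.ds_init
    ds_lo, ds_hi = config.ds_bounds
    ds_seed = float(np.clip(ds_seed, ds_lo, ds_hi))

    if shell_weights is None:
        w = np.ones_like(shell_b)
    else:
        w = np.asarray(shell_weights, dtype=float)
    resid, jac = _triexp_residual_factory(shell_b, y, config.df_fixed, w)
    f_p0, f_f0 = config.fractions_init
    if config.fix_ds_to_step1:
        # shrink the D_s box to the step-1 estimate (tiny slack keeps lo < hi)
        eps = max(1e-12, 1e-9 * ds_seed)
        lo = [0.0, 0.0, config.dp_bounds[0], max(ds_lo, ds_seed - eps)]
        hi = [1.0, 1.0, config.dp_bounds[1], min(ds_hi, ds_seed + eps)]
    else:
        lo = [0.0, 0.0, config.dp_bounds[0], ds_lo]
        hi = [1.0, 1.0, config.dp_bounds[1], ds_hi]
    x0 = np.clip([f_p0, f_f0, config.dp_init, ds_seed], lo, hi)

    try:
        sol = least_squares(
            resid, x0, jac=jac, bounds=(lo, hi), method="trf",
            x_scale=[0.1, 0.1, 1e-2, 1e-3],
            xtol=config.tol, ftol=config.tol, gtol=config.tol,
            max_nfev=config.max_iter,
        )
    except Exception:  # pragma: no cover - optimizer pathologies
        return nan_rec
    f_p, f_f, d_p, d_s = sol.x
    boundary = False
    if 1.0 - f_p - f_f < -1e-12:
        # re-solve on the active simplex face F_s = 0
        boundary = True
        resid_b, jac_b = _boundary_residual_factory(shell_b, y, config.df_fixed, w)
        sol_b = least_squares(
            resid_b, [min(f_p, 1.0), d_p],
            jac=jac_b, bounds=([0.0, config.dp_bounds[0]], [1.0, config.dp_bounds[1]]),
            method="trf", x_scale=[0.1, 1e-2],
            xtol=config.tol, ftol=config.tol, gtol=config.tol,
            max_nfev=config.max_iter,
        )
        f_p, d_p = sol_b.x
        f_f = 1.0 - f_p
        d_s = ds_seed  # D_s unidentifiable with F_s = 0; keep the seed
        res = sol_b.fun / w
        converged = sol_b.status > 0
    else:
        res = sol.fun / w
        converged = sol.status > 0
    f_s = max(0.0, 1.0 - f_p - f_f)
    if not converged:
        return nan_rec
    return {
        "F_p": float(f_p), "F_f": float(f_f), "F_s": float(f_s),
        "D_p": float(d_p), "D_f": config.df_fixed, "D_s": float(d_s),
        "S0": s0,
        "residual_rms": float(np.sqrt(np.mean(res**2))),
        "converged": True,
        "ds_clipped": False,
        "boundary": boundary,
    }


def _estimate_noise_floor(signal, b_per_volume, mask):
    """Noise sigma from the spread between repeated b0 volumes (0 if single b0)."""
    b0 = signal[..., np.asarray(b_per_volume) == 0]
    if b0.shape[-1] < 2:
        return 0.0
    sd = b0.std(axis=-1, ddof=1)
    vals = sd[mask]
    return float(np.median(vals)) if vals.size else 0.0


def fit_triexp_volume(
    signal: np.ndarray,
    b_per_volume: np.ndarray,
    mask: np.ndarray | None = None,
    config: TriExpFitConfig | None = None,
) -> TriExpParamMap:
    """Fit the tri-exponential model voxelwise over a 4D volume.

    Applies shell averaging, the step-1 mono-exponential D_s seed and the
    step-2 constrained fit to every voxel inside ``mask``.  Voxels whose b0
    mean falls below ``dropout_factor`` times the estimated noise floor are
    excluded as signal dropouts.
    """
    config = config or TriExpFitConfig()
    signal = np.asarray(signal, dtype=float)
    if mask is None:
        mask = np.ones(signal.shape[:-1], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        shape = signal.shape[:-1]
        nanvol = np.full(shape, np.nan)
        logger.info("fit_triexp_volume: empty mask, 0 voxels fitted")
        return TriExpParamMap(
            f_p=nanvol.copy(), f_f=nanvol.copy(), f_s=nanvol.copy(),
            d_p=nanvol.copy(), d_f=nanvol.copy(), d_s=nanvol.copy(),
            s0=nanvol.copy(), residual_rms=nanvol.copy(),
            converged=np.zeros(shape, dtype=bool),
            excluded=np.ones(shape, dtype=bool),
            ds_clipped=np.zeros(shape, dtype=bool),
        )

    shell_b, shell_mean = shell_average(signal, b_per_volume)
    counts = np.array([(np.asarray(b_per_volume) == b).sum() for b in shell_b])
    shell_weights = np.sqrt(counts.astype(float))
    shape = signal.shape[:-1]
    out = {k: np.full(shape, np.nan) for k in
           ("f_p", "f_f", "f_s", "d_p", "d_f", "d_s", "s0", "residual_rms")}
    converged = np.zeros(shape, dtype=bool)
    excluded = ~mask
    ds_clipped = np.zeros(shape, dtype=bool)

    noise_floor = _estimate_noise_floor(signal, b_per_volume, mask)
    dropout_thr = config.dropout_factor * noise_floor
    logger.info(
        "fit_triexp_volume: noise floor %.4g, dropout threshold %.4g",
        noise_floor, dropout_thr,
    )

    b0_mean = shell_mean[..., shell_b == 0].mean(axis=-1)
    n_fit = n_drop = n_fail = 0
    for idx in np.argwhere(mask):
        tidx = tuple(idx)
        if not (b0_mean[tidx] > dropout_thr and np.isfinite(b0_mean[tidx])):
            excluded[tidx] = True
            n_drop += 1
            continue
        d_s_seed, _, clipped, ok = fit_monoexp_ds(
            shell_mean[tidx], shell_b, config
        )
        if not ok:
            excluded[tidx] = True
            n_drop += 1
            continue
        rec = fit_triexp_voxel(shell_mean[tidx], shell_b, d_s_seed, config,
                               shell_weights=shell_weights)
        out["f_p"][tidx] = rec["F_p"]
        out["f_f"][tidx] = rec["F_f"]
        out["f_s"][tidx] = rec["F_s"]
        out["d_p"][tidx] = rec["D_p"]
        out["d_f"][tidx] = rec["D_f"]
        out["d_s"][tidx] = rec["D_s"]
        out["s0"][tidx] = rec["S0"]
        out["residual_rms"][tidx] = rec["residual_rms"]
        converged[tidx] = rec["converged"]
        ds_clipped[tidx] = clipped
        n_fit += rec["converged"]
        n_fail += not rec["converged"]
    logger.info(
        "fit_triexp_volume: %d fitted, %d excluded, %d non-converged",
        n_fit, n_drop, n_fail,
    )
    return TriExpParamMap(
        f_p=out["f_p"], f_f=out["f_f"], f_s=out["f_s"],
        d_p=out["d_p"], d_f=out["d_f"], d_s=out["d_s"],
        s0=out["s0"], residual_rms=out["residual_rms"],
        converged=converged, excluded=excluded, ds_clipped=ds_clipped,
    )
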
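"""Synthetic cohort, phantom and block-matrix generators.

Everything the pipeline consumes can be generated here: a diffusion
acquisition scheme matching the multi-shell IVIM protocol, voxel phantoms
with region-wise tri-exponential and perfusion ground truth, noisy DWI and
pCASL series simulated through the forward models, subject tables with group
labels and GOS-E outcome scores, directly constructed subject x ROI block
matrices with planted latent structure, and two-visit replicates with
controlled variance components.

Group effects emulate the mild-traumatic-brain-injury phenotype: reduced
perfusion (lower CBF and F_p) with a compensatory rise of the tissue
fraction F_s in designated (subcortical-like) regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .asl import ASLConstants, ASLSeries, delta_m_for_cbf
from .ivim import TriExpFitConfig, triexp_signal

__all__ = [
    "AcquisitionScheme",
    "PhantomSpec",
    "GroundTruth",
    "build_acquisition_scheme",
    "fibonacci_directions",
    "make_atlas",
    "make_cohort",
    "generate_phantom",
    "simulate_dwi",
    "simulate_asl",
    "simulate_block_matrices",
    "simulate_retest",
    "simulate_retest_maps",
    "synthesize_gose",
]

#: directions per non-zero b-value (s/mm^2) of the multi-shell IVIM protocol
PROTOCOL_DIRECTIONS = {
    10: 3, 25: 3, 35: 3, 50: 3, 75: 3, 100: 3, 200: 3,
    500: 10, 750: 10, 1000: 20, 1500: 5, 2000: 5, 2500: 5, 3000: 5,
}


@dataclass
class AcquisitionScheme:
    """Multi-shell diffusion acquisition: b-values, per-shell direction counts
    and unit direction vectors, plus the number of unweighted (b0) volumes."""

    b_values: np.ndarray  # distinct non-zero b, ascending (s/mm^2)
    directions_per_b: np.ndarray  # counts aligned with b_values
    direction_vectors: np.ndarray  # (n_weighted, 3) unit vectors, shell-ordered
    n_b0: int = 2

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.directions_per_b = np.asarray(self.directions_per_b, dtype=int)
        self.direction_vectors = np.asarray(self.direction_vectors, dtype=float)
        if np.any(self.b_values < 0):
            raise ValueError("b-values must be non-negative")
        if self.direction_vectors.shape != (self.n_weighted, 3):
            raise ValueError("direction vector count must equal the sum of "
                             "per-shell direction counts")
        norms = np.linalg.norm(self.direction_vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("direction vectors must have unit norm")

    @property
    def n_weighted(self) -> int:
        return int(self.directions_per_b.sum())

    @property
    def n_volumes(self) -> int:
        return self.n_b0 + self.n_weighted

    @property
    def b_per_volume(self) -> np.ndarray:
        """b-value of every volume: b0 volumes first, then shells ascending."""
        return np.concatenate([
            np.zeros(self.n_b0),
            np.repeat(self.b_values, self.directions_per_b),
        ])

    @property
    def bvec_per_volume(self) -> np.ndarray:
        """(n_volumes, 3) direction table; zero vectors for b0 volumes."""
        return np.vstack([np.zeros((self.n_b0, 3)), self.direction_vectors])


def fibonacci_directions(n: int, shell_index: int = 0) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors via the golden-angle spiral.

    Points are placed on the upper hemisphere only, since antipodal gradient
    directions sample the same diffusion displacement.  ``shell_index``
    rotates the spiral start so that different shells do not share
    directions.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n, dtype=float)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = (i + 0.5) / n  # hemisphere: z in (0, 1]
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = golden * i + 0.61803398875 * shell_index
    vecs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return vecs / np.linalg.norm(vecs, axis=1, keepdims=True)


def build_acquisition_scheme() -> AcquisitionScheme:
    """The 14-shell IVIM protocol: 81 weighted directions plus 2 b0 volumes.

    3 directions at b in {10, 25, 35, 50, 75, 100, 200}; 10 at {500, 750};
    20 at 1000; 5 at {1500, 2000, 2500, 3000} s/mm^2.
    """
    b_values = np.array(sorted(PROTOCOL_DIRECTIONS), dtype=float)
    counts = np.array([PROTOCOL_DIRECTIONS[int(b)] for b in b_values])
    vecs = np.vstack([
        fibonacci_directions(c, shell_index=i) for i, c in enumerate(counts)
    ])
    return AcquisitionScheme(b_values=b_values, directions_per_b=counts,
                             direction_vectors=vecs, n_b0=2)


# ---------------------------------------------------------------------------
# phantom ground truth


@dataclass
class PhantomSpec:
    """Ground-truth design for the imaging phantom.

    Base parameter values are typical brain-tissue magnitudes; regions vary
    around them by ``regional_spread`` (relative sd, the "anatomy", shared by
    all subjects) and subjects vary around their region values by
    ``subject_jitter`` (relative sd).  ``group_effect`` maps a metric name
    (``CBF``, ``F_p``, ``F_f``, ``F_s``, ``D_p``, ``D_s``) to a relative
    shift applied to mTBI subjects inside ``affected_regions`` (1-based atlas
    labels); fractions are re-normalised to the simplex after shifting.
    """

    shape: tuple[int, int, int] = (24, 24, 12)
    n_regions: int = 90
    f_p: float = 0.10
    f_f: float = 0.20
    d_p: float = 2.0e-2  # mm^2/s
    d_s: float = 7.0e-4  # mm^2/s
    cbf: float = 50.0  # mL/100 g/min
    regional_spread: float = 0.10
    subject_jitter: float = 0.05
    group_effect: dict = field(default_factory=lambda: {
        "CBF": -0.15, "F_p": -0.15, "F_s": +0.03,
    })
    affected_regions: tuple = tuple(range(70, 91))  # subcortical-like parcels
    snr: float = 100.0
    seed: int = 0

    @property
    def f_s(self) -> float:
        return 1.0 - self.f_p - self.f_f

    def validate(self) -> None:
        if min(self.f_p, self.f_f, self.f_s) < 0:
            raise ValueError("fractions must be non-negative and sum to 1")
        fit = TriExpFitConfig()
        if not (fit.ds_bounds[0] <= self.d_s <= fit.ds_bounds[1]):
            raise ValueError("d_s outside the tri-exponential fit bounds")
        if not (fit.dp_bounds[0] <= self.d_p <= fit.dp_bounds[1]):
            raise ValueError("d_p outside the tri-exponential fit bounds")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        if int(np.prod(self.shape)) < self.n_regions:
            raise ValueError("grid too small for the requested region count")


def make_atlas(shape, n_regions: int = 90) -> np.ndarray:
    """Integer-labelled atlas of ``n_regions`` contiguous equal-size parcels
    (labels 1..n_regions, 0 reserved for background; none emitted here)."""
    n_vox = int(np.prod(shape))
    if n_vox < n_regions:
        raise ValueError("grid too small for the requested region count")
    flat = np.zeros(n_vox, dtype=np.int16)
    for label, idx in enumerate(np.array_split(np.arange(n_vox), n_regions), 1):
        flat[idx] = label
    return flat.reshape(shape)


def make_cohort(
    n_hc: int = 24,
    n_mtbi: int = 19,
    n_retest: int = 11,
    seed: int = 0,
) -> pd.DataFrame:
    """Subject table emulating the study cohort.

    24 HC (12 female, age ~ 29.4 +/- 6.2 y) and 19 mTBI (10 female, age ~
    28.0 +/- 7.7 y); mTBI subjects carry a GOS-E outcome score in the
    6.4 +/- 1.1 regime (integers 3..8); the first ``n_retest`` HC subjects
    are flagged for a second visit.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_hc_f = round(n_hc * 12 / 24)
    n_tbi_f = round(n_mtbi * 10 / 19)
    for i in range(n_hc):
        rows.append({
            "subject": f"hc{i + 1:02d}", "group": "HC",
            "sex": "F" if i < n_hc_f else "M",
            "age": float(np.clip(np.round(rng.normal(29.4, 6.2), 1), 18, 60)),
            "gose": np.nan,
            "retest": i < n_retest,
        })
    latent = rng.normal(size=n_mtbi)
    gose = synthesize_gose(latent)
    for i in range(n_mtbi):
        rows.append({
            "subject": f"tbi{i + 1:02d}", "group": "mTBI",
            "sex": "F" if i < n_tbi_f else "M",
            "age": float(np.clip(np.round(rng.normal(28.0, 7.7), 1), 18, 60)),
            "gose": float(gose[i]),
            "retest": False,
        })
    return pd.DataFrame(rows)


def synthesize_gose(source: np.ndarray) -> np.ndarray:
    """Monotone map from a latent source to integer GOS-E scores in 3..8.

    Quantiles of the source are binned with probabilities proportional to a
    discretised normal centred at 6.4 with sd 1.1, so the output distribution
    sits in the observed post-injury outcome regime while remaining a
    deterministic, monotone function of the latent source.
    """
    from scipy.stats import norm, rankdata

    source = np.asarray(source, dtype=float)
    levels = np.arange(3, 9)
    edges = norm.cdf((np.arange(3, 9) + 0.5 - 6.4) / 1.1)
    probs = np.diff(np.concatenate([[norm.cdf((2.5 - 6.4) / 1.1)], edges]))
    probs = probs / probs.sum()
    cum = np.cumsum(probs)
    q = (rankdata(source, method="average") - 0.5) / source.size
    return levels[np.searchsorted(cum, q, side="left").clip(0, levels.size - 1)]


_METRICS = ("F_p", "F_f", "F_s", "D_p", "D_s", "CBF")


def generate_phantom(spec: PhantomSpec, design: pd.DataFrame):
    """Region-wise constant ground-truth maps for every subject in ``design``.

    Returns ``(truth, atlas)`` where ``truth`` maps subject id to a dict of
    3D volumes for F_p, F_f, F_s, D_p, D_s and CBF (plus the scalar subject
    perfusion factor under ``"latent"``).  mTBI subjects receive the
    configured group shifts inside the affected regions; fractions are
    re-normalised to the simplex afterwards.  Identical seeds give
    bit-identical outputs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    atlas = make_atlas(spec.shape, spec.n_regions)
    fit = TriExpFitConfig()

    base = {"F_p": spec.f_p, "F_f": spec.f_f, "F_s": spec.f_s,
            "D_p": spec.d_p, "D_s": spec.d_s, "CBF": spec.cbf}
    # shared anatomy: one regional profile per metric
    region_vals = {
        m: base[m] * (1.0 + spec.regional_spread * rng.standard_normal(spec.n_regions))
        for m in _METRICS
    }
    affected = np.isin(np.arange(1, spec.n_regions + 1), spec.affected_regions)

    truth: dict[str, dict[str, np.ndarray]] = {}
    for _, row in design.drop_duplicates("subject").iterrows():
        latent = float(rng.standard_normal())
        vals = {}
        for m in _METRICS:
            jitter = 1.0 + spec.subject_jitter * rng.standard_normal(spec.n_regions)
            v = region_vals[m] * jitter
            # the subject perfusion factor couples CBF and F_p across regions
            if m in ("CBF", "F_p"):
                v = v * (1.0 + 0.5 * spec.subject_jitter * latent)
            if row["group"] == "mTBI" and m in spec.group_effect:
                v = np.where(affected, v * (1.0 + spec.group_effect[m]), v)
            vals[m] = v
        # re-normalise fractions to the simplex
        total = vals["F_p"] + vals["F_f"] + vals["F_s"]
        for m in ("F_p", "F_f", "F_s"):
            vals[m] = vals[m] / total
        for m, (lo, hi) in (("D_s", fit.ds_bounds), ("D_p", fit.dp_bounds)):
            if np.any(vals[m] < lo) or np.any(vals[m] > hi):
                raise ValueError(
                    f"group effect/jitter pushed {m} outside the fit bounds "
                    f"[{lo}, {hi}] for subject {row['subject']}"
                )
        maps = {m: vals[m][atlas - 1] for m in _METRICS}
        maps["latent"] = latent
        truth[row["subject"]] = maps
    return truth, atlas


# ---------------------------------------------------------------------------
# forward simulation


def simulate_dwi(
    params: dict,
    scheme: AcquisitionScheme,
    snr: float | None = 100.0,
    noise_model: str = "rician",
    seed: int = 0,
    s0: float = 100.0,
) -> np.ndarray:
    """Simulate a 4D DWI series from tri-exponential ground-truth maps.

    ``params`` holds volumes (or scalars) for F_p, F_f, F_s, D_p, D_s and
    optionally D_f (default: free-water 3e-3 mm^2/s).  Rician noise is the
    magnitude of a complex Gaussian perturbation with sigma = s0 / snr.
    """
    if noise_model not in ("rician", "gaussian", "none"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    if noise_model != "none" and (snr is None or snr <= 0):
        raise ValueError("snr must be > 0")
    d_f = params.get("D_f", TriExpFitConfig().df_fixed)
    b = scheme.b_per_volume
    shape = np.broadcast(np.asarray(params["F_p"]), np.asarray(params["F_s"])).shape
    clean = s0 * triexp_signal(
        b.reshape((1,) * len(shape) + (-1,)),
        np.asarray(params["F_p"])[..., None],
        np.asarray(params["F_f"])[..., None],
        np.asarray(params["F_s"])[..., None],
        np.asarray(params["D_p"])[..., None],
        d_f if np.isscalar(d_f) else np.asarray(d_f)[..., None],
        np.asarray(params["D_s"])[..., None],
    )
    if noise_model == "none":
        return clean
    rng = np.random.default_rng(seed)
    sigma = s0 / snr
    if noise_model == "gaussian":
        return clean + rng.normal(0.0, sigma, clean.shape)
    real = clean + rng.normal(0.0, sigma, clean.shape)
    imag = rng.normal(0.0, sigma, clean.shape)
    return np.sqrt(real**2 + imag**2)


def simulate_asl(
    cbf: np.ndarray,
    constants: ASLConstants | None = None,
    n_pairs: int = 10,
    snr: float | None = 50.0,
    seed: int = 0,
    m0_value: float = 1000.0,
) -> ASLSeries:
    """Simulate an interleaved control/label pCASL series from a CBF map.

    The difference signal is obtained by inverting the quantification model at
    the ground-truth CBF; control volumes sit at the M0 baseline and label
    volumes at baseline minus dM.  Gaussian noise with sigma = m0 / snr is
    added per volume (none if ``snr`` is None).
    """
    constants = constants or ASLConstants()
    cbf = np.asarray(cbf, dtype=float)
    m0 = np.full(cbf.shape, m0_value)
    dm = delta_m_for_cbf(cbf, m0, constants)
    vols = []
    for _ in range(n_pairs):
        vols.append(m0.copy())  # control
        vols.append(m0 - dm)  # label
    data = np.stack(vols, axis=-1)
    if snr is not None:
        if snr <= 0:
            raise ValueError("snr must be > 0")
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, m0_value / snr, data.shape)
    return ASLSeries(data=data, m0=m0, constants=constants,
                     label_order="control-first")


# ---------------------------------------------------------------------------
# direct block-matrix construction for fusion tests


@dataclass
class GroundTruth:
    """Planted latent structure behind simulated block matrices."""

    sources: np.ndarray  # (n_subjects, n_sources) subject-mode sources
    patterns: list  # per block: (n_sources, n_features) spatial patterns
    group_labels: np.ndarray | None  # per subject, "HC" / "mTBI"
    group_source: int | None  # source column carrying the group effect
    gose_source: int | None  # source column driving GOS-E


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    out = np.zeros_like(x)
    ok = sd > 0
    out[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
    return out


def simulate_block_matrices(
    n_subjects: int = 43,
    n_rois: int = 90,
    n_sources: int = 3,
    n_blocks: int = 5,
    source_dist: str = "laplace",
    effect_size: float = 0.0,
    noise_sd: float = 0.2,
    sparsity: float = 0.3,
    group_labels: np.ndarray | None = None,
    seed: int = 0,
):
    """Subject x ROI matrices with shared subject-mode latent sources.

    Each block is ``X_b = A S_b + E_b`` with shared sources ``A`` (columns
    i.i.d. unit-variance Laplace by default), block-specific sparse spatial
    patterns ``S_b`` and Gaussian noise.  If ``effect_size`` > 0, source
    column 0 is shifted between the two groups by that many source standard
    deviations.  Output columns are z-scored (mean 0, sd 1).

    Returns ``(blocks, truth)`` where ``blocks`` is a list of z-scored
    (n_subjects, n_rois) arrays and ``truth`` a :class:`GroundTruth`.
    """
    if n_sources > min(n_subjects, n_rois):
        raise ValueError("n_sources must be <= min(n_subjects, n_rois)")
    rng = np.random.default_rng(seed)
    if source_dist == "laplace":
        a = rng.laplace(0.0, 1.0 / np.sqrt(2.0), (n_subjects, n_sources))
    elif source_dist == "uniform":
        a = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), (n_subjects, n_sources))
    else:
        raise ValueError(f"unknown source distribution {source_dist!r}")

    group_source = None
    if effect_size != 0.0:
        if group_labels is None:
            half = n_subjects // 2
            group_labels = np.array(["HC"] * half + ["mTBI"] * (n_subjects - half))
        is_tbi = np.asarray(group_labels) == "mTBI"
        shift = effect_size * (is_tbi.astype(float) - is_tbi.mean())
        a[:, 0] = a[:, 0] + shift
        group_source = 0

    patterns, blocks = [], []
    for b in range(n_blocks):
        mask = rng.random((n_sources, n_rois)) < sparsity
        for s in range(n_sources):  # every source must load somewhere
            if not mask[s].any():
                mask[s, rng.integers(n_rois)] = True
        s_b = mask * rng.normal(0.0, 1.0, (n_sources, n_rois))
        e_b = rng.normal(0.0, noise_sd, (n_subjects, n_rois)) if noise_sd > 0 \
            else np.zeros((n_subjects, n_rois))
        patterns.append(s_b)
        blocks.append(_zscore_columns(a @ s_b + e_b))
    truth = GroundTruth(
        sources=a, patterns=patterns, group_labels=group_labels,
        group_source=group_source,
        gose_source=n_sources - 1 if n_sources else None,
    )
    return blocks, truth


# ---------------------------------------------------------------------------
# test-retest replicates


def simulate_retest(
    mu: float,
    sigma_subject: float,
    sigma_error: float,
    n_subjects: int,
    seed: int = 0,
    n_visits: int = 2,
):
    """Two-visit measurements from the classic variance-components model
    ``y_iv = mu + u_i + e_iv`` with ``u ~ N(0, sigma_subject^2)`` and
    ``e ~ N(0, sigma_error^2)``.

    Returns ``(measurements, theoretical_icc)`` where ``measurements`` has
    shape (n_subjects, n_visits) and the theoretical intraclass correlation
    is ``sigma_subject^2 / (sigma_subject^2 + sigma_error^2)``.
    """
    if sigma_subject < 0 or sigma_error < 0:
        raise ValueError("variance components must be >= 0")
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, sigma_subject, (n_subjects, 1))
    e = rng.normal(0.0, sigma_error, (n_subjects, n_visits))
    total = sigma_subject**2 + sigma_error**2
    icc = sigma_subject**2 / total if total > 0 else np.nan
    return mu + u + e, icc


def simulate_retest_maps(
    shape,
    mu: float,
    sigma_subject,
    sigma_error,
    n_subjects: int,
    seed: int = 0,
):
    """Voxelwise two-visit maps; the variance components may be volumes to
    plant spatially varying reliability.

    Returns ``(visit1, visit2, theoretical_icc_map)`` with visit arrays of
    shape (n_subjects, \\*shape).
    """
    shape = tuple(shape)
    sig_u = np.broadcast_to(np.asarray(sigma_subject, dtype=float), shape)
    sig_e = np.broadcast_to(np.asarray(sigma_error, dtype=float), shape)
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n_subjects,) + shape) * sig_u
    v1 = mu + u + rng.standard_normal((n_subjects,) + shape) * sig_e
    v2 = mu + u + rng.standard_normal((n_subjects,) + shape) * sig_e
    total = sig_u**2 + sig_e**2
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(total > 0, sig_u**2 / total, np.nan)
    return v1, v2, icc
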
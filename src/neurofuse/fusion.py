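"""Two-stage multimodal fusion: multi-block RGCCA followed by joint ICA.

Stage 1 is regularized generalized canonical correlation analysis (RGCCA)
over B subject-aligned blocks X_1..X_B.  With per-block shrinkage tau = 1
the criterion is covariance-based (PLS-like): maximise

    sum_{b != c} c_bc * g( cov(X_b w_b, X_c w_c) )

over unit-norm weight vectors w_b, where ``c`` is the block connectivity
design (full off-diagonal by default) and ``g`` the scheme function
(factorial g(x) = x^2 by default; horst g(x) = x and centroid g(x) = |x|
are selectable).  Further components are obtained by deflating each block
against its own canonical variate.  The per-component outer AVE (mean
squared feature-variate correlation within a block) measures the variance a
component explains in each modality and drives component-count selection.

Stage 2 concatenates the canonical variates of all blocks into one
subject x (B*k) joint matrix and decomposes it by ICA (symmetric fixed-point
iteration with the logcosh contrast, i.e. FastICA): joint = loadings @
sources, where the loading columns are the maximally independent subject-mode
components ("IC subject scores") and the source rows their patterns across
the concatenated variates.  Rank-deficient joint matrices (e.g. when a
single-column behavioural block can yield only one non-trivial variate)
reduce the component count to the effective rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .roi import BlockMatrix

__all__ = [
    "FusionConfig",
    "RgccaModel",
    "JicaModel",
    "FusionResult",
    "fit_rgcca",
    "compute_ave",
    "select_n_components",
    "concatenate_variates",
    "fit_jica",
    "fuse",
]

logger = logging.getLogger(__name__)

_SCHEMES = {
    "horst": (lambda x: x, lambda x: np.ones_like(x)),
    "factorial": (lambda x: x**2, lambda x: 2.0 * x),
    "centroid": (np.abs, np.sign),
}


@dataclass
class FusionConfig:
    """Settings for the RGCCA + jICA fusion."""

    n_components: int = 3  # canonical components retained per block
    tau: float = 1.0  # shrinkage; 1 = covariance (PLS-like) criterion
    scheme: str = "factorial"  # horst | factorial | centroid
    connectivity: np.ndarray | None = None  # default: full off-diagonal
    max_iter: int = 500
    tol: float = 1e-10
    ica_seed: int = 0
    n_ic: int | None = None  # default: effective rank of the joint matrix

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")
        if self.tau != 1.0:
            raise NotImplementedError(
                "only the fully regularized criterion (tau = 1) is implemented"
            )
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.scheme not in _SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    def design(self, n_blocks: int) -> np.ndarray:
        if self.connectivity is None:
            c = np.ones((n_blocks, n_blocks)) - np.eye(n_blocks)
        else:
            c = np.asarray(self.connectivity, dtype=float)
            if c.shape != (n_blocks, n_blocks):
                raise ValueError("connectivity shape does not match block count")
            if not np.allclose(c, c.T) or np.any(np.diag(c) != 0):
                raise ValueError("connectivity must be symmetric with zero diagonal")
        return c


@dataclass
class RgccaModel:
    """Fitted RGCCA: per-block weights, canonical variates and diagnostics."""

    weights: list  # per block: (n_features, k)
    variates: list  # per block: (n_subjects, k)
    criterion_trace: list  # per component: list of criterion values
    converged: list  # per component: bool
    block_names: list


@dataclass
class JicaModel:
    """Joint-ICA decomposition ``joint ~= loadings @ sources + mean``."""

    sources: np.ndarray  # (n_ic, n_columns)
    loadings: np.ndarray  # (n_subjects, n_ic)
    unmixing: np.ndarray  # (n_ic, n_columns): loadings = centered @ unmixing.T
    column_mean: np.ndarray
    n_ic: int


@dataclass
class FusionResult:
    rgcca: RgccaModel
    ave: np.ndarray  # (k, n_blocks) outer AVE in percent
    joint: np.ndarray  # (n_subjects, B*k)
    joint_columns: list  # (block, component) provenance per column
    jica: JicaModel
    subjects: list
    block_names: list

    @property
    def ic_scores(self):
        """Per-subject IC score table (subjects x ICs)."""
        import pandas as pd

        k = self.jica.loadings.shape[1]
        return pd.DataFrame(
            self.jica.loadings, index=self.subjects,
            columns=[f"IC{i + 1}" for i in range(k)],
        )


def _as_arrays(blocks):
    names, mats, subjects = [], [], None
    for i, b in enumerate(blocks):
        if isinstance(b, BlockMatrix):
            names.append(b.modality)
            mats.append(b.values)
            subj = list(b.data.index)
        else:
            names.append(f"block{i + 1}")
            mats.append(np.asarray(b, dtype=float))
            subj = None
        if subjects is None and subj is not None:
            subjects = subj
        elif subj is not None and subj != subjects:
            raise ValueError("blocks have mismatched subject indices")
    n = {m.shape[0] for m in mats}
    if len(n) != 1:
        raise ValueError("all blocks must share the subject dimension")
    if subjects is None:
        subjects = list(range(n.pop()))
    return names, mats, subjects


def _leading_right_singular(x: np.ndarray) -> np.ndarray:
    """Deterministic initial weight: leading right singular vector, sign fixed
    so its largest-magnitude element is positive."""
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    w = vt[0]
    i = np.argmax(np.abs(w))
    return w * np.sign(w[i]) if w[i] != 0 else w


def _rgcca_component(mats, design, scheme, max_iter, tol):
    """One covariance-criterion RGCCA component via the block-relaxation update."""
    g, dg = _SCHEMES[scheme]
    n = mats[0].shape[0]
    w = [_leading_right_singular(x) for x in mats]
    y = [x @ wi for x, wi in zip(mats, w)]

    def criterion():
        val = 0.0
        for b in range(len(mats)):
            for c in range(len(mats)):
                if design[b, c]:
                    val += design[b, c] * g(y[b] @ y[c] / n)
        return val

    trace = [criterion()]
    converged = False
    for _ in range(max_iter):
        for b in range(len(mats)):
            z = np.zeros(n)
            for c in range(len(mats)):
                if design[b, c]:
                    z += design[b, c] * dg(y[b] @ y[c] / n) * y[c]
            grad = mats[b].T @ z
            norm = np.linalg.norm(grad)
            if norm > 0:
                w[b] = grad / norm
                y[b] = mats[b] @ w[b]
        trace.append(criterion())
        if abs(trace[-1] - trace[-2]) < tol * max(1.0, abs(trace[-2])):
            converged = True
            break
    return w, y, trace, converged


def _deflate(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Project the block onto the orthogonal complement of its own variate."""
    denom = y @ y
    if denom == 0:
        return x
    return x - np.outer(y, y @ x) / denom


def fit_rgcca(blocks, config: FusionConfig | None = None) -> RgccaModel:
    """Fit multi-block RGCCA (tau = 1) with deflation over components.

    Blocks must be z-scored subject x feature matrices (or
    :class:`~neurofuse.roi.BlockMatrix`) sharing the subject dimension.
    """
    config = config or FusionConfig()
    names, mats, _ = _as_arrays(blocks)
    if len(mats) < 2:
        raise ValueError("need at least two blocks")
    design = config.design(len(mats))
    k = config.n_components
    work = [m.copy() for m in mats]
    weights = [np.zeros((m.shape[1], k)) for m in mats]
    variates = [np.zeros((m.shape[0], k)) for m in mats]
    traces, convs = [], []
    for j in range(k):
        w, y, trace, conv = _rgcca_component(
            work, design, config.scheme, config.max_iter, config.tol
        )
        if not conv:
            logger.warning("RGCCA component %d did not converge", j + 1)
        for b in range(len(mats)):
            weights[b][:, j] = w[b]
            variates[b][:, j] = y[b]
            work[b] = _deflate(work[b], y[b])
        traces.append(trace)
        convs.append(conv)
    return RgccaModel(weights=weights, variates=variates,
                      criterion_trace=traces, converged=convs,
                      block_names=names)


def compute_ave(model: RgccaModel, blocks) -> np.ndarray:
    """Outer AVE table, (k components x B blocks), in percent.

    AVE of component j in block b is the mean over the block's features of
    the squared Pearson correlation between the feature column and the
    block's j-th canonical variate; constant features contribute 0.
    """
    _, mats, _ = _as_arrays(blocks)
    k = model.variates[0].shape[1]
    ave = np.zeros((k, len(mats)))
    for b, x in enumerate(mats):
        xc = x - x.mean(axis=0)
        xn = np.linalg.norm(xc, axis=0)
        for j in range(k):
            y = model.variates[b][:, j]
            yc = y - y.mean()
            yn = np.linalg.norm(yc)
            if yn == 0:
                ave[j, b] = 0.0
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (xc.T @ yc) / (xn * yn)
            r = np.where(xn > 0, r, 0.0)
            ave[j, b] = 100.0 * np.mean(r**2)
    return ave


def select_n_components(
    ave: np.ndarray,
    rule: str = "fixed",
    k: int = 3,
    threshold: float = 5.0,
) -> int:
    """Pick the number of retained components per block from the AVE profile.

    ``fixed`` returns ``k``; ``marginal`` returns the largest component count
    before the cross-block mean marginal AVE first drops below ``threshold``
    percentage points (at least 1).
    """
    ave = np.asarray(ave, dtype=float)
    if rule == "fixed":
        return min(k, ave.shape[0])
    if rule != "marginal":
        raise ValueError(f"unknown rule {rule!r}")
    marginal = ave.mean(axis=1)
    below = np.nonzero(marginal < threshold)[0]
    if below.size:
        return max(1, int(below[0]))
    return ave.shape[0]


def concatenate_variates(model: RgccaModel) -> tuple[np.ndarray, list]:
    """Concatenate canonical variates block-wise into the joint matrix.

    Each variate column is standardised to unit sample variance (exact-zero
    variates from exhausted blocks are left at zero); column provenance
    ``(block_name, component_index)`` is returned alongside.
    """
    cols, prov = [], []
    for b, y in enumerate(model.variates):
        sds = y.std(axis=0, ddof=1)
        # deflation of an exhausted block leaves variates at rounding level;
        # standardising those would fabricate rank, so they stay at zero
        tol = 1e-8 * sds.max() if sds.max() > 0 else 0.0
        for j in range(y.shape[1]):
            v = y[:, j]
            cols.append(v / sds[j] if sds[j] > tol and sds[j] > 0
                        else np.zeros_like(v))
            prov.append((model.block_names[b], j + 1))
    return np.stack(cols, axis=1), prov


def _sym_decorrelate(w: np.ndarray) -> np.ndarray:
    s, u = np.linalg.eigh(w @ w.T)
    return u @ np.diag(1.0 / np.sqrt(np.maximum(s, 1e-30))) @ u.T @ w


def fit_jica(
    joint: np.ndarray,
    n_ic: int | None = None,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-12,
    rank_tol: float = 1e-9,
) -> JicaModel:
    """Joint ICA of the concatenated canonical variates.

    Centers the columns, whitens across subjects by SVD, then runs the
    symmetric fixed-point iteration with the logcosh (tanh) contrast from a
    seeded random orthogonal start.  ``n_ic`` defaults to the effective rank
    of the joint matrix and is reduced to it (with a warning) when the
    requested count exceeds it.  Components are ordered by decreasing loading
    variance and signed so each source row's largest-magnitude element is
    positive.
    """
    x = np.asarray(joint, dtype=float)
    n, p = x.shape
    mean = x.mean(axis=0)
    xc = x - mean
    u, d, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int(np.sum(d > rank_tol * max(d[0], 1e-300)))
    cap = min(rank, n - 1, p)
    if n_ic is None:
        n_ic = cap
    if n_ic > cap:
        logger.warning(
            "requested %d components but effective rank allows %d; reducing",
            n_ic, cap,
        )
        n_ic = cap
    if n_ic < 1:
        raise ValueError("joint matrix has no usable rank")

    # whitened subject-mode coordinates: z has unit covariance over subjects
    z = np.sqrt(n) * u[:, :n_ic]  # (n, n_ic)
    rng = np.random.default_rng(seed)
    w = _sym_decorrelate(rng.standard_normal((n_ic, n_ic)))
    zt = z.T  # (n_ic, n)
    for _ in range(max_iter):
        wz = w @ zt  # (n_ic, n) current source estimates over subjects
        g = np.tanh(wz)
        g_prime = 1.0 - g**2
        w_new = (g @ zt.T) / n - np.diag(g_prime.mean(axis=1)) @ w
        w_new = _sym_decorrelate(w_new)
        delta = np.max(np.abs(np.abs(np.einsum("ij,ij->i", w_new, w)) - 1.0))
        w = w_new
        if delta < tol:
            break
    loadings = z @ w.T  # (n, n_ic): independent subject-mode components
    # least-squares patterns over the joint columns
    sources, *_ = np.linalg.lstsq(loadings, xc, rcond=None)
    # unmixing back to the original columns: loadings = xc @ unmixing.T
    unmixing = (w @ (np.sqrt(n) * np.diag(1.0 / d[:n_ic]) @ vt[:n_ic]))

    order = np.argsort(-sources.var(axis=1) * loadings.var(axis=0, ddof=1))
    loadings, sources, unmixing = loadings[:, order], sources[order], unmixing[order]
    for i in range(n_ic):
        j = np.argmax(np.abs(sources[i]))
        if sources[i, j] < 0:
            sources[i] *= -1.0
            loadings[:, i] *= -1.0
            unmixing[i] *= -1.0
    return JicaModel(sources=sources, loadings=loadings, unmixing=unmixing,
                     column_mean=mean, n_ic=n_ic)


def fuse(blocks, config: FusionConfig | None = None) -> FusionResult:
    """Run the full two-stage fusion: RGCCA -> AVE -> concatenation -> jICA."""
    config = config or FusionConfig()
    names, _, subjects = _as_arrays(blocks)
    model = fit_rgcca(blocks, config)
    ave = compute_ave(model, blocks)
    joint, prov = concatenate_variates(model)
    jica = fit_jica(joint, n_ic=config.n_ic, seed=config.ica_seed)
    return FusionResult(rgcca=model, ave=ave, joint=joint, joint_columns=prov,
                        jica=jica, subjects=subjects, block_names=names)
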
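"""PCA embeddings and the quantitative horseshoe decision.

An embedding is the projection of the column-centered (optionally
unit-variance-scaled) expression matrix onto its top principal axes.
The horseshoe assessment operationalizes the defining signature of the
arch: along the dominant ordering, PC1 is a half-wave sine of the cell's
normalized rank and PC2 a cosine, with both ends of the ordering folded
to similar PC2 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.decomposition import PCA

from .datasets import ExpressionDataset
from .errors import DegenerateDataError, DimensionError, ParameterError
from .model import COS_FREQUENCY, SIN_FREQUENCY, fit_frequency

EXACT_SOLVER_MAX_DIM = 2000


@dataclass
class Embedding:
    """Per-cell component scores with the preprocessing record.

    ``scores`` columns have zero mean; ``component_variances`` are the
    per-component variances, non-increasing.  ``components`` (k x genes)
    and ``mean`` allow exact reconstruction of the centered matrix when
    all components are kept.
    """

    scores: np.ndarray
    component_variances: np.ndarray
    centering: dict = field(default_factory=dict)
    components: Optional[np.ndarray] = None
    mean: Optional[np.ndarray] = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.component_variances = np.asarray(self.component_variances, dtype=float)
        if self.scores.ndim != 2:
            raise DimensionError("scores must be 2-D (cells x components)")
        if self.component_variances.shape[0] != self.scores.shape[1]:
            raise DimensionError("one variance per component required")
        if np.any(np.diff(self.component_variances) > 1e-9):
            raise ParameterError("component variances must be non-increasing")

    @property
    def n_cells(self) -> int:
        return self.scores.shape[0]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class HorseshoeAssessment:
    """Trigonometric fit quality of PC1/PC2 and the arch verdict.

    ``is_horseshoe`` is true iff both R^2 values reach the threshold
    tau; ``score`` is their minimum (clipped to [0, 1]).
    ``endpoint_similarity`` is the PC2 gap between the two ends of the
    ordering relative to the PC2 range -- small for a folded arch.
    """

    r2_pc1_sin: float
    r2_pc2_cos: float
    a_pc1: float
    a_pc2: float
    endpoint_similarity: float
    tau: float
    is_horseshoe: bool
    score: float


def pca_embed(ds: ExpressionDataset, k: int = 2, scale: bool = False) -> Embedding:
    """Project cells onto the top-k principal axes.

    Exact (full SVD) below ``EXACT_SOLVER_MAX_DIM``, truncated solver
    above.  Deterministic up to per-component sign.
    """
    m = ds.matrix
    n, p = m.shape
    if not 1 <= k <= min(n - 1, p):
        raise DimensionError(
            f"k must lie in [1, min(n_cells-1, n_genes)] = [1, {min(n - 1, p)}]")
    col_mean = m.mean(axis=0)
    centered = m - col_mean
    total_var = float(np.sum(centered ** 2))
    if total_var < 1e-300:
        raise DegenerateDataError("matrix is constant across cells")
    col_scale = None
    work = centered
    if scale:
        col_scale = centered.std(axis=0, ddof=1)
        col_scale[col_scale == 0] = 1.0
        work = centered / col_scale
    solver = "full" if min(n, p) <= EXACT_SOLVER_MAX_DIM else "arpack"
    pca = PCA(n_components=k, svd_solver=solver, random_state=0)
    scores = pca.fit_transform(work)
    return Embedding(
        scores=scores,
        component_variances=pca.explained_variance_,
        centering={"centered": True, "scaled": bool(scale)},
        components=pca.components_,
        mean=col_mean if not scale else None,
    )


def _template(component: int, x: np.ndarray) -> np.ndarray:
    """Reference trigonometric template for sign canonicalization."""
    if component == 0:
        return np.sin(SIN_FREQUENCY * (x - 0.5))
    if component == 1:
        return np.cos(COS_FREQUENCY * (x - 0.5))
    # higher components: alternate half-wave harmonics
    k = component + 1
    f = np.sin if component % 2 == 0 else np.cos
    return f(k * np.pi * (x - 0.5))


def canonicalize_signs(e: Embedding, order: np.ndarray) -> Embedding:
    """Flip each component's sign so its correlation with the reference
    trigonometric template along ``order`` is non-negative.  Idempotent."""
    order = _check_order(order, e.n_cells)
    n = e.n_cells
    x = np.arange(n) / (n - 1) if n > 1 else np.zeros(1)
    scores = e.scores.copy()
    for j in range(e.n_components):
        t = _template(j, x)
        v = scores[order, j]
        c = float(np.dot(v - v.mean(), t - t.mean()))
        if c < 0:
            scores[:, j] = -scores[:, j]
    comps = None if e.components is None else e.components.copy()
    return Embedding(scores=scores, component_variances=e.component_variances,
                     centering=dict(e.centering), components=comps, mean=e.mean)


def _check_order(order, n: int) -> np.ndarray:
    order = np.asarray(order, dtype=int)
    if order.shape != (n,) or sorted(order.tolist()) != list(range(n)):
        raise DimensionError(f"order must be a permutation of 0..{n - 1}")
    return order


def horseshoe_score(e: Embedding, order: Optional[np.ndarray] = None,
                    tau: float = 0.8) -> HorseshoeAssessment:
    """Decide whether the embedding traces an arch along ``order``.

    Cells are mapped to normalized rank positions ``x_i = i/(n-1)``
    along the ordering; a sine is fitted to PC1 and a cosine to PC2 by
    least squares over the frequency (via :func:`fit_frequency`).  When
    no ordering is supplied, the arc ordering of a principal curve
    through the embedding is used.
    """
    if e.n_components < 2:
        raise DimensionError("horseshoe assessment needs >= 2 components")
    if not 0.0 < tau < 1.0:
        raise ParameterError("tau must lie in (0, 1)")
    if order is None:
        from .curves import curve_order  # deferred: circular import
        order = curve_order(e)
    order = _check_order(order, e.n_cells)
    pc1 = e.scores[order, 0]
    pc2 = e.scores[order, 1]
    f1 = fit_frequency(pc1, "sin")
    f2 = fit_frequency(pc2, "cos")
    rng2 = float(np.ptp(pc2))
    endpoint = abs(pc2[0] - pc2[-1]) / rng2 if rng2 > 0 else 0.0
    r1 = float(np.clip(f1.r2, 0.0, 1.0))
    r2 = float(np.clip(f2.r2, 0.0, 1.0))
    return HorseshoeAssessment(
        r2_pc1_sin=r1,
        r2_pc2_cos=r2,
        a_pc1=f1.a,
        a_pc2=f2.a,
        endpoint_similarity=endpoint,
        tau=tau,
        is_horseshoe=bool(r1 >= tau and r2 >= tau),
        score=min(r1, r2),
    )
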
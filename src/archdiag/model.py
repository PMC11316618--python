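"""Spectral model of the horseshoe: exponential distance dissimilarity,
classical double centering, and trigonometric eigenfunctions.

For ``n`` cells at uniform positions ``x_i = i/n`` on the unit interval,
the model dissimilarity is ``X(i, j) = 1 - exp(-|i - j|/n)``: distance
grows with separation but *saturates* exponentially.  Double centering
(the classical MDS transform) turns X into a kernel

    K = -1/2 * H X H,       H = I - (1/n) 11^T,

whose eigenvectors are, to numerical precision, sines and cosines of the
position: the first two eigenvectors trace exactly the arch seen in PC
plots of ordered band matrices.  Eigenvalues are reported divided by n
(the Riemann-sum weight), so they converge to the eigenvalues of the
continuous integral operator as n grows.

The module also provides the least-squares frequency fitter used to
quantify how trigonometric an empirical principal component is.

Computed constants at n = 2000 (see ``docs/methods.md``): the leading
normalized eigenvalue is 0.0690 with sine frequency 3.6714, the second
is 0.0239 with cosine frequency 6.386; each pair satisfies the
integral-operator relation lambda = 1/(1 + a^2) to well under 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DimensionError, FitFailureError, ParameterError

#: Printed frequencies of the trigonometric eigenfunction approximations
#: used for the closed-form model embedding (Eqs. of the source model).
SIN_FREQUENCY = 3.1796
COS_FREQUENCY = 4.8989
#: Printed eigenvalues paired with the two frequencies above.
LAMBDA_1 = 0.09
LAMBDA_2 = 0.04

FREQ_SEARCH_MAX = 4.0 * np.pi


@dataclass
class DissimilarityModel:
    """Symmetric model dissimilarity matrix on n uniform positions."""

    n: int
    X: np.ndarray

    def __post_init__(self):
        if self.X.shape != (self.n, self.n):
            raise DimensionError("X must be n x n")


@dataclass
class SpectralModel:
    """Eigenpairs of the centered kernel plus fitted trig frequencies.

    ``eigenvalues`` are normalized by n and sorted descending;
    ``eigenvectors`` holds the matching orthonormal columns,
    sign-canonicalized so each one's first nonzero coordinate is
    positive.
    """

    n: int
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    a1: Optional[float] = None
    a2: Optional[float] = None
    lambda1: Optional[float] = None
    lambda2: Optional[float] = None


@dataclass
class FrequencyFit:
    """Result of a least-squares trigonometric frequency fit."""

    a: float
    r2: float
    amplitude: float
    offset: float
    form: str

    def __iter__(self):  # allow ``a, r2 = fit_frequency(...)``
        return iter((self.a, self.r2))


@dataclass
class TrigEmbedding:
    """Closed-form 2-D model embedding: the arch traced by
    ``(lambda1*f1(x_i), lambda2*f2(x_i))`` over the position grid."""

    n: int
    points: np.ndarray = field(repr=False)


def dissimilarity_matrix(n: int) -> DissimilarityModel:
    """Exponential distance dissimilarity ``X(i,j) = 1 - exp(-|i-j|/n)``."""
    if n < 2:
        raise ParameterError("n must be >= 2")
    i = np.arange(n)
    d = np.abs(i[:, None] - i[None, :]) / n
    return DissimilarityModel(n=n, X=1.0 - np.exp(-d))


def centered_kernel(m: DissimilarityModel, squared: bool = False) -> np.ndarray:
    """Classical double centering ``K = -1/2 H X H``.

    ``squared=True`` applies the transform to the elementwise-squared
    dissimilarities instead (the strict classical-MDS convention for
    metric distances); its spectrum differs and is exposed only for
    comparison.
    """
    X = m.X ** 2 if squared else m.X
    n = m.n
    H = np.eye(n) - np.ones((n, n)) / n
    K = -0.5 * (H @ X @ H)
    return 0.5 * (K + K.T)  # enforce exact symmetry


def _canonical_sign(v: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    nz = np.nonzero(np.abs(v) > tol)[0]
    if nz.size and v[nz[0]] < 0:
        return -v
    return v


def operator_spectrum(K: np.ndarray, k: int) -> SpectralModel:
    """Top-k eigenpairs of the centered kernel.

    Eigenvalues are divided by n so they discretize the continuous
    operator; eigenvectors keep unit norm and are sign-canonicalized.
    """
    n = K.shape[0]
    if K.shape != (n, n):
        raise DimensionError("K must be square")
    if not 1 <= k <= n:
        raise ParameterError("k must lie in [1, n]")
    w, V = np.linalg.eigh(K)
    order = np.argsort(w)[::-1][:k]
    vecs = np.column_stack([_canonical_sign(V[:, j]) for j in order])
    return SpectralModel(n=n, eigenvalues=w[order] / n, eigenvectors=vecs)


def trig_eigenfunction(x, which: int):
    """Closed-form eigenfunction approximations f1 (sine) and f2 (cosine)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ParameterError("x must lie in [0, 1]")
    if which == 1:
        return np.sin(SIN_FREQUENCY * (x - 0.5))
    if which == 2:
        return np.cos(COS_FREQUENCY * (x - 0.5))
    raise ParameterError("which must be 1 or 2")


def model_embedding(n: int) -> TrigEmbedding:
    """2-D arch traced by the closed-form eigenfunctions on the grid
    ``x_i = i/n``, weighted by their printed eigenvalues."""
    if n < 3:
        raise ParameterError("n must be >= 3")
    x = np.arange(n) / n
    pts = np.column_stack([
        LAMBDA_1 * trig_eigenfunction(x, 1),
        LAMBDA_2 * trig_eigenfunction(x, 2),
    ])
    return TrigEmbedding(n=n, points=pts)


def fit_frequency(v: np.ndarray, form: str = "sin",
                  a_max: float = FREQ_SEARCH_MAX,
                  offset: bool = True,
                  grid_points: int = 800) -> FrequencyFit:
    """Least-squares fit of ``c*sin(a(x - 1/2)) [+ b]`` (or cos) to a
    vector over ordered positions ``x_i = i/(n-1)``.

    The frequency is found by a coarse grid search on ``(0, a_max]``
    refined by bounded local optimization; amplitude (and offset, when
    enabled) are profiled out exactly at each candidate frequency.  The
    offset term is on by default because the even eigenfunctions of a
    double-centered kernel are cosines *plus a centering constant*.

    Returns the fitted frequency and the coefficient of determination
    R^2 (1 - SS_res / SS_tot about the mean).
    """
    v = np.asarray(v, dtype=float).ravel()
    n = v.size
    if n < 8:
        raise DimensionError("need at least 8 samples to fit a frequency")
    if form not in ("sin", "cos"):
        raise ParameterError("form must be 'sin' or 'cos'")
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    if ss_tot < 1e-300:
        raise FitFailureError("constant vector: frequency undefined")
    x = np.arange(n) / (n - 1)
    trig = np.sin if form == "sin" else np.cos

    def residual(a: float) -> tuple[float, float, float]:
        s = trig(a * (x - 0.5))
        if offset:
            A = np.column_stack([s, np.ones(n)])
            coef, *_ = np.linalg.lstsq(A, v, rcond=None)
            c, b = float(coef[0]), float(coef[1])
            res = v - A @ coef
        else:
            ss = float(s @ s)
            c = float(s @ v) / ss if ss > 1e-300 else 0.0
            b = 0.0
            res = v - c * s
        return float(res @ res), c, b

    grid = np.linspace(a_max / grid_points, a_max, grid_points)
    losses = np.array([residual(a)[0] for a in grid])
    best = grid[int(np.argmin(losses))]
    half_step = a_max / grid_points
    opt = minimize_scalar(lambda a: residual(a)[0],
                          bounds=(max(1e-6, best - 2 * half_step),
                                  min(a_max, best + 2 * half_step)),
                          method="bounded",
                          options={"xatol": 1e-10})
    a_hat = float(opt.x)
    ss_res, c, b = residual(a_hat)
    return FrequencyFit(a=a_hat, r2=1.0 - ss_res / ss_tot,
                        amplitude=c, offset=b, form=form)


def fit_spectral_model(n: int, squared: bool = False) -> SpectralModel:
    """Full model run: build X, center, eigendecompose, fit frequencies
    of the top two eigenvectors (sine then cosine)."""
    K = centered_kernel(dissimilarity_matrix(n), squared=squared)
    spec = operator_spectrum(K, k=min(10, n))
    f1 = fit_frequency(spec.eigenvectors[:, 0], "sin")
    f2 = fit_frequency(spec.eigenvectors[:, 1], "cos")
    spec.a1, spec.a2 = f1.a, f2.a
    spec.lambda1 = float(spec.eigenvalues[0])
    spec.lambda2 = float(spec.eigenvalues[1])
    return spec


def eigenvalue_convergence(sizes=(250, 500, 1000, 2000), k: int = 2) -> np.ndarray:
    """Normalized top-k eigenvalues across grid sizes (rows follow
    ``sizes``); successive rows approach the continuum limit."""
    out = []
    for n in sizes:
        K = centered_kernel(dissimilarity_matrix(n))
        out.append(operator_spectrum(K, k).eigenvalues)
    return np.array(out)
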
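"""Synthetic expression-matrix generators with ground truth.

Four designs are emulated, each as a cell x gene matrix whose rows are
cells ordered along a known gradient:

* **band A** -- a binary ordered band table: each cell expresses a
  contiguous block of genes, the block sliding along the gene axis with
  the cell index.  The archetypal matrix behind the horseshoe effect.
* **band B** -- a count-valued band: Poisson counts whose means taper
  linearly from the band centre toward its edges, plus sparse off-band
  noise.  A more realistic single-cell-like band.
* **block diagonal** -- discrete cell types with disjoint marker-gene
  blocks; the contrasting design in which no horseshoe arises.
* **no-saturation band** -- an overlapping band (width > half the gene
  count, unit step) with strictly increasing in-band values, built so
  that the euclidean distance from every reference cell grows strictly
  with index separation: a horseshoe without distance saturation.

All generators are deterministic given their seed and attach the
identity ``true_order`` plus a per-cell gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import DimensionError, GenerationError, ParameterError


class ValueModel(str, Enum):
    CONSTANT = "constant"
    COUNTS = "counts"


@dataclass(frozen=True)
class BandSpec:
    """Parameters of an ordered band matrix.

    ``band_width`` is the number of nonzero genes per cell and
    ``band_step`` the column shift between consecutive cells.
    ``noise_rate`` is the off-band nonzero probability (counts model
    only).
    """

    n_cells: int = 100
    n_genes: int = 120
    band_width: int = 20
    band_step: int = 1
    value_model: ValueModel = ValueModel.CONSTANT
    value: float = 1.0
    peak_mean: float = 10.0
    edge_mean: float = 1.0
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1 or self.n_genes < 1:
            raise ParameterError("n_cells and n_genes must be positive")
        if self.band_width < 1:
            raise ParameterError("band_width must be positive")
        if self.band_step < 0:
            raise ParameterError("band_step must be non-negative")
        if self.band_width > self.n_genes:
            raise DimensionError(
                f"band_width <= n_genes violated: {self.band_width} > {self.n_genes}"
            )
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ParameterError("noise_rate must lie in [0, 1]")

    def check_band_fits(self):
        """The last cell's band must not run past the gene range."""
        reach = self.band_width + self.band_step * (self.n_cells - 1)
        if reach > self.n_genes:
            raise DimensionError(
                "band_width + band_step*(n_cells-1) <= n_genes violated: "
                f"{self.band_width} + {self.band_step}*{self.n_cells - 1} = "
                f"{reach} > {self.n_genes}"
            )


@dataclass
class ExpressionDataset:
    """A cells x genes matrix with labels and optional ground truth.

    ``true_order[i]`` is the ground-truth rank of the cell stored in row
    ``i``; sorting rows by ``true_order`` recovers the generated
    ordering.  ``gradient`` holds the per-cell gradient values phi_i.
    ``true_gene_order`` is the analogous rank vector for columns,
    recorded by :func:`shuffle_dataset` so round trips are exact.
    """

    matrix: np.ndarray
    cell_labels: list[str] = field(default_factory=list)
    gene_labels: list[str] = field(default_factory=list)
    true_order: Optional[np.ndarray] = None
    gradient: Optional[np.ndarray] = None
    true_gene_order: Optional[np.ndarray] = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise DimensionError("matrix must be 2-D (cells x genes)")
        n, p = self.matrix.shape
        if not self.cell_labels:
            self.cell_labels = [f"cell_{i}" for i in range(n)]
        if not self.gene_labels:
            self.gene_labels = [f"gene_{j}" for j in range(p)]
        if len(self.cell_labels) != n:
            raise DimensionError(
                f"{len(self.cell_labels)} cell labels for {n} rows")
        if len(self.gene_labels) != p:
            raise DimensionError(
                f"{len(self.gene_labels)} gene labels for {p} columns")
        if not np.all(np.isfinite(self.matrix)):
            raise ParameterError("matrix entries must be finite")
        if np.any(self.matrix < 0):
            raise ParameterError("matrix entries must be non-negative")
        for name in ("true_order", "true_gene_order"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=int)
                size = n if name == "true_order" else p
                if sorted(val.tolist()) != list(range(size)):
                    raise DimensionError(f"{name} is not a permutation of 0..{size - 1}")
                setattr(self, name, val)
        if self.gradient is not None:
            self.gradient = np.asarray(self.gradient, dtype=float)
            if self.gradient.shape != (n,):
                raise DimensionError("gradient length must equal n_cells")
            if not np.all(np.isfinite(self.gradient)):
                raise ParameterError("gradient values must be finite")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]


def _identity_gradient(n: int) -> np.ndarray:
    if n == 1:
        return np.zeros(1)
    return np.arange(n) / (n - 1)


def generate_band_a(spec: BandSpec) -> ExpressionDataset:
    """Binary/constant ordered band table.

    Row ``i`` carries the constant ``spec.value`` on the contiguous gene
    block ``[i*band_step, i*band_step + band_width)`` and zero elsewhere.
    """
    if spec.value_model is not ValueModel.CONSTANT:
        raise ParameterError("generate_band_a requires value_model=constant")
    spec.check_band_fits()
    m = np.zeros((spec.n_cells, spec.n_genes))
    for i in range(spec.n_cells):
        start = i * spec.band_step
        m[i, start:start + spec.band_width] = spec.value
    return ExpressionDataset(
        matrix=m,
        true_order=np.arange(spec.n_cells),
        gradient=_identity_gradient(spec.n_cells),
    )


def generate_band_b(spec: BandSpec) -> ExpressionDataset:
    """Count-valued band with tapered Poisson means and off-band noise.

    In-band entries are Poisson with means falling linearly from
    ``peak_mean`` at the band centre to ``edge_mean`` at its edges;
    off-band entries are nonzero (``1 + Poisson(1)``) with probability
    ``noise_rate``.
    """
    if spec.value_model is not ValueModel.COUNTS:
        raise ParameterError("generate_band_b requires value_model=counts")
    spec.check_band_fits()
    if spec.noise_rate >= 0.5:
        raise ParameterError("noise_rate must be < 0.5 for a band to dominate")
    rng = np.random.default_rng(spec.seed)
    w = spec.band_width
    centre = (w - 1) / 2.0
    if w == 1:
        taper = np.array([spec.peak_mean])
    else:
        taper = spec.peak_mean + (spec.edge_mean - spec.peak_mean) * (
            np.abs(np.arange(w) - centre) / centre
        )
    m = np.zeros((spec.n_cells, spec.n_genes))
    for i in range(spec.n_cells):
        start = i * spec.band_step
        m[i, start:start + w] = rng.poisson(taper)
    if spec.noise_rate > 0:
        band_mask = np.zeros_like(m, dtype=bool)
        for i in range(spec.n_cells):
            start = i * spec.band_step
            band_mask[i, start:start + w] = True
        noise_sites = (~band_mask) & (rng.random(m.shape) < spec.noise_rate)
        m[noise_sites] = 1.0 + rng.poisson(1.0, size=int(noise_sites.sum()))
    return ExpressionDataset(
        matrix=m,
        true_order=np.arange(spec.n_cells),
        gradient=_identity_gradient(spec.n_cells),
    )


def generate_block_diagonal(n_blocks: int, cells_per_block: int,
                            genes_per_block: int, seed: int = 0,
                            mean_count: float = 5.0) -> ExpressionDataset:
    """Discrete cell types: cell i of block b is supported only on block
    b's gene columns.  The Gram matrix of cells is block diagonal, so no
    single gradient orders the cells and no horseshoe arises.

    The gradient attached is the block index.
    """
    if n_blocks < 2:
        raise ParameterError("n_blocks must be >= 2")
    if cells_per_block < 1 or genes_per_block < 1:
        raise ParameterError("cells_per_block and genes_per_block must be positive")
    rng = np.random.default_rng(seed)
    n = n_blocks * cells_per_block
    p = n_blocks * genes_per_block
    m = np.zeros((n, p))
    for b in range(n_blocks):
        rows = slice(b * cells_per_block, (b + 1) * cells_per_block)
        cols = slice(b * genes_per_block, (b + 1) * genes_per_block)
        # 1 + Poisson keeps the whole block strictly nonzero
        m[rows, cols] = 1.0 + rng.poisson(mean_count,
                                          size=(cells_per_block, genes_per_block))
    gradient = np.repeat(np.arange(n_blocks, dtype=float), cells_per_block)
    return ExpressionDataset(matrix=m, true_order=np.arange(n), gradient=gradient)


def generate_no_saturation(n_cells: int, n_genes: Optional[int] = None,
                           seed: int = 0,
                           band_fraction: float = 0.7) -> ExpressionDataset:
    """Overlapping band in which no cell's distance profile saturates.

    The band width is ``ceil(band_fraction * n_genes)`` with unit step,
    so every pair of cells shares nonzero genes, and the in-band values
    increase strictly along the band.  The defining postcondition --
    euclidean distance from every reference cell strictly increasing
    with index separation on both sides -- is verified explicitly; a
    violation raises :class:`GenerationError` rather than silently
    regenerating.

    ``seed`` is accepted for interface symmetry; the construction is
    deterministic.
    """
    del seed  # deterministic construction
    if n_cells < 6:
        raise ParameterError("n_cells must be >= 6")
    if not 0.5 < band_fraction < 1.0:
        raise ParameterError("band_fraction must lie in (0.5, 1) for universal overlap")
    if n_genes is None:
        # smallest gene count that fits the unit-step band
        n_genes = int(np.ceil((n_cells - 1) / (1.0 - band_fraction)))
    w = int(np.ceil(band_fraction * n_genes))
    if w + (n_cells - 1) > n_genes:
        raise DimensionError(
            "band_width + (n_cells-1) <= n_genes violated: "
            f"{w} + {n_cells - 1} > {n_genes}; increase n_genes"
        )
    values = 1.0 + np.arange(w)  # strictly increasing along the band
    m = np.zeros((n_cells, n_genes))
    for i in range(n_cells):
        m[i, i:i + w] = values
    # postcondition: strict monotonicity of every distance profile
    dist = squareform(pdist(m))
    for ref in range(n_cells):
        for arm in (dist[ref, ref:], dist[ref, :ref + 1][::-1]):
            if arm.size > 1 and not np.all(np.diff(arm) > 0):
                raise GenerationError(
                    f"distance profile not strictly increasing for reference {ref}"
                )
    return ExpressionDataset(
        matrix=m,
        true_order=np.arange(n_cells),
        gradient=_identity_gradient(n_cells),
    )


def shuffle_dataset(ds: ExpressionDataset, seed: int = 0) -> ExpressionDataset:
    """Independently permute rows and columns, carrying ground truth.

    ``true_order`` / ``true_gene_order`` of the result rank each row and
    column by its position in the *input*, composed with the input's own
    ground truth when present, so that sorting by them restores the
    original matrix bit-identically.
    """
    rng = np.random.default_rng(seed)
    n, p = ds.matrix.shape
    perm_r = rng.permutation(n)
    perm_c = rng.permutation(p)
    base_r = ds.true_order if ds.true_order is not None else np.arange(n)
    base_c = ds.true_gene_order if ds.true_gene_order is not None else np.arange(p)
    return ExpressionDataset(
        matrix=ds.matrix[np.ix_(perm_r, perm_c)],
        cell_labels=[ds.cell_labels[i] for i in perm_r],
        gene_labels=[ds.gene_labels[j] for j in perm_c],
        true_order=base_r[perm_r],
        true_gene_order=base_c[perm_c],
        gradient=None if ds.gradient is None else ds.gradient[perm_r],
    )


def unshuffle(ds: ExpressionDataset) -> ExpressionDataset:
    """Invert a recorded shuffle using the stored rank vectors."""
    if ds.true_order is None or ds.true_gene_order is None:
        raise ParameterError("dataset carries no stored permutations")
    inv_r = np.argsort(ds.true_order, kind="stable")
    inv_c = np.argsort(ds.true_gene_order, kind="stable")
    return ExpressionDataset(
        matrix=ds.matrix[np.ix_(inv_r, inv_c)],
        cell_labels=[ds.cell_labels[i] for i in inv_r],
        gene_labels=[ds.gene_labels[j] for j in inv_c],
        true_order=np.arange(ds.n_cells),
        true_gene_order=np.arange(ds.n_genes),
        gradient=None if ds.gradient is None else ds.gradient[inv_r],
    )
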
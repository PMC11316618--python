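"""End-to-end diagnostic runner: the three horseshoe perspectives.

Given an expression matrix, the pipeline (1) sorts it by the dominant
gradient and scores bandedness, (2) recovers the gradient as a principal
curve through the PC embedding and reports how well its arc ordering
matches, (3) sweeps distance-saturation verdicts across reference cells,
then assesses the trigonometric horseshoe signature of PC1/PC2 and
compares their fitted frequencies with the spectral model's
eigenfunctions.  Any stage failure is recorded as skipped-with-reason
rather than aborting the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import curves, saturation as sat
from .config import Config, DEFAULTS, log
from .datasets import ExpressionDataset
from .embedding import canonicalize_signs, horseshoe_score, pca_embed
from .errors import ArchDiagError
from .niche_sort import GradientAssignment, GradientSource
from .niche_sort import niche_sort as _niche_sort


@dataclass
class StageResult:
    """One perspective's verdict; ``skipped`` carries the reason."""

    name: str
    positive: Optional[bool] = None
    details: dict = field(default_factory=dict)
    skipped: Optional[str] = None

    def to_dict(self) -> dict:
        return {"name": self.name, "positive": self.positive,
                "details": self.details, "skipped": self.skipped}


@dataclass
class DiagnosticReport:
    """Summary of the three perspectives plus the horseshoe verdict."""

    perspective1: StageResult
    perspective2: StageResult
    perspective3: StageResult
    horseshoe: StageResult
    model_comparison: StageResult

    def stages(self):
        return [self.perspective1, self.perspective2, self.perspective3,
                self.horseshoe, self.model_comparison]

    def to_dict(self) -> dict:
        return {s.name: s.to_dict() for s in self.stages()}

    def summary(self) -> str:
        lines = []
        for s in self.stages():
            if s.skipped:
                verdict = f"skipped ({s.skipped})"
            else:
                verdict = "positive" if s.positive else "negative"
            lines.append(f"{s.name:>22}: {verdict}")
        return "\n".join(lines)


def preprocess(ds: ExpressionDataset, log1p: bool = False,
               min_cells_per_gene: int = 0) -> ExpressionDataset:
    """Optional real-data preprocessing, all off by default.

    ``min_cells_per_gene`` drops genes expressed in fewer cells;
    ``log1p`` applies log(1 + x).  Anything beyond these two steps is
    out of scope for this package.
    """
    m = ds.matrix
    gene_labels = ds.gene_labels
    true_gene_order = ds.true_gene_order
    if min_cells_per_gene > 0:
        keep = (m > 0).sum(axis=0) >= min_cells_per_gene
        m = m[:, keep]
        gene_labels = [g for g, k in zip(gene_labels, keep) if k]
        true_gene_order = None  # ranks are no longer a permutation
    if log1p:
        m = np.log1p(m)
    return ExpressionDataset(matrix=m, cell_labels=list(ds.cell_labels),
                             gene_labels=gene_labels,
                             true_order=ds.true_order,
                             true_gene_order=true_gene_order,
                             gradient=ds.gradient)


def _run_stage(name: str, fn) -> StageResult:
    try:
        return fn()
    except ArchDiagError as err:
        return StageResult(name=name, skipped=str(err))


def run_diagnostics(ds: ExpressionDataset, config: Config = DEFAULTS) -> DiagnosticReport:
    """Execute all stages on one dataset and assemble the report."""
    log.info("resolved config: %s", config.to_dict())
    ds = preprocess(ds, log1p=config.log1p,
                    min_cells_per_gene=config.min_cells_per_gene)
    emb = pca_embed(ds, k=config.n_components, scale=config.scale)

    # perspective II first: its arc ordering stands in for a missing gradient
    curve = None
    arc_order = None

    def _p2() -> StageResult:
        nonlocal curve, arc_order
        pts = emb.scores[:, :2]
        candidates = []
        try:
            local = curves.fit_local_curve(
                pts,
                step=config.curve_step_frac * curves._diameter(pts),
                radius=None, angle_max=config.curve_angle_max)
            candidates.append(local)
        except ArchDiagError:
            pass
        try:
            n_nodes = min(config.global_n_nodes, max(4, pts.shape[0] // 2))
            candidates.append(curves.fit_global_curve(
                pts, n_nodes=n_nodes, smoothness=config.global_smoothness,
                seed=config.global_seed))
        except ArchDiagError:
            pass
        if not candidates:
            raise ArchDiagError("both curve fitters failed")
        reports = [curves.curve_fit_report(c, pts, reference_order=ds.true_order,
                                           gradient=ds.gradient)
                   for c in candidates]
        # the better gradient representation = lower projection error
        best = int(np.argmin([r.mean_projection_distance for r in reports]))
        curve, report = candidates[best], reports[best]
        arc, _ = curves.project_onto_curve(curve, pts)
        arc_order = np.argsort(arc, kind="stable")
        rho = report.ordering_correlation
        positive = (not np.isnan(rho)) and abs(rho) >= config.ordering_rho_threshold
        return StageResult(
            name="perspective2_gradient",
            positive=bool(positive),
            details={"mean_projection_distance": report.mean_projection_distance,
                     "ordering_correlation": rho,
                     "coverage": report.coverage,
                     "fit": curve.fit_params.get("method")})

    p2 = _run_stage("perspective2_gradient", _p2)

    if ds.gradient is not None:
        phi = GradientAssignment(ds.gradient, GradientSource.PROVIDED)
    elif arc_order is not None:
        ranks = np.empty(ds.n_cells)
        ranks[arc_order] = np.arange(ds.n_cells)
        phi = GradientAssignment(ranks, GradientSource.CURVE_ARC)
    else:
        phi = None

    def _p1() -> StageResult:
        if phi is None:
            raise ArchDiagError("no gradient available (curve fit failed)")
        result = _niche_sort(ds, phi)
        return StageResult(
            name="perspective1_band",
            positive=bool(result.bandedness >= config.bandedness_threshold),
            details={"bandedness": result.bandedness,
                     "gradient_source": phi.source.value})

    p1 = _run_stage("perspective1_band", _p1)
    sort_result = None
    if p1.skipped is None and phi is not None:
        sort_result = _niche_sort(ds, phi)

    order = (sort_result.cell_order if sort_result is not None
             else (arc_order if arc_order is not None else np.arange(ds.n_cells)))

    def _p3() -> StageResult:
        table = sat.saturation_sweep(ds, order, rel_tol=config.rel_tol,
                                     min_run_frac=config.min_run_frac)
        ref0 = table[table.ref_position == 0]
        positive = bool(ref0.is_saturated.iloc[0]) if len(ref0) else False
        return StageResult(
            name="perspective3_saturation",
            positive=positive,
            details={"n_references": int(len(table)),
                     "n_saturated": int(table.is_saturated.sum()),
                     "table": table.to_dict(orient="list")})

    p3 = _run_stage("perspective3_saturation", _p3)

    def _hs() -> StageResult:
        canon = canonicalize_signs(emb, order)
        a = horseshoe_score(canon, order, tau=config.horseshoe_threshold)
        return StageResult(
            name="horseshoe",
            positive=a.is_horseshoe,
            details={"r2_pc1_sin": a.r2_pc1_sin, "r2_pc2_cos": a.r2_pc2_cos,
                     "a_pc1": a.a_pc1, "a_pc2": a.a_pc2,
                     "endpoint_similarity": a.endpoint_similarity,
                     "tau": a.tau, "score": a.score})

    hs = _run_stage("horseshoe", _hs)

    def _model() -> StageResult:
        if hs.skipped is not None:
            raise ArchDiagError(f"horseshoe stage skipped: {hs.skipped}")
        d = hs.details
        return StageResult(
            name="model_comparison",
            positive=hs.positive,
            details={"pc1": {"form": "sin", "a": d["a_pc1"], "r2": d["r2_pc1_sin"]},
                     "pc2": {"form": "cos", "a": d["a_pc2"], "r2": d["r2_pc2_cos"]}})

    model_cmp = _run_stage("model_comparison", _model)

    report = DiagnosticReport(perspective1=p1, perspective2=p2, perspective3=p3,
                              horseshoe=hs, model_comparison=model_cmp)
    log.info("diagnostic summary:\n%s", report.summary())
    return report
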
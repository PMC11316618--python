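"""Declarative configuration for the diagnostics pipeline.

Every numeric default named by the individual modules lives here, so a
single YAML file (or :class:`Config` instance) reproduces a full run.
CLI flags override config values; the resolved configuration is logged
by the pipeline before each run.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

log = logging.getLogger("archdiag")
if not log.handlers:  # pragma: no cover - logging plumbing
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass
class Config:
    """All tunable parameters with their package-wide defaults.

    Attributes mirror the knobs of the individual modules; see
    ``docs/methods.md`` for units and rationale.
    """

    # synthetic band matrices
    n_cells: int = 100
    n_genes: int = 120
    band_width: int = 20
    band_step: int = 1
    band_value: float = 1.0
    peak_count_mean: float = 10.0
    edge_count_mean: float = 1.0
    noise_rate: float = 0.02
    seed: int = 0

    # block-diagonal design
    n_blocks: int = 3
    cells_per_block: int = 30
    genes_per_block: int = 30

    # no-saturation counterexample
    nosat_n_cells: int = 10
    nosat_band_fraction: float = 0.7

    # real-data preprocessing (both off by default)
    log1p: bool = False
    min_cells_per_gene: int = 0

    # embedding / horseshoe decision
    n_components: int = 2
    scale: bool = False
    horseshoe_threshold: float = 0.8  # R^2 threshold tau
    exact_solver_max_dim: int = 2000

    # saturation detector
    rel_tol: float = 0.05
    min_run_frac: float = 0.25

    # principal curves
    curve_step_frac: float = 0.05  # step = frac * embedding diameter
    curve_radius_factor: float = 2.0  # radius = factor * step
    curve_angle_max: float = 1.5707963267948966  # pi/2
    global_n_nodes: int = 20
    global_smoothness: float = 1.0
    global_seed: int = 0

    # spectral model
    model_n: int = 2000
    freq_search_max: float = 12.566370614359172  # 4*pi
    squared_dissimilarity: bool = False

    # niche sort / report
    bandedness_threshold: float = 0.8
    ordering_rho_threshold: float = 0.95

    # stage labels of the supported real datasets, in developmental order;
    # used to map categorical annotations onto an integer gradient.
    stage_order: dict = field(default_factory=lambda: {
        "human_embryo": ["E3", "E4", "E5", "E6", "E7"],
        "mouse_embryo": [
            "MIIoocyte", "zygote", "early2cell", "mid2cell", "late2cell",
            "4cell", "8cell", "16cell", "earlyblast", "midblast", "lateblast",
        ],
        "liver_haematopoiesis": [
            "HSC/MPP", "MEMP", "early erythroid", "mid erythroid", "late erythroid",
        ],
    })

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "Config":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


DEFAULTS = Config()
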
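"""Pipeline configuration: every tunable parameter of every stage, with
defaults, grouped per stage and serializable to/from YAML.

Defaults follow the conventions of the droplet snRNA-seq tooling family this
pipeline mirrors: nuclei are kept when they show between 1000 and 7000
detected genes, log-normalization uses a 10^4 scale factor, marker tests use
a natural-log fold-change threshold of 0.25 with BH-adjusted p ≤ 0.05 and a
10% in-cluster detection floor, trajectory association is tested at FDR ≤
0.01, and cross-species profiles are compared over 30 equal-cell pseudotime
bins at Pearson r ≥ 0.5 and FDR ≤ 0.01.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

log = logging.getLogger("crossvasc")
if not log.handlers:
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass
class QCParams:
    """Detected-gene bounds for keeping a nucleus (inclusive on both ends)."""

    min_genes_per_cell: int = 1000
    max_genes_per_cell: int = 7000

    def __post_init__(self) -> None:
        if not (0 < self.min_genes_per_cell <= self.max_genes_per_cell):
            raise ValueError("require 0 < min_genes_per_cell <= max_genes_per_cell")


@dataclass
class NormalizationParams:
    scale: float = 1.0e4


@dataclass
class HVGParams:
    n_top: int = 2000
    n_mean_bins: int = 20


@dataclass
class PCAParams:
    n_pcs: int = 30


@dataclass
class ClusterParams:
    k_neighbors: int = 20
    resolution: float = 0.5


@dataclass
class MarkerTestParams:
    """Thresholds for cluster-marker retention.

    min_logfc is a natural-log fold change of expm1-backtransformed
    normalized means; min_fraction is the share of in-cluster cells with a
    nonzero raw count.
    """

    min_logfc: float = 0.25
    max_adj_p: float = 0.05
    min_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0 <= self.min_fraction <= 1 and 0 <= self.max_adj_p <= 1):
            raise ValueError("min_fraction and max_adj_p must lie in [0, 1]")


@dataclass
class IntegrationParams:
    k_mnn: int = 15
    n_dims: int = 30
    smooth_sigma: float | None = None  # None -> median MNN-pair distance


@dataclass
class TrajectoryParams:
    start_cluster: int = 0
    principal_curve_iters: int = 0  # optional project->reorder->refit refinement


@dataclass
class GAMParams:
    """Negative-binomial spline regression along pseudotime.

    A cubic B-spline basis with ``df`` degrees of freedom (knots at
    pseudotime quantiles) models the smooth; the gene-level test is a
    likelihood-ratio against the intercept-only model with a log
    library-size offset, chi-squared with ``df`` degrees of freedom.
    """

    df: int = 6
    max_fdr: float = 0.01
    min_expressed_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.df < 3:
            raise ValueError("spline df must be >= 3")


@dataclass
class ComparisonParams:
    """30-bin cross-species profile comparison thresholds."""

    n_bins: int = 30
    min_corr: float = 0.5
    max_fdr: float = 0.01
    permutation_p: bool = False  # circular-shift permutation p instead of t-test

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if abs(self.min_corr) > 1:
            raise ValueError("|min_corr| must be <= 1")


@dataclass
class SimulationConfig:
    """Conditions of the default two-species simulation.

    1000 genes split 200/200/600 into conserved / divergent / flat classes,
    600 cells per species on a shared latent differentiation axis, NB counts
    with dispersion theta = 2, lognormal library sizes around 3618 UMIs,
    species batch offsets of SD 0.3 on the log scale, three clusters along
    the axis, and 10% of species-B genes duplicated into two paralog copies.
    """

    n_cells_per_species: int = 600
    n_genes: int = 1000
    class_proportions: tuple[float, float, float] = (0.2, 0.2, 0.6)
    nb_dispersion: float = 2.0
    mean_library_size: float = 3618.0
    library_size_log_sd: float = 0.3
    batch_sd: float = 0.3
    n_clusters_per_lineage: int = 3
    paralog_fraction: float = 0.1
    amplitude_range: tuple[float, float] = (1.5, 2.5)
    baseline_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        for name in ("n_cells_per_species", "n_genes", "nb_dispersion", "mean_library_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be non-negative")


@dataclass
class PipelineConfig:
    """All stage parameters plus the RNG seed, round-trippable through YAML."""

    qc: QCParams = field(default_factory=QCParams)
    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    hvg: HVGParams = field(default_factory=HVGParams)
    pca: PCAParams = field(default_factory=PCAParams)
    clustering: ClusterParams = field(default_factory=ClusterParams)
    markers: MarkerTestParams = field(default_factory=MarkerTestParams)
    integration: IntegrationParams = field(default_factory=IntegrationParams)
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)
    gam: GAMParams = field(default_factory=GAMParams)
    comparison: ComparisonParams = field(default_factory=ComparisonParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return conv(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in _SECTIONS:
                sec_cls = _SECTIONS[f.name]
                sub = dict(v)
                for sf in dataclasses.fields(sec_cls):
                    if sf.name in sub and isinstance(sub[sf.name], list):
                        sub[sf.name] = tuple(sub[sf.name])
                kwargs[f.name] = sec_cls(**sub)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


_SECTIONS = {
    "qc": QCParams,
    "normalization": NormalizationParams,
    "hvg": HVGParams,
    "pca": PCAParams,
    "clustering": ClusterParams,
    "markers": MarkerTestParams,
    "integration": IntegrationParams,
    "trajectory": TrajectoryParams,
    "gam": GAMParams,
    "comparison": ComparisonParams,
    "simulation": SimulationConfig,
}
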
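"""Simulation and pipeline configuration.

All randomness in the package flows from a single integer seed through
named substreams (one per generator stage), so each stage is reproducible
in isolation and the full pipeline is reproducible end to end.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = [
    "BindingTruth",
    "MassComponent",
    "SimConfig",
    "substream",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a named, independent random substream derived from ``seed``.

    The substream key is a CRC32 of ``name``, so the mapping is stable
    across sessions and platforms.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass
class BindingTruth:
    """Ground truth for the one-site binding isotherm simulator.

    kd_nM is the equilibrium dissociation constant; r_free and r_bound are
    the polarization plateaus (mP) of free and fully bound probe.
    """

    kd_nM: float = 167.0
    r_free: float = 60.0
    r_bound: float = 260.0
    probe_conc_nM: float = 2.0

    def validate(self) -> None:
        if self.kd_nM <= 0:
            raise ValueError(f"kd_nM must be positive, got {self.kd_nM}")
        if self.probe_conc_nM <= 0:
            raise ValueError("probe_conc_nM must be positive")
        if self.r_bound == self.r_free:
            raise ValueError("r_bound must differ from r_free")


@dataclass
class MassComponent:
    """One Gaussian component of a particle-mass distribution."""

    mean_kDa: float
    sd_kDa: float
    weight: float


@dataclass
class SimConfig:
    """Ground truth and sizes for every synthetic input the pipeline consumes.

    Defaults emulate the study conditions: a pooled knockout screen read at
    day 4 and day 20 in two AML lines and one T-ALL line with 4 sgRNAs per
    gene; crosslink sites biased toward 5'UTRs across three metabolic
    conditions (normal glucose, low glucose, galactose) with two replicates
    each; negative-binomial knockdown/control RNA-seq counts in which a
    designated target set is destabilized; and plate-reader assay curves
    (binding titrations, mass-photometry events, actinomycin-D decay).
    """

    seed: int = 0

    # --- screen ---
    n_genes: int = 1000
    n_guides_per_gene: int = 4
    depleted_gene_fraction: float = 0.05
    depletion_fold: float = 8.0
    screen_depth: int = 1_600_000
    cell_lines: tuple = (("MOLM-13", "AML"), ("THP-1", "AML"), ("Jurkat", "T-ALL"))
    n_screen_replicates: int = 2
    forced_fold_changes: dict = field(default_factory=dict)

    # --- annotation & crosslink sites ---
    n_transcripts: int = 300
    utr5_enrichment: float = 0.6
    n_sites_per_sample: int = 400
    site_sharing: float = 0.6
    conditions: tuple = ("norm", "low", "gal")
    n_clip_replicates: int = 2

    # --- expression counts ---
    nb_dispersion: float = 0.05
    target_gene_ids: tuple | None = None
    target_gene_fraction: float = 0.10
    stabilization_lfc: float = -0.5
    te_lfc: float = 0.0
    expr_mean_reads: float = 200.0
    n_expr_replicates: int = 2
    include_rnc: bool = True

    # --- assay curves ---
    binding_truth: BindingTruth = field(default_factory=BindingTruth)
    titration_top_nM: float = 8000.0
    n_titration_points: int = 12
    titration_noise_mP: float = 3.0
    mass_components: tuple = (
        MassComponent(38.5, 4.0, 0.4),
        MassComponent(148.3, 6.0, 0.6),
    )
    n_mass_events: int = 20_000
    decay_halflives_h: dict = field(default_factory=lambda: {"control": 6.0, "knockdown": 2.0})
    decay_times_h: tuple = tuple(float(t) for t in range(9))
    n_decay_replicates: int = 4
    decay_noise_sd: float = 0.10

    # When True every generator emits its expected (noise-free) output.
    noiseless: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.screen_depth <= 0:
            raise ValueError(f"screen_depth must be positive, got {self.screen_depth}")
        if self.n_guides_per_gene < 1:
            raise ValueError("n_guides_per_gene must be >= 1")
        if not 0.0 <= self.depleted_gene_fraction <= 1.0:
            raise ValueError("depleted_gene_fraction must lie in [0, 1]")
        if not 0.0 <= self.utr5_enrichment <= 1.0:
            raise ValueError("utr5_enrichment must lie in [0, 1]")
        if not 0.0 <= self.site_sharing <= 1.0:
            raise ValueError("site_sharing must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError(f"nb_dispersion must be >= 0, got {self.nb_dispersion}")
        if self.depletion_fold <= 0:
            raise ValueError("depletion_fold must be positive")
        if isinstance(self.binding_truth, dict):
            self.binding_truth = BindingTruth(**self.binding_truth)
        self.binding_truth.validate()
        comps = []
        for c in self.mass_components:
            comps.append(MassComponent(**c) if isinstance(c, dict) else c)
        self.mass_components = tuple(comps)
        wsum = sum(c.weight for c in self.mass_components)
        if self.mass_components and not np.isclose(wsum, 1.0):
            raise ValueError(f"mass_components weights must sum to 1, got {wsum}")
        for cond, hl in self.decay_halflives_h.items():
            if hl <= 0:
                raise ValueError(f"half-life for {cond!r} must be positive")

    def rng(self, name: str) -> np.random.Generator:
        """Named substream for one generator stage."""
        return substream(self.seed, name)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("cell_lines", "mass_components", "conditions", "decay_times_h", "target_gene_ids"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(tuple(v) if isinstance(v, list) else v for v in raw[key])
        return cls(**raw)
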
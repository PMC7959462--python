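"""Run and simulation configuration objects.

A single :class:`RunConfig` (usually loaded from YAML) drives the whole
pipeline; its ``simulate`` block, a :class:`SimulationConfig`, fully
specifies a synthetic cohort so a run is reproducible from one root seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from ptmburden.constants import (
    CATEGORY_TO_DIVISION,
    MATRISOME_CATEGORIES,
    PTM_TYPES,
)


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


# matrisome-project-like proportions of the six categories among matrisome
# genes (collagens, ECM glycoproteins, proteoglycans, ECM-affiliated,
# ECM regulators, secreted factors)
DEFAULT_CATEGORY_SPLIT = {
    "collagens": 0.043,
    "ecm_glycoproteins": 0.190,
    "proteoglycans": 0.034,
    "ecm_affiliated": 0.166,
    "ecm_regulators": 0.232,
    "secreted_factors": 0.335,
}

# Relative PTM-type frequencies by matrisome category.  Collagens are
# hydroxylation-heavy; core glycoproteins and proteoglycans carry the
# glycosylation load; the intracellular-leaning rest of the genome is
# dominated by phosphorylation and lysine modifications.
DEFAULT_PTM_DENSITY = {
    "collagens": {
        "hydroxylation": 0.55,
        "o_glycosylation": 0.10,
        "n_glycosylation": 0.05,
        "phosphorylation": 0.15,
        "ubiquitylation": 0.05,
        "acetylation": 0.04,
        "sumoylation": 0.03,
        "methylation": 0.03,
    },
    "ecm_glycoproteins": {
        "n_glycosylation": 0.30,
        "o_glycosylation": 0.15,
        "phosphorylation": 0.30,
        "ubiquitylation": 0.08,
        "acetylation": 0.07,
        "sumoylation": 0.05,
        "methylation": 0.05,
    },
    "proteoglycans": {
        "o_glycosylation": 0.35,
        "n_glycosylation": 0.20,
        "phosphorylation": 0.25,
        "ubiquitylation": 0.07,
        "acetylation": 0.06,
        "sumoylation": 0.04,
        "methylation": 0.03,
    },
    "ecm_affiliated": {
        "phosphorylation": 0.40,
        "n_glycosylation": 0.15,
        "o_glycosylation": 0.10,
        "ubiquitylation": 0.12,
        "acetylation": 0.10,
        "sumoylation": 0.07,
        "methylation": 0.06,
    },
    "ecm_regulators": {
        "phosphorylation": 0.40,
        "n_glycosylation": 0.15,
        "o_glycosylation": 0.10,
        "ubiquitylation": 0.12,
        "acetylation": 0.10,
        "sumoylation": 0.07,
        "methylation": 0.06,
    },
    "secreted_factors": {
        "phosphorylation": 0.40,
        "n_glycosylation": 0.15,
        "o_glycosylation": 0.10,
        "ubiquitylation": 0.12,
        "acetylation": 0.10,
        "sumoylation": 0.07,
        "methylation": 0.06,
    },
    "none": {
        "phosphorylation": 0.50,
        "acetylation": 0.15,
        "ubiquitylation": 0.15,
        "sumoylation": 0.07,
        "methylation": 0.08,
        "n_glycosylation": 0.04,
        "o_glycosylation": 0.01,
    },
}

# uniform profile used by the neutral preset: identical densities in both
# gene sets so burden folds are expected to vanish without selection
UNIFORM_PTM_DENSITY = {
    cat: {
        "phosphorylation": 0.25,
        "n_glycosylation": 0.25,
        "acetylation": 0.25,
        "ubiquitylation": 0.25,
    }
    for cat in MATRISOME_CATEGORIES
}

DEFAULT_NONSILENT_EFFECTS = {
    "missense": 0.85,
    "nonsense": 0.05,
    "frameshift": 0.04,
    "inframe_indel": 0.03,
    "splice_site": 0.03,
}


@dataclass(frozen=True)
class HotspotSpec:
    """A recurrent PTM-site mutation injected verbatim into the cohort."""

    gene: str
    position: int
    ptm_type: str
    cancers: tuple[str, ...]

    def __post_init__(self):
        if self.ptm_type not in PTM_TYPES:
            raise ConfigError(f"hotspot_specs: unknown ptm_type {self.ptm_type!r}")
        if self.position < 1:
            raise ConfigError("hotspot_specs: position must be >= 1")
        object.__setattr__(self, "cancers", tuple(self.cancers))


@dataclass
class SimulationConfig:
    """Generative model for a synthetic pan-cancer cohort.

    Parameters
    ----------
    n_genes, matrisome_fraction
        Catalog size and fraction flagged as matrisome (the human genome
        proportion is ~1027/21255 ≈ 4.8%; desk-scale runs use a larger
        fraction so every matrisome category is populated).
    mutation_rate
        Expected somatic mutations per tumor sample (Poisson).
    ptm_selection_s
        Probability in [0, 1] that a non-silent candidate mutation landing
        on an annotated PTM site is rejected and redrawn; 0 is neutral.
    selection_matrisome_only
        Apply the rejection step only to matrisome genes.
    silent_fraction
        Probability that a candidate mutation is synonymous.
    titv_ratio
        Transition/transversion ratio of simulated SNVs.
    ptm_density_by_category
        category -> {ptm_type: relative frequency} profile.
    sites_per_100aa
        Expected PTM sites per 100 residues (binomial placement).
    hotspot_specs
        Recurrent mutations injected after selection filtering, so they
        survive any value of ``ptm_selection_s``.
    """

    n_genes: int = 200
    matrisome_fraction: float = 0.25
    n_cancers: int = 5
    samples_per_cancer: int = 50
    mutation_rate: float = 40.0
    ptm_selection_s: float = 0.0
    selection_matrisome_only: bool = False
    silent_fraction: float = 0.30
    titv_ratio: float = 2.0
    ptm_density_by_category: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PTM_DENSITY.items()}
    )
    sites_per_100aa: float = 12.0
    hotspot_specs: Sequence[HotspotSpec] = field(default_factory=tuple)
    seed: int = 0
    # plumbing knobs with realistic defaults
    category_split: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_SPLIT)
    )
    mean_protein_length: float = 450.0
    protein_length_sigma: float = 0.5
    nonsilent_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NONSILENT_EFFECTS)
    )
    edges_per_gene: float = 2.0
    homotypic_fraction: float = 0.05
    region_coverage: float = 0.6
    n_domain_families: int = 30

    def __post_init__(self):
        for name in ("matrisome_fraction", "ptm_selection_s", "silent_fraction",
                     "region_coverage", "homotypic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 10:
            raise ConfigError(f"n_genes must be >= 10, got {self.n_genes}")
        if self.titv_ratio <= 0:
            raise ConfigError(f"titv_ratio must be positive, got {self.titv_ratio}")
        if self.mutation_rate <= 0:
            raise ConfigError(f"mutation_rate must be positive")
        for cat, profile in self.ptm_density_by_category.items():
            if cat not in MATRISOME_CATEGORIES:
                raise ConfigError(f"ptm_density_by_category: unknown category {cat!r}")
            for t in profile:
                if t not in PTM_TYPES:
                    raise ConfigError(f"ptm_density_by_category: unknown ptm_type {t!r}")
        self.hotspot_specs = tuple(
            h if isinstance(h, HotspotSpec) else HotspotSpec(**h)
            for h in self.hotspot_specs
        )
        cancer_names = set(self.cancer_names())
        for h in self.hotspot_specs:
            missing = set(h.cancers) - cancer_names
            if missing:
                raise ConfigError(
                    f"hotspot_specs: cancers {sorted(missing)} not among the "
                    f"{self.n_cancers} configured cohorts"
                )

    def cancer_names(self) -> list[str]:
        return [f"C{i:02d}" for i in range(1, self.n_cancers + 1)]

    @classmethod
    def neutral(cls, **overrides) -> "SimulationConfig":
        """Neutral preset: no selection, identical PTM densities in both
        gene sets, so burden folds and r^dN/dS have no built-in signal."""
        kw = dict(
            ptm_selection_s=0.0,
            ptm_density_by_category={k: dict(v) for k, v in UNIFORM_PTM_DENSITY.items()},
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def selected(cls, s: float = 0.8, **overrides) -> "SimulationConfig":
        """Selection preset: rejection probability ``s`` against non-silent
        mutations at matrisome PTM sites only; densities as in neutral()."""
        kw = dict(
            ptm_selection_s=s,
            selection_matrisome_only=True,
            ptm_density_by_category={k: dict(v) for k, v in UNIFORM_PTM_DENSITY.items()},
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class RunConfig:
    """Top-level pipeline configuration (one YAML file, one root seed)."""

    outdir: str = "ptmburden_out"
    seed: int = 0
    simulate: SimulationConfig | None = None
    inputs: Mapping[str, str] | None = None
    min_cohorts: int = 3
    domain_fold: float = 2.0
    motif_window: int = 3
    context_flank: int = 10
    alpha: float = 0.05
    n_random_draws: int = 100
    dnds_pseudocount: float = 0.5

    REQUIRED_INPUTS = ("mutations", "sites", "catalog")

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in ("min_cohorts", "domain_fold", "motif_window",
                     "context_flank", "n_random_draws"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.dnds_pseudocount < 0:
            raise ConfigError("dnds_pseudocount must be >= 0")
        if self.simulate is None and self.inputs is None:
            raise ConfigError(
                "config must provide either a 'simulate' block or 'inputs' paths"
            )
        if self.simulate is not None and not isinstance(self.simulate, SimulationConfig):
            self.simulate = SimulationConfig(**self.simulate)
        if self.simulate is None:
            missing = [k for k in self.REQUIRED_INPUTS if k not in self.inputs]
            if missing:
                raise ConfigError(f"inputs: missing required path(s) {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
        return d


def child_seed(root: int, stage: int) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2**31)."""
    return (int(root) * 1_000_003 + 7919 * int(stage)) % (2**31 - 1)


def validate_division(category: str, division: str) -> bool:
    return CATEGORY_TO_DIVISION.get(category) == division
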
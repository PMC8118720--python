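"""Configuration objects for the microcosm experiment and its analysis.

The experiment template is a fully factorial litter-microcosm design:
each fungal isolate (plus an optional uninoculated control) is incubated
at several moisture levels (fractions of water holding capacity, WHC)
with a fixed number of replicate jars.  The default values reproduce the
study design this package was built around: 15 isolates + 1 control
x 3 moisture levels (4 / 27 / 50 % WHC) x 2 replicates = 96 microcosms
of 5 g sterilised grassland litter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml

#: Canonical enzyme panel: cellobiohydrolase, beta-glucosidase,
#: beta-xylosidase, N-acetyl-beta-D-glucosaminidase.
ENZYMES = ("CBH", "BG", "BX", "NAG")

#: Taxonomic ranks usable as nesting levels, coarsest first.
RANKS = ("phylum", "class", "order", "family", "genus")

CONTROL_ID = "CONTROL"


class InvalidConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class TaxonomySpec:
    """How many taxa exist at each rank; isolates are distributed over them.

    Ranks must be nested: each taxon at a rank belongs to exactly one
    taxon at the rank above, which the generator enforces by construction.
    """

    n_phyla: int = 2
    n_classes: int = 3
    n_orders: int = 4
    n_families: int = 8
    n_genera: int = 12
    n_species: int = 12

    def validate(self) -> None:
        sizes = [self.n_phyla, self.n_classes, self.n_orders,
                 self.n_families, self.n_genera, self.n_species]
        if any(s < 1 for s in sizes):
            raise InvalidConfigError("taxonomy counts must all be >= 1")
        for lo, hi, names in zip(sizes, sizes[1:], RANKS):
            if lo > hi:
                raise InvalidConfigError(
                    f"taxonomy counts must be non-decreasing with depth "
                    f"({names}: {lo} > {hi})")


@dataclass(frozen=True)
class NoiseSpec:
    """Per-instrument measurement noise magnitudes.

    ``microcosm_cv`` is jar-to-jar biological variability (lognormal CV)
    applied jointly to hyphal growth and mass loss of a jar, so that an
    isolate's growth yield is unaffected; ``enzyme_cv`` is the analogous
    jar-level multiplier on true enzyme activity.  Setting every field to
    zero produces exactly noiseless raw tables.
    """

    fluorescence_sd: float = 20.0      # plate-reader units, per well
    field_length_sigma: float = 0.3    # lognormal sigma of microscope fields
    mass_sd_g: float = 0.02            # balance error on final mass
    microcosm_cv: float = 0.15
    enzyme_cv: float = 0.15

    def validate(self) -> None:
        if any(v < 0 for v in asdict(self).values()):
            raise InvalidConfigError("noise magnitudes must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class GrowthModel:
    """Forward model linking latent traits to expected raw measurements.

    The moisture response of hyphal growth is a Gaussian kernel over WHC
    whose optimum moves monotonically from ``optimum_hi`` (stress-latent
    -> -inf) down to ``optimum_lo`` (stress-latent -> +inf); drought
    tolerant isolates therefore peak in the driest jars.
    """

    peak_hyphal_length_m: float = 250.0     # expected total length at optimum
    yield_scale_m_per_g: float = 250.0      # median growth yield, m per g lost
    kernel_width_whc: float = 0.18
    optimum_lo: float = 0.04
    optimum_hi: float = 0.50
    max_mass_loss_fraction: float = 0.9
    #: median per-gram activity (nmol h-1 g-1) of each enzyme
    enzyme_base_activity: Mapping[str, float] = field(
        default_factory=lambda: {"CBH": 50.0, "BG": 200.0, "BX": 60.0, "NAG": 100.0})
    #: log-linear tilt of activity with moisture (per unit WHC around 0.27)
    enzyme_moisture_tilt: Mapping[str, float] = field(
        default_factory=lambda: {"CBH": 0.0, "BG": 0.0, "BX": 0.0, "NAG": 1.5})


@dataclass(frozen=True)
class PlateModel:
    """True optical parameters of the simulated fluorometric assay."""

    f_emission: float = 4000.0       # fluorescence units per nmol fluorophore
    quench: float = 0.8              # fluorescence retained in homogenate
    blank: float = 50.0              # buffer + substrate-free background
    homogenate_background: float = 30.0   # extra background of the homogenate
    substrate_background: float = 30.0    # substrate autohydrolysis signal


@dataclass(frozen=True)
class AssayGeometry:
    """Volumes, masses and times of the fluorometric enzyme assay."""

    litter_mass_assayed_g: float = 0.2
    buffer_volume_ml: float = 75.0
    homogenate_per_well_ml: float = 0.2
    substrate_per_well_ml: float = 0.05
    incubation_time_h: float = 1.0
    standard_amount_nmol: float = 0.5

    def validate(self) -> None:
        if any(v <= 0 for v in asdict(self).values()):
            raise InvalidConfigError("assay geometry values must be > 0")


@dataclass(frozen=True)
class MicroscopyScaling:
    """Geometry of the hyphal-length microscopy scale-up.

    Total hyphal length per gram litter is the mean field length scaled by
    (filter area / field area) x (extract volume / filtered volume)
    / litter mass extracted.
    """

    filter_area_mm2: float = 200.0
    field_area_mm2: float = 0.2
    extract_volume_ml: float = 50.0
    filtered_volume_per_filter_ml: float = 5.0
    litter_mass_extracted_g: float = 0.5
    n_filters: int = 2
    fields_per_filter: int = 5

    def validate(self) -> None:
        if not (self.filter_area_mm2 >= self.field_area_mm2 > 0):
            raise InvalidConfigError("need filter_area >= field_area > 0")
        if not (self.extract_volume_ml >= self.filtered_volume_per_filter_ml > 0):
            raise InvalidConfigError(
                "need extract_volume >= filtered_volume_per_filter > 0")
        if self.litter_mass_extracted_g <= 0:
            raise InvalidConfigError("litter_mass_extracted must be > 0")
        if self.n_filters < 1 or self.fields_per_filter < 1:
            raise InvalidConfigError("need >= 1 filter and >= 1 field per filter")


def _default_latent_cov() -> np.ndarray:
    # log-scale marginal SDs: yield 0.5, acquisition 0.5, stress 1.0;
    # no cross-trait correlation by default (null study conditions)
    return np.diag([0.25, 0.25, 1.0])


def _default_taxonomy_fractions() -> dict:
    # no taxonomic conservatism by default; rank-level structure is
    # injected explicitly (see docs/methods.md)
    return {"phylum": 0.0, "class": 0.0, "order": 0.0, "family": 0.0,
            "isolate": 1.0}


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of one simulated microcosm experiment."""

    n_isolates: int = 15
    moisture_levels: tuple = (0.04, 0.27, 0.50)
    n_replicates: int = 2
    include_control: bool = True
    initial_litter_mass_g: float = 5.0
    taxonomy_spec: TaxonomySpec = field(default_factory=TaxonomySpec)
    latent_cov: np.ndarray = field(default_factory=_default_latent_cov)
    taxonomy_variance_fractions: Mapping[str, float] = field(
        default_factory=_default_taxonomy_fractions)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    growth_model: GrowthModel = field(default_factory=GrowthModel)
    plate_model: PlateModel = field(default_factory=PlateModel)
    assay: AssayGeometry = field(default_factory=AssayGeometry)
    microscopy: MicroscopyScaling = field(default_factory=MicroscopyScaling)
    seed: int = 0

    def validate(self) -> None:
        if self.n_isolates < 1:
            raise InvalidConfigError("need at least one isolate")
        levels = tuple(self.moisture_levels)
        if len(levels) != len(set(levels)):
            raise InvalidConfigError("moisture levels must be distinct")
        if any(not (0.0 < m <= 1.0) for m in levels):
            raise InvalidConfigError("moisture levels must lie in (0, 1]")
        if self.n_replicates < 1:
            raise InvalidConfigError("n_replicates must be >= 1")
        if self.initial_litter_mass_g <= 0:
            raise InvalidConfigError("initial litter mass must be > 0")
        cov = np.asarray(self.latent_cov, dtype=float)
        if cov.shape != (3, 3):
            raise InvalidConfigError("latent_cov must be 3x3")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise InvalidConfigError("latent_cov must be symmetric")
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-10:
            raise InvalidConfigError(
                f"latent_cov is not positive semi-definite (min eigenvalue "
                f"{eig.min():.3g})")
        fr = dict(self.taxonomy_variance_fractions)
        if any(v < 0 for v in fr.values()):
            raise InvalidConfigError("variance fractions must be >= 0")
        total = sum(fr.values())
        if total <= 0:
            raise InvalidConfigError("variance fractions must not all be zero")
        unknown = set(fr) - set(RANKS) - {"isolate"}
        if unknown:
            raise InvalidConfigError(f"unknown variance-fraction ranks: {unknown}")
        self.taxonomy_spec.validate()
        self.noise.validate()
        self.assay.validate()
        self.microscopy.validate()

    @property
    def n_microcosms(self) -> int:
        n_units = self.n_isolates + int(self.include_control)
        return n_units * len(self.moisture_levels) * self.n_replicates


@dataclass(frozen=True)
class PermutationScheme:
    """Row-shuffling scheme for the ordination permutation test."""

    n_permutations: int = 999
    strata: str = "family"   # none | family | order | phylum
    seed: int = 0

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise InvalidConfigError("n_permutations must be >= 1")
        if self.strata not in ("none", "family", "order", "phylum"):
            raise InvalidConfigError(f"unknown strata {self.strata!r}")


@dataclass(frozen=True)
class StatsOptions:
    alpha: float = 0.05
    rank_yield: bool = True
    include_genus: bool = False
    collapse_replicates: bool = True
    bh_correction: bool = False


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration (simulate -> derive -> test -> RDA)."""

    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    stats: StatsOptions = field(default_factory=StatsOptions)
    permutation: PermutationScheme = field(default_factory=PermutationScheme)
    allow_negative_activity: bool = False
    mass_basis: str = "remaining"    # or "initial"
    rda_mode: str = "strata"         # or "partial"
    standardize_rda: bool = True
    seed: int = 0

    def validate(self) -> None:
        self.experiment.validate()
        self.permutation.validate()
        if self.mass_basis not in ("remaining", "initial"):
            raise InvalidConfigError("mass_basis must be 'remaining' or 'initial'")
        if self.rda_mode not in ("strata", "partial"):
            raise InvalidConfigError("rda_mode must be 'strata' or 'partial'")
        if not (0 < self.stats.alpha < 1):
            raise InvalidConfigError("alpha must be in (0, 1)")


def _cfg_to_plain(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _cfg_to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _cfg_to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_cfg_to_plain(v) for v in obj]
    return obj


def run_config_to_yaml(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_cfg_to_plain(cfg), fh, sort_keys=False)


def run_config_from_yaml(path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; missing keys keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return run_config_from_dict(raw)


def run_config_from_dict(raw: Mapping) -> RunConfig:
    def build(cls, data, **nested):
        data = dict(data or {})
        for key, builder in nested.items():
            if key in data:
                data[key] = builder(data[key])
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise InvalidConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
        return cls(**data)

    exp_raw = dict(raw.get("experiment") or {})
    if "latent_cov" in exp_raw:
        exp_raw["latent_cov"] = np.asarray(exp_raw["latent_cov"], dtype=float)
    if "moisture_levels" in exp_raw:
        exp_raw["moisture_levels"] = tuple(exp_raw["moisture_levels"])
    exp = build(ExperimentConfig, exp_raw,
                taxonomy_spec=lambda d: build(TaxonomySpec, d),
                noise=lambda d: build(NoiseSpec, d),
                growth_model=lambda d: build(GrowthModel, d),
                plate_model=lambda d: build(PlateModel, d),
                assay=lambda d: build(AssayGeometry, d),
                microscopy=lambda d: build(MicroscopyScaling, d))
    cfg = RunConfig(
        experiment=exp,
        stats=build(StatsOptions, raw.get("stats")),
        permutation=build(PermutationScheme, raw.get("permutation")),
        allow_negative_activity=raw.get("allow_negative_activity", False),
        mass_basis=raw.get("mass_basis", "remaining"),
        rda_mode=raw.get("rda_mode", "strata"),
        standardize_rda=raw.get("standardize_rda", True),
        seed=raw.get("seed", 0),
    )
    cfg.validate()
    return cfg
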
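"""Synthetic microcosm experiment generator.

Produces the four raw tables the trait pipeline consumes (taxonomy,
microcosm design + masses, microscopy field lengths, enzyme plate
readings) from a forward model with known latent traits, so that every
downstream stage can be tested against ground truth without any
deposited data.

The forward model gives each isolate three latent lifestyle traits on a
log scale — growth yield (Y), resource acquisition (A) and drought
stress tolerance (S) — drawn from a configurable trivariate normal
distribution, optionally with variance shared at taxonomic ranks.
Hyphal growth responds to moisture through a unimodal kernel whose
optimum is a monotone function of the stress latent, so stress-tolerant
isolates peak in the driest jars.  Applying the trait-derivation module
to noiseless output returns the latent traits' observable counterparts
exactly (forward-inverse identity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import (CONTROL_ID, ENZYMES, AssayGeometry, ExperimentConfig,
                     GrowthModel, PlateModel, TaxonomySpec)

WELL_ROLES = ("sample", "homogenate_control", "substrate_control",
              "standard", "quench_standard", "blank")
WELLS_PER_ROLE = 8

# fixed spawn keys: one deterministic substream per output table, so that
# adding a table never perturbs the earlier ones
_STREAMS = {"latents": 0, "jars": 1, "microscopy": 2, "enzymes": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class ExperimentTables:
    """The four raw tables plus the generator's ground truth."""

    taxonomy: pd.DataFrame
    microcosms: pd.DataFrame
    microscopy: pd.DataFrame
    enzyme_plates: pd.DataFrame
    truth: pd.DataFrame            # per microcosm: true lengths/losses/activities
    isolate_truth: pd.DataFrame    # per isolate: latent traits and true MAI
    config: ExperimentConfig

    def write(self, outdir) -> dict:
        """Write the four raw CSVs; returns {name: path}."""
        import os
        os.makedirs(outdir, exist_ok=True)
        paths = {}
        for name in ("taxonomy", "microcosms", "microscopy", "enzyme_plates"):
            path = os.path.join(outdir, f"{name}.csv")
            getattr(self, name).to_csv(path, index=False)
            paths[name] = path
        return paths


def assign_taxonomy(n_isolates: int, spec: TaxonomySpec) -> pd.DataFrame:
    """Distribute isolates over a nested taxonomy.

    Each child taxon maps to exactly one parent (contiguous blocks), so
    the hierarchy is nested by construction, and sibling taxa are spread
    as evenly as possible — with the default counts every order holds
    two families, keeping rank-level variance components identifiable.
    With two phyla the real names of the dominant litter-decomposer
    phyla are used.
    """
    spec.validate()

    def parent(child, n_child, n_parent):
        return child * n_parent // n_child

    iso = np.arange(n_isolates)
    species = iso % spec.n_species
    genus = parent(species, spec.n_species, spec.n_genera)
    family = parent(genus, spec.n_genera, spec.n_families)
    order = parent(family, spec.n_families, spec.n_orders)
    klass = parent(order, spec.n_orders, spec.n_classes)
    phylum = parent(klass, spec.n_classes, spec.n_phyla)
    if spec.n_phyla == 2:
        phylum_names = np.array(["Ascomycota", "Basidiomycota"])
    else:
        phylum_names = np.array([f"Phylum_{i+1:02d}" for i in range(spec.n_phyla)])
    return pd.DataFrame({
        "isolate_id": [f"ISO{i+1:02d}" for i in iso],
        "phylum": phylum_names[phylum],
        "class": [f"Class_{c+1:02d}" for c in klass],
        "order": [f"Order_{o+1:02d}" for o in order],
        "family": [f"Family_{f+1:02d}" for f in family],
        "genus": [f"Genus_{g+1:02d}" for g in genus],
        "species": [f"Species_{s+1:02d}" for s in species],
    })


def draw_latent_traits(taxonomy: pd.DataFrame, latent_cov: np.ndarray,
                       fractions, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-isolate latent (Y, A, S) vectors.

    The total covariance across isolates equals ``latent_cov``; the
    ``fractions`` mapping splits it over taxonomic ranks (shared effects
    within a taxon) plus an isolate-specific remainder, so taxonomic
    conservatism can be injected without changing the marginal law.
    """
    cov = np.asarray(latent_cov, dtype=float)
    eigval, eigvec = np.linalg.eigh(cov)
    L = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))
    fr = {k: v for k, v in dict(fractions).items() if v > 0}
    total = sum(fr.values())
    n = len(taxonomy)
    z = np.zeros((n, 3))
    for rank, f in fr.items():
        if rank == "isolate":
            groups = np.arange(n)
        else:
            groups = pd.factorize(taxonomy[rank])[0]
        eff = rng.standard_normal((groups.max() + 1, 3)) @ L.T
        z += np.sqrt(f / total) * eff[groups]
    return pd.DataFrame(z, columns=["yield_latent", "acquisition_latent",
                                    "stress_latent"],
                        index=taxonomy["isolate_id"])


def growth_optimum(stress_latent, model: GrowthModel = GrowthModel()):
    """WHC at which expected hyphal growth peaks; decreasing in stress."""
    s = np.asarray(stress_latent, dtype=float)
    return model.optimum_lo + (model.optimum_hi - model.optimum_lo) * expit(-s)


def simulate_growth(latent, moisture: float,
                    model: GrowthModel = GrowthModel(),
                    initial_mass_g: float = 5.0):
    """Expected total hyphal length (m) and mass loss (g) for one jar.

    ``latent`` is anything with yield_latent / stress_latent attributes or
    keys.  Mass loss is the hyphal length divided by the isolate's growth
    yield (m of hyphae built per g of litter consumed), capped below the
    initial litter mass.
    """
    if moisture <= 0:
        raise ValueError(f"moisture must be > 0, got {moisture}")
    get = (latent.get if hasattr(latent, "get")
           else lambda k: getattr(latent, k))
    stress = float(get("stress_latent"))
    yld = float(get("yield_latent"))
    mode = growth_optimum(stress, model)
    kernel = np.exp(-((moisture - mode) ** 2) / (2 * model.kernel_width_whc ** 2))
    total_len = model.peak_hyphal_length_m * kernel
    yield_trait = model.yield_scale_m_per_g * np.exp(yld)
    mass_loss = min(total_len / yield_trait,
                    model.max_mass_loss_fraction * initial_mass_g)
    return float(total_len), float(mass_loss)


def simulate_enzyme_plate(true_activity: float, assay: AssayGeometry,
                          noise_sd: float,
                          plate: PlateModel = PlateModel(),
                          rng: Optional[np.random.Generator] = None,
                          ) -> pd.DataFrame:
    """Simulate one microcosm x enzyme set of plate wells.

    Constructed as the exact inverse of the activity equation: applying
    the trait-derivation reduction to a noiseless plate returns
    ``true_activity`` to floating point.
    """
    if true_activity < 0:
        raise ValueError("true_activity must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    means = _plate_role_means(np.array([true_activity]), assay, plate)
    rows = []
    for role in WELL_ROLES:
        mu = means[role][0]
        for w in range(WELLS_PER_ROLE):
            rows.append((role, w + 1, mu))
    out = pd.DataFrame(rows, columns=["well_role", "well_index", "fluorescence"])
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        out["fluorescence"] += rng.normal(0.0, noise_sd, len(out))
    return out


def _plate_role_means(activity: np.ndarray, assay: AssayGeometry,
                      plate: PlateModel) -> dict:
    """Noise-free mean fluorescence per well role for a vector of activities."""
    B = plate.blank
    H = B + plate.homogenate_background
    C = B + plate.substrate_background
    std_buf = plate.f_emission * assay.standard_amount_nmol + B
    quench_std = plate.quench * (std_buf - B) + H
    per_well = (activity * plate.f_emission * assay.homogenate_per_well_ml
                * assay.incubation_time_h * assay.litter_mass_assayed_g
                / assay.buffer_volume_ml)
    sample = plate.quench * ((C - B) + per_well) + H
    n = len(activity)
    return {
        "sample": sample,
        "homogenate_control": np.full(n, H),
        "substrate_control": np.full(n, C),
        "standard": np.full(n, std_buf),
        "quench_standard": np.full(n, quench_std),
        "blank": np.full(n, B),
    }


def generate_experiment(config: ExperimentConfig = ExperimentConfig()
                        ) -> ExperimentTables:
    """Generate one full factorial microcosm experiment.

    Returns the raw tables plus ground truth.  Identical configs and
    seeds give byte-identical tables.
    """
    config.validate()
    gm, noise = config.growth_model, config.noise
    taxonomy = assign_taxonomy(config.n_isolates, config.taxonomy_spec)
    latents = draw_latent_traits(taxonomy, config.latent_cov,
                                 config.taxonomy_variance_fractions,
                                 _rng(config.seed, "latents"))

    moistures = np.asarray(config.moisture_levels, dtype=float)
    units = list(taxonomy["isolate_id"])
    if config.include_control:
        units.append(CONTROL_ID)

    # design grid: unit x moisture x replicate, in deterministic order
    rows = [(u, m, r + 1) for u in units for m in moistures
            for r in range(config.n_replicates)]
    n = len(rows)
    unit_arr = np.array([r[0] for r in rows])
    moist_arr = np.array([r[1] for r in rows])
    rep_arr = np.array([r[2] for r in rows])
    micro_ids = np.array([f"M{i+1:03d}" for i in range(n)])
    is_control = unit_arr == CONTROL_ID

    # expected growth per jar
    exp_len = np.zeros(n)
    exp_loss = np.zeros(n)
    for i in range(n):
        if is_control[i]:
            continue
        exp_len[i], exp_loss[i] = simulate_growth(
            latents.loc[unit_arr[i]], moist_arr[i], gm,
            config.initial_litter_mass_g)

    jar_rng = _rng(config.seed, "jars")
    if noise.microcosm_cv > 0:
        sig = np.sqrt(np.log1p(noise.microcosm_cv ** 2))
        jar_mult = np.exp(sig * jar_rng.standard_normal(n) - sig ** 2 / 2)
    else:
        jar_mult = np.ones(n)
        jar_rng.standard_normal(n)  # keep substream alignment
    true_len = exp_len * jar_mult
    true_loss = np.minimum(exp_loss * jar_mult,
                           gm.max_mass_loss_fraction * config.initial_litter_mass_g)
    true_len[is_control] = 0.0
    true_loss[is_control] = 0.0

    mass_noise = jar_rng.normal(0.0, noise.mass_sd_g, n) if noise.mass_sd_g > 0 \
        else np.zeros(n)
    final_mass = np.clip(config.initial_litter_mass_g - true_loss + mass_noise,
                         0.0, config.initial_litter_mass_g)

    microcosms = pd.DataFrame({
        "microcosm_id": micro_ids,
        "isolate_id": unit_arr,
        "moisture_whc": moist_arr,
        "replicate": rep_arr,
        "initial_mass_g": config.initial_litter_mass_g,
        "final_mass_g": final_mass,
    })

    # microscopy: expected per-field length from the per-gram true length
    ms = config.microscopy
    mass_remaining = config.initial_litter_mass_g - true_loss
    per_gram = np.where(mass_remaining > 0, true_len / np.where(
        mass_remaining > 0, mass_remaining, 1.0), 0.0)
    mu_field = (per_gram * ms.litter_mass_extracted_g
                * (ms.filtered_volume_per_filter_ml / ms.extract_volume_ml)
                * (ms.field_area_mm2 / ms.filter_area_mm2))
    n_fields = ms.n_filters * ms.fields_per_filter
    mic_rng = _rng(config.seed, "microscopy")
    field_mu = np.repeat(mu_field, n_fields)
    if noise.field_length_sigma > 0:
        s = noise.field_length_sigma
        field_len = field_mu * np.exp(
            s * mic_rng.standard_normal(len(field_mu)) - s ** 2 / 2)
    else:
        field_len = field_mu
    microscopy = pd.DataFrame({
        "microcosm_id": np.repeat(micro_ids, n_fields),
        "filter_id": np.tile(np.repeat(np.arange(1, ms.n_filters + 1),
                                       ms.fields_per_filter), n),
        "field_id": np.tile(np.arange(1, ms.fields_per_filter + 1),
                            n * ms.n_filters),
        "field_length_m": field_len,
    })

    # enzyme plates: per-gram activity = base * exp(A latent) * moisture tilt
    enz_rng = _rng(config.seed, "enzymes")
    acq = np.array([0.0 if c else latents.loc[u, "acquisition_latent"]
                    for u, c in zip(unit_arr, is_control)])
    activities = {}
    for enz in ENZYMES:
        a = (gm.enzyme_base_activity[enz]
             * np.exp(acq + gm.enzyme_moisture_tilt[enz] * (moist_arr - 0.27)))
        a[is_control] = 0.0
        if noise.enzyme_cv > 0:
            s = np.sqrt(np.log1p(noise.enzyme_cv ** 2))
            a = a * np.exp(s * enz_rng.standard_normal(n) - s ** 2 / 2)
        else:
            enz_rng.standard_normal(n)
        activities[enz] = a

    frames = []
    n_wells = len(WELL_ROLES) * WELLS_PER_ROLE
    for enz in ENZYMES:
        means = _plate_role_means(activities[enz], config.assay,
                                  config.plate_model)
        fluor = np.column_stack([
            np.repeat(np.asarray(means[role])[:, None], WELLS_PER_ROLE, axis=1)
            for role in WELL_ROLES]).ravel()
        frames.append(pd.DataFrame({
            "microcosm_id": np.repeat(micro_ids, n_wells),
            "enzyme": enz,
            "well_role": np.tile(np.repeat(np.array(WELL_ROLES), WELLS_PER_ROLE), n),
            "well_index": np.tile(np.arange(1, WELLS_PER_ROLE + 1),
                                  n * len(WELL_ROLES)),
            "fluorescence": fluor,
        }))
    enzyme_plates = pd.concat(frames, ignore_index=True)
    if noise.fluorescence_sd > 0:
        # plate readers report non-negative RFU; clip rather than allow
        # impossible readings
        enzyme_plates["fluorescence"] = np.maximum(
            enzyme_plates["fluorescence"]
            + enz_rng.normal(0.0, noise.fluorescence_sd, len(enzyme_plates)),
            0.0)

    truth = pd.DataFrame({
        "microcosm_id": micro_ids,
        "isolate_id": unit_arr,
        "moisture_whc": moist_arr,
        "replicate": rep_arr,
        "true_total_hyphal_length_m": true_len,
        "true_mass_loss_g": true_loss,
        "true_growth_yield_m_per_g": np.where(true_loss > 0,
                                              true_len / np.where(true_loss > 0,
                                                                  true_loss, 1.0),
                                              np.nan),
        **{f"true_activity_{e}": activities[e] for e in ENZYMES},
    })

    iso_truth = latents.copy()
    mai = []
    for iso in taxonomy["isolate_id"]:
        lens = np.array([simulate_growth(latents.loc[iso], m, gm,
                                         config.initial_litter_mass_g)[0]
                         for m in moistures])
        mai.append(100.0 * float(lens @ moistures) / float(lens.sum()))
    iso_truth["true_mai_percent"] = mai
    iso_truth["growth_optimum_whc"] = growth_optimum(
        iso_truth["stress_latent"].to_numpy(), gm)
    iso_truth = iso_truth.reset_index()

    return ExperimentTables(taxonomy=taxonomy, microcosms=microcosms,
                            microscopy=microscopy, enzyme_plates=enzyme_plates,
                            truth=truth, isolate_truth=iso_truth, config=config)
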
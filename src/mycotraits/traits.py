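"""Derive lifestyle traits from raw microcosm measurements.

Three trait families are produced:

* growth yield (Y): total hyphal length per gram of litter mass lost,
  with hyphal length scaled up from stained-filter microscopy fields;
* resource acquisition (A): potential activities of four extracellular
  enzymes (CBH, BG, BX, NAG) from fluorometric plate assays, reduced
  through emission and quench coefficients and standardised per
  microcosm by multiplying by the litter mass remaining;
* drought stress tolerance (S): the moisture association index (MAI),
  the hyphal-length-weighted mean of the moisture treatment fractions
  times 100.  For treatments at 4/27/50 % WHC the index ranges from 4
  (growth only in the driest jars) to 50 (growth only in the wettest).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CONTROL_ID, ENZYMES, AssayGeometry, MicroscopyScaling


class InvalidStandardError(ValueError):
    """The fluorescence standard carries no usable signal."""


class AssayQCWarning(UserWarning):
    """A derived assay quantity fell outside its plausible range."""


def emission_coefficient(standard_fluor: float, blank_fluor: float,
                         standard_amount: float) -> float:
    """Fluorescence units per nmol of fluorophore, from a known standard."""
    if standard_amount <= 0:
        raise ValueError("standard_amount must be > 0")
    coef = (standard_fluor - blank_fluor) / standard_amount
    if coef <= 0:
        raise InvalidStandardError(
            f"standard has no net signal (net fluorescence "
            f"{standard_fluor - blank_fluor:.3g})")
    return coef


def quench_coefficient(standard_in_homog: float, homog_control: float,
                       standard_in_buffer: float, blank: float) -> float:
    """Fraction of fluorescence retained in sample homogenate.

    Values outside (0, 1.5] are clamped with a warning: a slightly
    negative or >1 estimate is assay noise, not a physical quench.
    """
    denom = standard_in_buffer - blank
    if denom <= 0:
        raise InvalidStandardError(
            "buffer standard does not exceed blank; quench undefined")
    q = (standard_in_homog - homog_control) / denom
    if q <= 0:
        warnings.warn(f"quench coefficient {q:.3g} <= 0; clamped to 0 "
                      "(total quench)", AssayQCWarning, stacklevel=2)
        return 0.0
    if q > 1.5:
        warnings.warn(f"quench coefficient {q:.3g} > 1.5; clamped",
                      AssayQCWarning, stacklevel=2)
        return 1.5
    return q


def enzyme_activity(mean_sample_fluor: float, homog_control: float,
                    substrate_control: float, blank: float,
                    q: float, f_e: float, assay: AssayGeometry) -> float:
    """Potential enzyme activity in nmol h-1 per g litter assayed.

    activity = [((S - H) / q) - (C - B)] * V_buffer
               / (f_e * V_homogenate * t * m_litter)
    with S the mean sample fluorescence, H the homogenate control, C the
    substrate control and B the blank.  May be negative for noisy plates
    near zero activity; callers decide how to handle that.
    """
    vals = (mean_sample_fluor, homog_control, substrate_control, blank, q, f_e)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError(f"non-finite assay input: {vals}")
    if q <= 0:
        raise ValueError("quench coefficient must be > 0")
    if f_e <= 0:
        raise ValueError("emission coefficient must be > 0")
    net = (mean_sample_fluor - homog_control) / q - (substrate_control - blank)
    return (net * assay.buffer_volume_ml
            / (f_e * assay.homogenate_per_well_ml * assay.incubation_time_h
               * assay.litter_mass_assayed_g))


def standardize_per_microcosm(activity_per_g: float, mass_remaining: float
                              ) -> float:
    """Scale per-gram activity to the whole microcosm (nmol h-1 per jar)."""
    if mass_remaining < 0:
        raise ValueError("mass_remaining must be >= 0")
    return activity_per_g * mass_remaining


def hyphal_length_per_gram(field_lengths: Sequence[float],
                           scaling: MicroscopyScaling) -> float:
    """Scale mean microscope-field hyphal length up to m per g litter."""
    lengths = np.asarray(list(field_lengths), dtype=float)
    if lengths.size == 0:
        raise ValueError("need at least one field length")
    if (lengths < 0).any():
        raise ValueError("field lengths must be >= 0")
    return float(lengths.mean()
                 * (scaling.filter_area_mm2 / scaling.field_area_mm2)
                 * (scaling.extract_volume_ml
                    / scaling.filtered_volume_per_filter_ml)
                 / scaling.litter_mass_extracted_g)


def growth_yield(total_hyphal_length: float, mass_loss: float) -> float:
    """Hyphal length built per gram of litter consumed (m g-1).

    Returns NaN (the undefined-yield flag) when mass loss is not
    positive; such records are excluded from yield analyses.
    """
    if total_hyphal_length < 0:
        raise ValueError("total_hyphal_length must be >= 0")
    if mass_loss <= 0:
        return float("nan")
    return total_hyphal_length / mass_loss


def moisture_association_index(lengths_by_moisture: Mapping[float, float]
                               ) -> float:
    """Hyphal-length-weighted mean moisture level, as a percentage.

    MAI = 100 * sum_i(h_i * w_i) / sum_i(h_i), with h_i the hyphal
    length at moisture level w_i (a WHC fraction).  Lower values mean
    the isolate concentrated its growth in drier jars, i.e. greater
    drought stress tolerance.
    """
    if len(lengths_by_moisture) < 2:
        raise ValueError("need at least two moisture levels")
    w = np.array(list(lengths_by_moisture.keys()), dtype=float)
    h = np.array(list(lengths_by_moisture.values()), dtype=float)
    if (w <= 0).any() or (w > 1).any():
        raise ValueError("moisture levels must be WHC fractions in (0, 1]")
    if (h < 0).any():
        raise ValueError("hyphal lengths must be >= 0")
    total = h.sum()
    if total <= 0:
        raise ValueError("all hyphal lengths are zero; MAI undefined")
    return float(100.0 * ((h / total) @ w))   # normalise first: stable for
                                              # subnormal length sums


@dataclass
class TraitDerivationResult:
    traits: pd.DataFrame     # one row per inoculated microcosm
    mai: pd.DataFrame        # one row per isolate
    log: dict = field(default_factory=dict)


def _plate_means(plate: pd.DataFrame) -> pd.Series:
    return plate.groupby("well_role")["fluorescence"].mean()


def derive_plate_activity(plate: pd.DataFrame, assay: AssayGeometry) -> float:
    """Reduce one microcosm x enzyme set of wells to per-gram activity."""
    means = _plate_means(plate)
    required = {"sample", "homogenate_control", "substrate_control",
                "standard", "quench_standard", "blank"}
    missing = required - set(means.index)
    if missing:
        raise ValueError(f"plate lacks well roles: {sorted(missing)}")
    f_e = emission_coefficient(means["standard"], means["blank"],
                               assay.standard_amount_nmol)
    q = quench_coefficient(means["quench_standard"],
                           means["homogenate_control"],
                           means["standard"], means["blank"])
    if q == 0:
        return float("nan")
    return enzyme_activity(means["sample"], means["homogenate_control"],
                           means["substrate_control"], means["blank"],
                           q, f_e, assay)


def build_trait_table(microcosms: pd.DataFrame, microscopy: pd.DataFrame,
                      enzyme_plates: pd.DataFrame,
                      assay: AssayGeometry = AssayGeometry(),
                      scaling: MicroscopyScaling = MicroscopyScaling(),
                      allow_negative_activity: bool = False,
                      mass_basis: str = "remaining",
                      mai_method: str = "replicate_means",
                      ) -> TraitDerivationResult:
    """Derive the per-microcosm trait table and the per-isolate MAI table.

    Total hyphal length per microcosm is the microscopy-derived per-gram
    length times the litter mass (mass remaining at harvest by default,
    ``mass_basis='initial'`` for the initial mass).  Control microcosms
    are excluded from both outputs but summarised in the log.  Negative
    enzyme activities are truncated to zero (and counted) unless
    ``allow_negative_activity`` is set.
    """
    if mass_basis not in ("remaining", "initial"):
        raise ValueError("mass_basis must be 'remaining' or 'initial'")
    if mai_method not in ("replicate_means", "pooled"):
        raise ValueError("mai_method must be 'replicate_means' or 'pooled'")
    micro_ids = set(microcosms["microcosm_id"])
    for name, table in (("microscopy", microscopy),
                        ("enzyme_plates", enzyme_plates)):
        orphans = sorted(set(table["microcosm_id"]) - micro_ids)
        if orphans:
            raise ValueError(f"{name} references unknown microcosms: {orphans}")

    log: dict = {"n_microcosms": len(microcosms)}
    mc = microcosms.set_index("microcosm_id")
    mass_loss = mc["initial_mass_g"] - mc["final_mass_g"]
    mass_remaining = mc["final_mass_g"]
    mass_for_length = (mass_remaining if mass_basis == "remaining"
                       else mc["initial_mass_g"])

    per_gram = microscopy.groupby("microcosm_id")["field_length_m"].apply(
        lambda f: hyphal_length_per_gram(f.to_numpy(), scaling))
    total_len = (per_gram * mass_for_length).rename("total_hyphal_length_m")

    # vectorised equivalent of derive_plate_activity per (microcosm, enzyme)
    means = (enzyme_plates
             .groupby(["microcosm_id", "enzyme", "well_role"], sort=True)
             ["fluorescence"].mean().unstack("well_role"))
    f_e = (means["standard"] - means["blank"]) / assay.standard_amount_nmol
    bad_std = f_e <= 0
    log["n_invalid_standards"] = int(bad_std.sum())
    q = ((means["quench_standard"] - means["homogenate_control"])
         / (means["standard"] - means["blank"]))
    log["n_quench_clamped"] = int(((q <= 0) | (q > 1.5)).sum())
    q = q.clip(upper=1.5)
    q[q <= 0] = np.nan     # total quench: activity unrecoverable
    net = ((means["sample"] - means["homogenate_control"]) / q
           - (means["substrate_control"] - means["blank"]))
    act = (net * assay.buffer_volume_ml
           / (f_e * assay.homogenate_per_well_ml * assay.incubation_time_h
              * assay.litter_mass_assayed_g))
    act[bad_std] = np.nan
    act_df = act.unstack("enzyme")
    n_negative = int((act_df < 0).sum().sum())
    log["n_negative_activities"] = n_negative
    if not allow_negative_activity:
        act_df = act_df.clip(lower=0.0)

    out = mc.reset_index()[["microcosm_id", "isolate_id", "moisture_whc",
                            "replicate", "initial_mass_g", "final_mass_g"]].copy()
    out["mass_loss_g"] = mass_loss.to_numpy()
    out["total_hyphal_length_m"] = out["microcosm_id"].map(total_len)
    out["growth_yield_m_per_g"] = [
        growth_yield(l, ml) if np.isfinite(l) else float("nan")
        for l, ml in zip(out["total_hyphal_length_m"], out["mass_loss_g"])]
    for enz in ENZYMES:
        if enz in act_df.columns:
            per_g = out["microcosm_id"].map(act_df[enz])
        else:
            per_g = pd.Series(np.nan, index=out.index)
            log.setdefault("missing_enzymes", []).append(enz)
        out[f"activity_{enz}"] = [
            standardize_per_microcosm(a, m) if np.isfinite(a) else float("nan")
            for a, m in zip(per_g, mass_remaining.loc[out["microcosm_id"]].to_numpy())]

    is_control = out["isolate_id"] == CONTROL_ID
    log["n_controls_excluded"] = int(is_control.sum())
    controls = out[is_control]
    if len(controls):
        log["control_summary"] = {
            "mean_total_hyphal_length_m":
                float(controls["total_hyphal_length_m"].mean()),
            "mean_mass_loss_g": float(controls["mass_loss_g"].mean()),
            **{f"mean_activity_{e}": float(controls[f"activity_{e}"].mean())
               for e in ENZYMES if f"activity_{e}" in controls},
        }
    traits = out[~is_control].reset_index(drop=True)
    log["n_undefined_yield"] = int(
        traits["growth_yield_m_per_g"].isna().sum()
        - traits["total_hyphal_length_m"].isna().sum())

    # MAI per isolate from hyphal lengths per moisture level
    agg = "mean" if mai_method == "replicate_means" else "sum"
    lengths = traits.pivot_table(index="isolate_id", columns="moisture_whc",
                                 values="total_hyphal_length_m", aggfunc=agg)
    mai_rows = []
    for iso, row in lengths.iterrows():
        vals = row.dropna()
        rec = {"isolate_id": iso}
        rec.update({f"hyphal_length_{int(round(m*100))}pct": v
                    for m, v in vals.items()})
        try:
            rec["mai_percent"] = moisture_association_index(vals.to_dict())
        except ValueError as exc:
            rec["mai_percent"] = float("nan")
            log.setdefault("mai_undefined", []).append(f"{iso}: {exc}")
        mai_rows.append(rec)
    mai = pd.DataFrame(mai_rows)
    return TraitDerivationResult(traits=traits, mai=mai, log=log)
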
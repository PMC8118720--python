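"""Simulation harnesses validating the statistical error rates.

These run the full pipeline — generate raw tables, derive traits, test —
many times under known conditions:

* type-I error of the pairwise mixed regression, using the one trait
  pair that is independent by construction under the default (diagonal)
  latent covariance: MAI (driven by the stress latent) versus growth
  yield (driven by the yield latent).  Enzyme pairs are unsuitable as a
  null because all four activities share the acquisition latent, and
  mass-remaining standardisation weakly couples MAI to the activities.
* power against a strong negative yield-acquisition trade-off
  (latent correlation rho) under low measurement noise;
* type-I error of the RDA permutation test, under a null configuration
  whose growth and enzyme responses are flat in moisture and whose
  latent variance is zero, so traits are pure noise independent of the
  moisture + species constraints;
* recovery of taxonomic variance structure when all isolate-level
  variance is injected at one rank.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .config import (ExperimentConfig, GrowthModel, NoiseSpec,
                     PermutationScheme)
from .ordination import rda_from_traits
from .stats import pairwise_trait_regression, taxonomy_variance, trait_matrix
from .synthetic import generate_experiment
from .traits import build_trait_table

#: low instrument noise for the power study (not zero: assays are never exact)
LOW_NOISE = NoiseSpec(fluorescence_sd=2.0, field_length_sigma=0.05,
                      mass_sd_g=0.005, microcosm_cv=0.02, enzyme_cv=0.02)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def latent_cov_with_rho(rho: float, sd=(0.5, 0.5, 1.0)) -> np.ndarray:
    """Default latent covariance with a yield-acquisition correlation."""
    cov = np.diag(np.square(sd)).astype(float)
    cov[0, 1] = cov[1, 0] = rho * sd[0] * sd[1]
    return cov


def _derive(cfg: ExperimentConfig):
    tab = generate_experiment(cfg)
    res = build_trait_table(tab.microcosms, tab.microscopy,
                            tab.enzyme_plates, cfg.assay, cfg.microscopy)
    return tab, res


def simulate_pair_pvalue(seed: int, response: str, predictor: str,
                         config: ExperimentConfig) -> tuple:
    """One dataset -> (slope t, p) of the requested trait pair."""
    cfg = replace(config, seed=int(seed))
    tab, res = _derive(cfg)
    data = trait_matrix(res.traits, res.mai)
    pr = pairwise_trait_regression(data, response=response,
                                   predictor=predictor,
                                   taxonomy=tab.taxonomy)
    return pr.tvalue, pr.pvalue


def pairwise_null_pvalues(n_sims: int, seed: int,
                          config: ExperimentConfig = None) -> np.ndarray:
    """Null p-values of the MAI vs growth-yield test (independent latents)."""
    if config is None:
        config = ExperimentConfig()
    seeds = _child_seeds(seed, n_sims)
    return np.array([simulate_pair_pvalue(s, "growth_yield", "mai", config)[1]
                     for s in seeds])


def pairwise_power(n_sims: int, seed: int, rho: float = -0.9) -> float:
    """Fraction of datasets where the yield-BG trade-off is detected.

    Detection = negative t with p < 0.05 for the growth-yield predictor
    of BG activity, under imposed latent correlation ``rho`` and low
    noise.
    """
    cfg = ExperimentConfig(latent_cov=latent_cov_with_rho(rho),
                           noise=LOW_NOISE)
    seeds = _child_seeds(seed, n_sims)
    hits = 0
    for s in seeds:
        t, p = simulate_pair_pvalue(s, "BG", "growth_yield", cfg)
        hits += (p < 0.05) and (np.sign(t) == np.sign(rho))
    return hits / n_sims


def rda_null_config() -> ExperimentConfig:
    """Generator configuration whose traits are independent of the
    moisture + species constraints: zero latent variance and
    moisture-flat growth/enzyme responses."""
    gm = GrowthModel(kernel_width_whc=1e6,
                     enzyme_moisture_tilt={e: 0.0 for e in
                                           ("CBH", "BG", "BX", "NAG")})
    return ExperimentConfig(latent_cov=np.zeros((3, 3)), growth_model=gm)


def rda_null_pvalues(n_sims: int, seed: int, n_perm: int = 199) -> np.ndarray:
    """Null permutation p-values of the trait-matrix RDA."""
    base = rda_null_config()
    seeds = _child_seeds(seed, n_sims)
    ps = np.empty(n_sims)
    for i, s in enumerate(seeds):
        cfg = replace(base, seed=int(s))
        tab, res = _derive(cfg)
        scheme = PermutationScheme(n_permutations=n_perm, strata="family",
                                   seed=int(s))
        result, _ = rda_from_traits(res.traits, tab.taxonomy, scheme)
        ps[i] = result.permutation_p
    return ps


def taxonomy_recovery(n_sims: int, seed: int, rank: str = "family",
                      alpha: float = 0.05) -> dict:
    """Recovery of variance injected entirely at one taxonomic rank.

    Each dataset puts 100 % of isolate-level latent variance at
    ``rank``; the log isolate-mean BG activity is then decomposed by
    rank.  Returns the fraction of runs where the rank's share exceeds
    0.8 and where its likelihood-ratio test is significant.
    """
    fractions = {"phylum": 0.0, "class": 0.0, "order": 0.0, "family": 0.0,
                 "isolate": 0.0}
    fractions[rank] = 1.0
    base = ExperimentConfig(taxonomy_variance_fractions=fractions)
    seeds = _child_seeds(seed, n_sims)
    dominant = 0
    significant = 0
    for s in seeds:
        cfg = replace(base, seed=int(s))
        tab, res = _derive(cfg)
        iso_mean = res.traits.groupby("isolate_id")["activity_BG"].mean()
        v = np.log(iso_mean.clip(lower=1e-9))
        out = taxonomy_variance(v, tab.taxonomy).set_index("rank")
        dominant += out.loc[rank, "share_parsimonious"] > 0.8
        significant += out.loc[rank, "p"] < alpha
    return {"n_sims": n_sims, "dominant_rate": dominant / n_sims,
            "significant_rate": significant / n_sims}


def specificity(n_sims: int, seed: int, alpha: float = 0.05) -> pd.DataFrame:
    """Flag rates of related vs unrelated pairs under the default model.

    Under the default generator the four enzyme activities share the
    acquisition latent (truly related), while growth yield is
    independent of MAI and of every enzyme.  Returns per-pair rejection
    frequencies over ``n_sims`` datasets.
    """
    seeds = _child_seeds(seed, n_sims)
    pairs = [("CBH", "BG"), ("mai", "growth_yield"),
             ("growth_yield", "BG"), ("growth_yield", "NAG")]
    counts = {p: 0 for p in pairs}
    cfg = ExperimentConfig()
    for s in seeds:
        c = replace(cfg, seed=int(s))
        tab, res = _derive(c)
        data = trait_matrix(res.traits, res.mai)
        for a, b in pairs:
            pr = pairwise_trait_regression(data, response=b, predictor=a,
                                           taxonomy=tab.taxonomy)
            counts[(a, b)] += pr.pvalue < alpha
    rows = [{"trait_a": a, "trait_b": b,
             "related": (a, b) == ("CBH", "BG"),
             "rejection_rate": counts[(a, b)] / n_sims}
            for a, b in pairs]
    return pd.DataFrame(rows)
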
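"""Univariate trade-off statistics.

Implements the study's univariate toolkit on the derived trait tables:

* fully factorial ANOVAs of each trait on moisture x isolate;
* rank transformation of growth yield (its raw values are strongly
  right-skewed);
* pairwise regressions between the six traits (MAI, growth yield, four
  enzyme activities) with moisture as a covariate and nested taxonomic
  random intercepts, the taxonomy-aware analogue of a phylogenetically
  controlled correlation;
* per-rank variance-component models quantifying how much of a trait is
  conserved at each taxonomic rank.

The pairwise regression is fit on isolate x moisture replicate means.
Because those rows are repeated measures of the same isolate, the model
always carries an isolate-level random intercept in addition to the
configured taxonomic ranks, and the predictor enters through a
within/between (Mundlak) decomposition; the reported slope, t and p
refer to the between-isolate component, which is the scale on which a
life-history trade-off would act.  Small-sample inference uses a
Kenward-Roger adjusted covariance with Satterthwaite degrees of
freedom (see docs/methods.md).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import ENZYMES
from .lmm import fit_lmm, indicator_matrix, kr_wald, lrt_component

#: canonical trait order for the pairwise matrix
TRAITS = ("mai", "growth_yield") + ENZYMES

DEFAULT_RANKS = ("phylum", "class", "order", "family")


def rank_transform(values) -> np.ndarray:
    """Average ranks (1..n over non-missing entries); NaN stays NaN."""
    arr = np.asarray(values, dtype=float)
    if np.isnan(arr).all():
        raise ValueError("cannot rank an all-missing vector")
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    out[ok] = sps.rankdata(arr[ok], method="average")
    return out


def factorial_anova(data: pd.DataFrame, value: str,
                    factor_a: str = "moisture_whc",
                    factor_b: str = "isolate_id") -> pd.DataFrame:
    """Two-way fully factorial ANOVA (main effects + interaction).

    Returns a table with one row per term (factor_a, factor_b,
    interaction, residual) holding sum of squares, df, mean square, F
    and p.  Type II sums of squares; for balanced layouts these equal
    the classical means-based decomposition.  A factor with a single
    level is dropped with a warning; without replication the
    interaction is untestable and omitted.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data[[value, factor_a, factor_b]].dropna().copy()
    df.columns = ["y", "a", "b"]
    df["a"] = df["a"].astype(str)
    df["b"] = df["b"].astype(str)
    terms = []
    for name, col in ((factor_a, "a"), (factor_b, "b")):
        if df[col].nunique() < 2:
            warnings.warn(f"factor {name!r} has a single level; dropped")
        else:
            terms.append(col)
    if not terms:
        raise ValueError("no factor with >= 2 levels")
    with_interaction = len(terms) == 2 and \
        (df.groupby(["a", "b"]).size() > 1).any()
    if len(terms) == 2 and not with_interaction:
        warnings.warn("no replication within cells; interaction untestable")
    formula = "y ~ " + " + ".join(f"C({t})" for t in terms)
    if with_interaction:
        formula += " + C(a):C(b)"
    fit = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-residual layouts emit noise
        tab = sm.stats.anova_lm(fit, typ=2)

    rename = {f"C({t})": name for t, name in
              (("a", factor_a), ("b", factor_b))}
    rename["C(a):C(b)"] = f"{factor_a} x {factor_b}"
    rename["Residual"] = "residual"
    tab = tab.rename(index=rename)
    out = pd.DataFrame({
        "sum_sq": tab["sum_sq"],
        "df": tab["df"].astype(int),
        "mean_sq": tab["sum_sq"] / tab["df"],
        "F": tab.get("F"),
        "p": tab.get("PR(>F)"),
    })
    ss_model = out.loc[out.index != "residual", "sum_sq"].sum()
    if ss_model <= 1e-12 * max(len(df), 1):
        out.loc[out.index != "residual", "F"] = np.nan
        out.loc[out.index != "residual", "p"] = np.nan
    out.index.name = "term"
    return out


def trait_matrix(traits: pd.DataFrame, mai: pd.DataFrame,
                 collapse_replicates: bool = True) -> pd.DataFrame:
    """Tidy isolate x moisture trait table for the pairwise analyses.

    Columns: isolate_id, moisture_whc, growth_yield, CBH..NAG, mai.
    Replicates are averaged by default (figures and pairwise tests work
    on replicate means); ``collapse_replicates=False`` keeps raw rows.
    MAI is an isolate-level trait and is constant across a given
    isolate's moisture rows.
    """
    cols = {"growth_yield_m_per_g": "growth_yield",
            **{f"activity_{e}": e for e in ENZYMES}}
    d = traits[["isolate_id", "moisture_whc", *cols]].rename(columns=cols)
    if collapse_replicates:
        d = (d.groupby(["isolate_id", "moisture_whc"], as_index=False)
             .mean())
    d = d.merge(mai[["isolate_id", "mai_percent"]]
                .rename(columns={"mai_percent": "mai"}),
                on="isolate_id", how="left")
    return d


@dataclass
class PairwiseRegressionResult:
    trait_a: str
    trait_b: str
    slope: float
    tvalue: float
    df: float
    pvalue: float
    r: float
    n: int
    model: str

    @property
    def sign_consistent(self) -> bool:
        return np.sign(self.tvalue) == np.sign(self.slope) or self.slope == 0


def _rank_columns(data: pd.DataFrame, ranks, taxonomy: pd.DataFrame):
    tax = taxonomy.set_index("isolate_id")
    used, Zs = [], []
    for rank in ranks:
        labels = tax.loc[data["isolate_id"], rank].to_numpy()
        if len(np.unique(labels)) < 2:
            continue
        used.append(rank)
        Zs.append(indicator_matrix(labels))
    return used, Zs


def pairwise_trait_regression(data: pd.DataFrame, response: str,
                              predictor: str, taxonomy: pd.DataFrame,
                              ranks: Sequence[str] = DEFAULT_RANKS,
                              rank_yield: bool = True,
                              ) -> PairwiseRegressionResult:
    """Mixed regression of one trait on another across isolates.

    Fixed effects: intercept, moisture (numeric WHC), and the predictor
    split into its between-isolate mean and within-isolate deviation;
    random intercepts at the configured taxonomic ranks plus isolate.
    The returned slope/t/p are for the between-isolate predictor term.
    ``r`` is the marginal Pearson correlation of the two (possibly
    ranked) trait columns.
    """
    d = data[["isolate_id", "moisture_whc", response, predictor]].dropna()
    if d["isolate_id"].nunique() < 2:
        raise ValueError("need >= 2 isolates")
    if d["moisture_whc"].nunique() < 2:
        raise ValueError("need >= 2 moisture levels")
    y = d[response].to_numpy(dtype=float)
    x = d[predictor].to_numpy(dtype=float)
    ranked = []
    if rank_yield and response == "growth_yield":
        y = rank_transform(y)
        ranked.append(response)
    if rank_yield and predictor == "growth_yield":
        x = rank_transform(x)
        ranked.append(predictor)

    iso = d["isolate_id"].to_numpy()
    Zi = indicator_matrix(iso)
    counts = Zi.sum(axis=0)
    x_between = Zi @ ((Zi.T @ x) / counts)
    x_within = x - x_between
    cols = [np.ones(len(d)), d["moisture_whc"].to_numpy(dtype=float), x_between]
    fixed = ["intercept", "moisture", f"{predictor}_between"]
    if np.ptp(x_within) > 1e-12 * max(np.ptp(x), 1e-300):
        cols.append(x_within)
        fixed.append(f"{predictor}_within")
    X = np.column_stack(cols)

    used_ranks, Zs = _rank_columns(d, ranks, taxonomy)
    Zs = Zs + [Zi]
    names = used_ranks + ["isolate"]
    res = kr_wald(y, X, Zs, cidx=2, names=names)
    r = float(np.corrcoef(x, y)[0, 1])
    model = (f"{response} ~ moisture + {predictor} (between/within); "
             f"random: {'/'.join(names)}"
             + (f"; ranked: {','.join(ranked)}" if ranked else ""))
    return PairwiseRegressionResult(
        trait_a=predictor, trait_b=response, slope=res.estimate,
        tvalue=res.tvalue, df=res.df, pvalue=res.pvalue, r=r,
        n=len(d), model=model)


def all_pairwise_tests(traits: pd.DataFrame, mai: pd.DataFrame,
                       taxonomy: pd.DataFrame, alpha: float = 0.05,
                       rank_yield: bool = True, include_genus: bool = False,
                       collapse_replicates: bool = True,
                       bh_correction: bool = False) -> pd.DataFrame:
    """All 15 unordered pairs of the six traits.

    The earlier trait in the canonical order (MAI, growth yield, CBH,
    BG, BX, NAG) is the predictor.  A trait that is entirely missing
    yields untested rows rather than an error.
    """
    data = trait_matrix(traits, mai, collapse_replicates)
    ranks = DEFAULT_RANKS + (("genus",) if include_genus else ())
    rows = []
    for a, b in itertools.combinations(TRAITS, 2):
        if data[a].isna().all() or data[b].isna().all():
            rows.append({"trait_a": a, "trait_b": b, "slope": np.nan,
                         "t": np.nan, "df": np.nan, "p": np.nan, "r": np.nan,
                         "n": 0, "model": "untested: trait missing"})
            continue
        res = pairwise_trait_regression(data, response=b, predictor=a,
                                        taxonomy=taxonomy, ranks=ranks,
                                        rank_yield=rank_yield)
        rows.append({"trait_a": a, "trait_b": b, "slope": res.slope,
                     "t": res.tvalue, "df": res.df, "p": res.pvalue,
                     "r": res.r, "n": res.n, "model": res.model})
    out = pd.DataFrame(rows)
    pcol = out["p"].copy()
    if bh_correction:
        from statsmodels.stats.multitest import multipletests
        ok = pcol.notna()
        adj = pcol.copy()
        if ok.any():
            adj.loc[ok] = multipletests(pcol[ok], method="fdr_bh")[1]
        out["p_adjusted"] = adj
        pcol = adj
    out["significant"] = pcol < alpha
    return out


def taxonomy_variance(values: pd.Series, taxonomy: pd.DataFrame,
                      ranks: Sequence[str] = DEFAULT_RANKS) -> pd.DataFrame:
    """Nested variance components of an isolate-level trait by rank.

    ``values`` is indexed by isolate_id.  Components are estimated by
    maximum likelihood with an intercept-only mean; each rank gets a
    boundary-corrected likelihood-ratio test.  A rank with a single
    level is reported with zero variance and no test.

    Besides the joint-fit shares, a ``share_parsimonious`` column is
    reported after backward elimination of unsupported components
    (drop the rank with the largest LRT p >= ``keep_alpha``, refit,
    repeat).  With few taxa per rank the joint fit cannot cleanly
    separate a rank's variance from chance differences at coarser
    ranks, so the parsimonious attribution is the one to read when
    asking which rank carries the signal (see docs/methods.md).
    """
    keep_alpha = 0.05
    v = values.dropna()
    if len(v) < 3:
        raise ValueError("need >= 3 isolates with data")
    tax = taxonomy.set_index("isolate_id").loc[v.index]
    y = v.to_numpy(dtype=float)
    X = np.ones((len(v), 1))
    used, Zs, degenerate = [], [], []
    for rank in ranks:
        labels = tax[rank].to_numpy()
        if len(np.unique(labels)) < 2:
            degenerate.append(rank)
            continue
        used.append(rank)
        Zs.append(indicator_matrix(labels))
    full = fit_lmm(y, X, Zs, reml=False, names=used)
    shares = full.shares()
    pvals = {}
    for i, rank in enumerate(used):
        stat, p, _ = lrt_component(y, X, Zs, drop=i, names=used)
        pvals[rank] = (stat, p)

    # backward elimination: drop the least-supported rank until all
    # retained components pass the LRT at keep_alpha
    kept, kept_Zs = list(used), list(Zs)
    kept_fit = full
    while kept:
        worst, worst_p, worst_fit = None, keep_alpha, None
        for i, rank in enumerate(kept):
            red = fit_lmm(y, X, [Z for j, Z in enumerate(kept_Zs) if j != i],
                          reml=False)
            stat = max(red.neg2loglik - kept_fit.neg2loglik, 0.0)
            p = 0.5 * sps.chi2.sf(stat, 1) if stat > 0 else 1.0
            if p >= worst_p:
                worst, worst_p, worst_fit = i, p, red
        if worst is None:
            break
        kept.pop(worst)
        kept_Zs.pop(worst)
        kept_fit = worst_fit
    if kept:
        tot = max(float(kept_fit.theta.sum()), 1e-300)
        pars = {"residual": float(kept_fit.theta[0]) / tot}
        pars.update({r: float(kept_fit.theta[i + 1]) / tot
                     for i, r in enumerate(kept)})
    else:
        pars = {"residual": 1.0}

    rows = []
    for i, rank in enumerate(used):
        stat, p = pvals[rank]
        rows.append({"rank": rank, "variance": float(full.theta[i + 1]),
                     "share": shares[rank],
                     "share_parsimonious": pars.get(rank, 0.0),
                     "chi2": stat, "p": p})
    for rank in degenerate:
        rows.append({"rank": rank, "variance": 0.0, "share": 0.0,
                     "share_parsimonious": 0.0, "chi2": np.nan, "p": np.nan})
    rows.append({"rank": "residual", "variance": full.residual,
                 "share": shares["residual"],
                 "share_parsimonious": pars.get("residual", 1.0),
                 "chi2": np.nan, "p": np.nan})
    out = pd.DataFrame(rows)
    order = {r: i for i, r in enumerate(list(ranks) + ["residual"])}
    return out.sort_values("rank", key=lambda s: s.map(order)
                           ).reset_index(drop=True)
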
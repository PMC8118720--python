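"""Redundancy analysis (RDA) of the multivariate trait matrix.

RDA regresses the (centred, optionally unit-scaled) trait matrix on a
constraint design — here moisture (numeric WHC) and species indicators
— and performs a principal component analysis of the fitted values.
The constrained variance fraction trace(fitted) / trace(total) measures
how much multivariate trait variation the constraints explain, and a
permutation test of the pseudo-F statistic assesses its significance.

Classical RDA has no random effects; the study's taxonomic hierarchy is
honoured either by restricting permutations to shuffle rows only within
a taxonomic stratum (default: family) or by partialling taxonomy ranks
out of both matrices before the analysis (partial RDA).  Both are
approximations and are recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ENZYMES, PermutationScheme

#: response columns used for the trait-matrix ordination
RESPONSE_TRAITS = ("growth_yield_m_per_g", "total_hyphal_length_m",
                   "mass_loss_g") + tuple(f"activity_{e}" for e in ENZYMES)


@dataclass
class RdaResult:
    constrained_fraction: float
    eigenvalues: np.ndarray
    site_scores: np.ndarray
    trait_scores: np.ndarray
    pseudo_f: float
    rank: int
    n: int
    trait_names: Sequence[str]
    permutation_p: Optional[float] = None
    n_permutations: Optional[int] = None
    seed: Optional[int] = None
    notes: list = field(default_factory=list)


def _orthonormal_basis(X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing SVD)."""
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    r = int((s > tol * max(s[0], 1e-300)).sum()) if s.size else 0
    return u[:, :r]


def _prepare(Y: np.ndarray, standardize: bool):
    Yc = Y - Y.mean(axis=0)
    if standardize:
        sd = Yc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Yc = Yc / sd
    return Yc


def rda_fit(Y, X, standardize: bool = True,
            condition: Optional[np.ndarray] = None,
            trait_names: Optional[Sequence[str]] = None) -> RdaResult:
    """Fit an RDA of response matrix ``Y`` on constraint design ``X``.

    ``condition`` columns, if given, are partialled out of both matrices
    first (partial RDA).  Rows must be complete cases.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be 2-D (rows = microcosms)")
    if np.isnan(Y).any() or np.isnan(X).any():
        raise ValueError("Y and X must be complete cases (drop NaN rows first)")
    n = Y.shape[0]
    notes = []
    Yc = _prepare(Y, standardize)
    Xc = X - X.mean(axis=0)
    if condition is not None:
        C = np.asarray(condition, dtype=float)
        Qc = _orthonormal_basis(C - C.mean(axis=0))
        Yc = Yc - Qc @ (Qc.T @ Yc)
        Xc = Xc - Qc @ (Qc.T @ Xc)
        notes.append(f"partialled out {Qc.shape[1]} conditioning dimensions")
    Q = _orthonormal_basis(Xc)
    rank = Q.shape[1]
    if rank == 0:
        raise ValueError("constraint design has no variation")
    if n <= rank + 1:
        raise ValueError(f"too few rows ({n}) for {rank} constraint dimensions")
    if rank < Xc.shape[1]:
        notes.append(f"rank-deficient constraints: rank {rank} < "
                     f"{Xc.shape[1]} columns")
    Yfit = Q @ (Q.T @ Yc)
    total = float((Yc ** 2).sum())
    constrained = float((Yfit ** 2).sum())
    frac = constrained / total if total > 0 else 0.0
    # PCA of fitted values; eigenvalues on the vegan-style (n-1) scale
    cross = Yfit.T @ Yfit / (n - 1)
    eigval, eigvec = np.linalg.eigh(cross)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    keep = min(rank, Y.shape[1])
    eigval, eigvec = eigval[:keep], eigvec[:, :keep]
    site = Yfit @ eigvec
    trait = eigvec * np.sqrt(eigval)[None, :]
    resid = total - constrained
    df_resid = n - 1 - rank
    pseudo_f = ((constrained / rank) / (resid / df_resid)
                if resid > 0 and df_resid > 0 else np.inf)
    if trait_names is None:
        trait_names = [f"trait_{j+1}" for j in range(Y.shape[1])]
    return RdaResult(constrained_fraction=frac, eigenvalues=eigval,
                     site_scores=site, trait_scores=trait,
                     pseudo_f=float(pseudo_f), rank=rank, n=n,
                     trait_names=list(trait_names), notes=notes)


def rda_permutation_test(Y, X, scheme: PermutationScheme,
                         standardize: bool = True,
                         strata_labels: Optional[np.ndarray] = None,
                         condition: Optional[np.ndarray] = None) -> RdaResult:
    """Permutation test of the RDA pseudo-F.

    Rows of the response are shuffled (within strata when given) and
    p = (1 + #{F* >= F_obs}) / (1 + n_permutations).
    """
    scheme.validate()
    result = rda_fit(Y, X, standardize=standardize, condition=condition)
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = Y.shape[0]
    Yc = _prepare(Y, standardize)
    Xc = X - X.mean(axis=0)
    if condition is not None:
        C = np.asarray(condition, dtype=float)
        Qc = _orthonormal_basis(C - C.mean(axis=0))
        Yc = Yc - Qc @ (Qc.T @ Yc)
        Xc = Xc - Qc @ (Qc.T @ Xc)
    Q = _orthonormal_basis(Xc)
    rank = Q.shape[1]
    total = float((Yc ** 2).sum())
    df_resid = n - 1 - rank

    if strata_labels is not None:
        strata_labels = np.asarray(strata_labels)
        if len(strata_labels) != n:
            raise ValueError("strata labels must cover every row")
        groups = [np.where(strata_labels == g)[0]
                  for g in np.unique(strata_labels)]
        if all(len(g) == 1 for g in groups):
            raise ValueError("every stratum has a single row; "
                             "permutation test degenerate")
    else:
        groups = [np.arange(n)]

    rng = np.random.default_rng(scheme.seed)
    count = 0
    idx = np.arange(n)
    for _ in range(scheme.n_permutations):
        perm = idx.copy()
        for g in groups:
            perm[g] = g[rng.permutation(len(g))]
        Yp = Yc[perm]
        constrained = float(((Q.T @ Yp) ** 2).sum())
        resid = total - constrained
        f_star = ((constrained / rank) / (resid / df_resid)
                  if resid > 0 else np.inf)
        if f_star >= result.pseudo_f - 1e-12:
            count += 1
    result.permutation_p = (1 + count) / (1 + scheme.n_permutations)
    result.n_permutations = scheme.n_permutations
    result.seed = scheme.seed
    return result


def rda_from_traits(traits: pd.DataFrame, taxonomy: pd.DataFrame,
                    scheme: PermutationScheme = PermutationScheme(),
                    mode: str = "strata", standardize: bool = True):
    """Run the trait-matrix RDA with moisture + species constraints.

    ``mode='strata'`` restricts permutations within the stratum named by
    the scheme; ``mode='partial'`` instead conditions on phylum, order
    and family indicator blocks.  Returns (RdaResult, row index used).
    """
    cols = [c for c in RESPONSE_TRAITS if c in traits.columns]
    d = traits.dropna(subset=cols).reset_index(drop=True)
    tax = taxonomy.set_index("isolate_id")
    species = tax.loc[d["isolate_id"], "species"].to_numpy()
    sp_ind = pd.get_dummies(pd.Series(species)).to_numpy(dtype=float)
    X = np.column_stack([d["moisture_whc"].to_numpy(dtype=float), sp_ind])
    Y = d[cols].to_numpy(dtype=float)
    strata = None
    condition = None
    if mode == "strata" and scheme.strata != "none":
        strata = tax.loc[d["isolate_id"], scheme.strata].to_numpy()
    elif mode == "partial":
        blocks = [pd.get_dummies(
            tax.loc[d["isolate_id"], r]).to_numpy(dtype=float)
            for r in ("phylum", "order", "family")]
        condition = np.column_stack(blocks)
    result = rda_permutation_test(Y, X, scheme, standardize=standardize,
                                  strata_labels=strata, condition=condition)
    result.trait_names = cols
    result.notes.append(f"taxonomy handled via mode={mode!r}")
    return result, d
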
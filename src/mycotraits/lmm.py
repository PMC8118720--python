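"""Small linear mixed-model engine for nested variance components.

Fits y = X beta + sum_r Z_r u_r + e with independent random intercepts
per component (u_r ~ N(0, s2_r I)) by direct (restricted) maximum
likelihood over the variance vector, which is cheap at the problem
sizes this package handles (tens of rows, <= 6 components).

Inference for a fixed-effect contrast uses the Kenward-Roger adjusted
covariance (the plug-in GLS covariance underestimates uncertainty when
variance components are estimated from few groups) together with
Satterthwaite denominator degrees of freedom.  Likelihood-ratio tests
for single variance components use the 0.5*chi2(0) + 0.5*chi2(1)
boundary mixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = ["VarianceComponents", "WaldTest", "fit_lmm", "kr_wald",
           "lrt_component", "indicator_matrix"]


def indicator_matrix(groups) -> np.ndarray:
    """0/1 design matrix of group membership (one column per level)."""
    g = np.asarray(groups)
    levels = np.unique(g)
    return (g[:, None] == levels[None, :]).astype(float)


def _neg2(theta: np.ndarray, y, X, Zs, reml: bool) -> float:
    n, p = X.shape
    V = theta[0] * np.eye(n)
    for t, Z in zip(theta[1:], Zs):
        if t > 0:
            V += t * (Z @ Z.T)
    try:
        c = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e12
    ldV = 2.0 * np.sum(np.log(np.diag(c)))
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    try:
        beta = np.linalg.solve(A, X.T @ Vi @ y)
    except np.linalg.LinAlgError:
        return 1e12
    r = y - X @ beta
    crit = ldV + float(r @ Vi @ r)
    if reml:
        sign, ldA = np.linalg.slogdet(A)
        if sign <= 0:
            return 1e12
        crit += ldA
    return crit


@dataclass
class VarianceComponents:
    """Fitted variance components; index 0 is the residual."""

    theta: np.ndarray
    names: List[str]
    neg2loglik: float
    reml: bool

    @property
    def residual(self) -> float:
        return float(self.theta[0])

    def shares(self) -> dict:
        tot = float(self.theta.sum())
        if tot <= 0:
            return {n: 0.0 for n in ["residual"] + self.names}
        vals = self.theta / tot
        return dict(zip(["residual"] + self.names, map(float, vals)))


def fit_lmm(y, X, Zs: Sequence[np.ndarray], reml: bool = True,
            names: Optional[Sequence[str]] = None) -> VarianceComponents:
    """Maximise the (restricted) likelihood over variance components."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    k = len(Zs)
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    v0 = max(float(resid @ resid) / max(n - p, 1), 1e-12)

    def obj(log_theta):
        return _neg2(np.exp(log_theta), y, X, Zs, reml)

    starts = [np.log(np.r_[0.5 * v0, np.full(k, 0.2 * v0)]),
              np.log(np.r_[v0, np.full(k, 1e-4 * v0)])]
    if k:
        starts.append(np.log(np.r_[0.05 * v0, np.full(k, 0.5 * v0)]))
    best = None
    lo, hi = np.log(v0) - 25.0, np.log(v0) + 8.0
    bounds = [(lo, hi)] * (k + 1)
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    theta = np.exp(best.x)
    # snap numerically-zero components to exactly zero
    theta[theta < v0 * np.exp(-20.0)] = 0.0
    crit = _neg2(np.maximum(theta, 0), y, X, Zs, reml)
    if names is None:
        names = [f"vc{i+1}" for i in range(k)]
    return VarianceComponents(theta=theta, names=list(names),
                              neg2loglik=float(min(crit, best.fun)), reml=reml)


@dataclass
class WaldTest:
    estimate: float
    se: float
    tvalue: float
    df: float
    pvalue: float
    vc: VarianceComponents


def _build_V(theta, n, Zs):
    V = theta[0] * np.eye(n)
    for t, Z in zip(theta[1:], Zs):
        if t > 0:
            V += t * (Z @ Z.T)
    return V


def kr_wald(y, X, Zs: Sequence[np.ndarray], cidx: int,
            names: Optional[Sequence[str]] = None) -> WaldTest:
    """Wald test of the fixed-effect coefficient ``cidx``.

    Standard error from the Kenward-Roger first-order adjusted
    covariance; degrees of freedom by Satterthwaite on the adjusted
    variance, capped at the residual df.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    vc = fit_lmm(y, X, Zs, reml=True, names=names)
    theta = vc.theta.copy()
    # deterministic responses drive every component to zero; keep V
    # invertible so the (enormous) t statistic is still computable
    theta[0] = max(theta[0], 1e-12 * max(float(np.var(y)), 1e-6))
    Gs = [np.eye(n)] + [Z @ Z.T for Z in Zs]
    V = _build_V(theta, n, Zs)
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    Phi = np.linalg.inv(A)
    beta = Phi @ X.T @ Vi @ y

    # numeric Hessian of the -2 REML criterion at theta (natural scale)
    k1 = len(theta)
    hs = np.array([1e-4 * max(t, 1e-8 * max(theta.max(), 1e-12))
                   for t in theta])
    H = np.zeros((k1, k1))
    def f(th):
        return _neg2(np.maximum(th, 0.0), y, X, Zs, reml=True)
    for i in range(k1):
        for j in range(i, k1):
            tpp = theta.copy(); tpp[i] += hs[i]; tpp[j] += hs[j]
            tpm = theta.copy(); tpm[i] += hs[i]; tpm[j] -= hs[j]
            tmp = theta.copy(); tmp[i] -= hs[i]; tmp[j] += hs[j]
            tmm = theta.copy(); tmm[i] -= hs[i]; tmm[j] -= hs[j]
            H[i, j] = H[j, i] = ((f(tpp) - f(tpm) - f(tmp) + f(tmm))
                                 / (4 * hs[i] * hs[j]))
    W = 2.0 * np.linalg.pinv(H)   # asymptotic covariance of theta-hat

    VG = [Vi @ G for G in Gs]
    Pm = [-(X.T @ vg @ Vi @ X) for vg in VG]
    M = np.zeros((p, p))
    for i in range(k1):
        for j in range(k1):
            M += W[i, j] * ((X.T @ VG[i] @ VG[j] @ Vi @ X)
                            - Pm[i] @ Phi @ Pm[j])
    PhiA = Phi + 2.0 * Phi @ M @ Phi
    se2 = float(PhiA[cidx, cidx])
    if not np.isfinite(se2) or se2 <= 0:
        se2 = float(Phi[cidx, cidx])

    def plug_var(th):
        Vv = _build_V(np.maximum(th, 1e-14), n, Zs)
        return float(np.linalg.inv(X.T @ np.linalg.inv(Vv) @ X)[cidx, cidx])

    g = np.zeros(k1)
    for i in range(k1):
        tp = theta.copy(); tp[i] += hs[i]
        tm = theta.copy(); tm[i] = max(tm[i] - hs[i], 0.0)
        g[i] = (plug_var(tp) - plug_var(tm)) / (tp[i] - tm[i])
    denom = float(g @ W @ g)
    if denom > 0:
        df = 2.0 * se2 ** 2 / denom
        df = float(min(max(df, 1.0), n - p))
    else:
        df = float(n - p)
    se = np.sqrt(se2)
    t = float(beta[cidx] / se)
    pval = float(2.0 * stats.t.sf(abs(t), df))
    return WaldTest(estimate=float(beta[cidx]), se=float(se), tvalue=t,
                    df=df, pvalue=pval, vc=vc)


def lrt_component(y, X, Zs: Sequence[np.ndarray], drop: int,
                  names: Optional[Sequence[str]] = None):
    """Boundary-corrected LRT for variance component ``drop`` (ML fits).

    Returns (chi2 statistic, p-value) using the half-half mixture of
    chi2(0) and chi2(1) appropriate for a variance tested at zero.
    """
    full = fit_lmm(y, X, Zs, reml=False, names=names)
    reduced = fit_lmm(y, X, [Z for i, Z in enumerate(Zs) if i != drop],
                      reml=False)
    stat = max(reduced.neg2loglik - full.neg2loglik, 0.0)
    p = 0.5 * stats.chi2.sf(stat, 1) if stat > 0 else 1.0
    return stat, p, full
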
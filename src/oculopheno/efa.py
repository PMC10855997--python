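"""Maximum-likelihood exploratory factor analysis with oblique rotation.

The m-factor model decomposes the indicator correlation matrix as
``Sigma = Lambda Lambda' + Psi`` with ``Psi`` diagonal (uniquenesses).  The
ML discrepancy

    F(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

is minimized by profiling the loadings out analytically for fixed
uniquenesses (Lawley-Maxwell): given ``Psi``, the optimal loadings come
from the leading eigenpairs of ``Psi^-1/2 S Psi^-1/2``, leaving a smooth
p-dimensional optimization over the uniquenesses that L-BFGS-B handles with
an analytic gradient.  Oblimin (quartimin) rotation is applied via the
gradient-projection algorithm; fit indices use the plain ML chi-square
(robust corrections are not implemented and outputs are labelled
accordingly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: Lower bound on uniquenesses; hitting it flags a Heywood case.
PSI_FLOOR = 0.005


@dataclass
class FactorModel:
    """A fitted and rotated m-factor solution on the correlation metric."""

    loadings: pd.DataFrame          # p x m pattern matrix
    factor_correlations: np.ndarray  # m x m
    uniquenesses: pd.Series         # p
    f_min: float                    # ML discrepancy at the optimum
    n_obs: int | None = None
    heywood: bool = False
    rotation: str = "oblimin"
    estimator: str = "ML (non-robust)"

    @property
    def p(self) -> int:
        return self.loadings.shape[0]

    @property
    def m(self) -> int:
        return self.loadings.shape[1]

    def communalities(self) -> pd.Series:
        return 1.0 - self.uniquenesses


@dataclass
class FitIndices:
    """Plain-ML global fit statistics for a factor model."""

    chi_square: float
    df: int
    p_value: float
    cfi: float
    tli: float | None
    rmsea: float | None
    srmr: float
    estimator: str = "ML (non-robust)"


def efa_df(p: int, m: int) -> int:
    """Degrees of freedom of the m-factor model on p indicators:
    ``((p - m)^2 - (p + m)) / 2``."""
    if p < 1 or m < 0:
        raise ValueError("need p >= 1 and m >= 0")
    df2 = (p - m) ** 2 - (p + m)
    if df2 % 2:
        raise ValueError(f"non-integer df for p={p}, m={m}")
    df = df2 // 2
    if df < 0:
        raise ValueError(f"model with p={p}, m={m} is not identified (df={df})")
    return df


def max_factors(p: int) -> int:
    """Largest m with non-negative degrees of freedom (Ledermann bound)."""
    m = 0
    while True:
        if (p - (m + 1)) ** 2 - (p + m + 1) < 0:
            return m
        m += 1


# --------------------------------------------------------------------------
# ML estimation (uniqueness-profiled likelihood)
# --------------------------------------------------------------------------

def _profiled_objective(psi, S, m):
    sc = 1.0 / np.sqrt(psi)
    Sstar = S * np.outer(sc, sc)
    vals = np.linalg.eigvalsh(Sstar)[::-1]
    tail = vals[m:]
    return float(np.sum(tail - np.log(tail) - 1.0))


def _profiled_gradient(psi, S, m):
    sc = 1.0 / np.sqrt(psi)
    Sstar = S * np.outer(sc, sc)
    vals, vecs = np.linalg.eigh(Sstar)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    lam = vecs[:, :m] * np.sqrt(np.maximum(vals[:m] - 1.0, 0.0))
    load = lam * np.sqrt(psi)[:, None]
    g = load @ load.T + np.diag(psi) - S
    return np.diag(g) / psi ** 2


def _unrotated_loadings(psi, S, m):
    sc = 1.0 / np.sqrt(psi)
    Sstar = S * np.outer(sc, sc)
    vals, vecs = np.linalg.eigh(Sstar)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    lam = vecs[:, :m] * np.sqrt(np.maximum(vals[:m] - 1.0, 0.0))
    return lam * np.sqrt(psi)[:, None]


def _fit_ml(S: np.ndarray, m: int, n_starts: int = 5, seed: int = 0):
    """Minimize the profiled discrepancy over uniquenesses, multi-start."""
    p = S.shape[0]
    rng = np.random.default_rng(seed)
    inv_diag = np.diag(np.linalg.inv(S))
    base = (1 - 0.5 * m / p) / inv_diag          # factanal-style start
    starts = [np.clip(base, PSI_FLOOR, 1.0)]
    for _ in range(n_starts - 1):
        starts.append(np.clip(base * rng.uniform(0.5, 1.5, size=p),
                              PSI_FLOOR, 1.0))
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _profiled_objective, x0, args=(S, m), jac=_profiled_gradient,
            method="L-BFGS-B", bounds=[(PSI_FLOOR, 1.0)] * p,
            options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    psi = best.x
    return psi, float(best.fun)


# --------------------------------------------------------------------------
# Oblimin rotation (gradient projection algorithm)
# --------------------------------------------------------------------------

def _quartimin(L):
    """Quartimin criterion (oblimin with gamma = 0) and its gradient."""
    m = L.shape[1]
    N = np.ones((m, m)) - np.eye(m)
    L2 = L ** 2
    X = L2 @ N
    f = np.sum(L2 * X) / 4.0
    G = L * X
    return f, G


def _gpa_oblique(A, maxiter=2000, tol=1e-10):
    """Oblique gradient-projection rotation of unrotated loadings ``A``."""
    m = A.shape[1]
    T = np.eye(m)
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin(L)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    for _ in range(maxiter):
        Gp = G - T @ np.diag(np.diag(T.T @ G))
        s = np.linalg.norm(Gp)
        if s < tol:
            break
        al *= 2.0
        for _ in range(30):
            X = T - al * Gp
            X = X / np.sqrt(np.sum(X ** 2, axis=0))
            Ti = np.linalg.inv(X)
            Lt = A @ Ti.T
            ft, Gq = _quartimin(Lt)
            if ft < f - 0.5 * s ** 2 * al:
                break
            al /= 2.0
        T, f, L = X, ft, Lt
        G = -(L.T @ Gq @ np.linalg.inv(T)).T
    phi = T.T @ T
    return L, phi


def _order_and_sign(L, phi):
    """Canonical column order (descending explained variance) and signs
    (largest-magnitude loading positive per column)."""
    ssq = np.sum(L ** 2, axis=0)
    order = np.argsort(ssq)[::-1]
    L = L[:, order]
    phi = phi[np.ix_(order, order)]
    signs = np.array([np.sign(col[np.argmax(np.abs(col))]) or 1.0
                      for col in L.T])
    L = L * signs
    phi = phi * np.outer(signs, signs)
    return L, phi


# --------------------------------------------------------------------------
# Public fitting interface
# --------------------------------------------------------------------------

def fit_efa(data: pd.DataFrame, m: int, rotate: bool = True,
            seed: int = 0) -> FactorModel:
    """Fit an m-factor ML model to an indicator table.

    Estimation runs on the sample correlation matrix of the (complete
    rows of the) supplied table.  After fitting, quartimin rotation is
    applied and columns are ordered by explained variance with the
    dominant loading of each factor made positive.  A uniqueness at the
    lower bound is flagged as a Heywood case (warning, bounded estimate).
    """
    X = data.dropna()
    n, p = X.shape
    if n <= p:
        raise ValueError("need more complete observations than indicators")
    if m > max_factors(p):
        raise ValueError(
            f"{m}-factor model on {p} indicators is not identified "
            f"(max m = {max_factors(p)})")
    S = np.corrcoef(X.to_numpy(), rowvar=False)
    return fit_efa_from_corr(S, n_obs=n, m=m, names=list(X.columns),
                             rotate=rotate, seed=seed)


def fit_efa_from_corr(S: np.ndarray, n_obs: int, m: int,
                      names: list[str] | None = None, rotate: bool = True,
                      seed: int = 0) -> FactorModel:
    """Fit from a precomputed correlation matrix (n_obs for fit indices)."""
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    names = names or [f"x{j}" for j in range(p)]
    if np.linalg.eigvalsh(S).min() <= 1e-10:
        raise ValueError("correlation matrix is not positive-definite")
    efa_df(p, m)  # raises if not identified
    psi, fmin = _fit_ml(S, m)
    # boundary region, not just the exact bound: L-BFGS-B may stall a hair
    # above the floor on the flat face of a Heywood solution
    heywood = bool(np.any(psi <= 2 * PSI_FLOOR))
    if heywood:
        warnings.warn("Heywood case: uniqueness bounded at "
                      f"{PSI_FLOOR}", stacklevel=2)
    A = _unrotated_loadings(psi, S, m)
    if rotate and m > 1:
        L, phi = _gpa_oblique(A)
    else:
        L, phi = A, np.eye(m)
    L, phi = _order_and_sign(L, phi)
    return FactorModel(
        loadings=pd.DataFrame(L, index=names,
                              columns=[f"F{j + 1}" for j in range(m)]),
        factor_correlations=phi,
        uniquenesses=pd.Series(psi, index=names),
        f_min=fmin, n_obs=n_obs, heywood=heywood,
        rotation="oblimin" if (rotate and m > 1) else "none")


def fit_indices(model: FactorModel, n: int | None = None,
                S: np.ndarray | None = None) -> FitIndices:
    """Chi-square and incremental/absolute fit indices for a fitted model.

    ``chi2 = (n - 1) * F_min``; the baseline is the independence model
    whose discrepancy on a correlation matrix is ``-ln|S|``.  With
    ``df = 0`` the TLI and RMSEA are undefined and reported as absent.
    SRMR needs the sample correlation matrix ``S`` (the root mean square
    of the residual correlations, diagonal included).
    """
    n = n or model.n_obs
    if n is None or n <= model.p:
        raise ValueError("need sample size n > p")
    df = efa_df(model.p, model.m)
    chi2 = (n - 1) * model.f_min
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")

    L = model.loadings.to_numpy()
    phi = model.factor_correlations
    sigma = L @ phi @ L.T + np.diag(model.uniquenesses.to_numpy())

    if S is None:
        # residual-based quantities need S; reconstruct exactly-fit values
        srmr = 0.0
        f_base = None
    else:
        S = np.asarray(S, dtype=float)
        resid = S - sigma
        iu = np.triu_indices(model.p)
        srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
        f_base = float(-np.linalg.slogdet(S)[1])
    if f_base is None:
        raise ValueError("fit_indices requires the sample correlation matrix")

    df_base = model.p * (model.p - 1) // 2
    chi2_base = (n - 1) * f_base
    num = max(chi2 - df, 0.0)
    den = max(chi2_base - df_base, chi2 - df, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    if df > 0 and df_base > 0 and chi2_base > df_base:
        tli = ((chi2_base / df_base) - (chi2 / df)) / ((chi2_base / df_base) - 1)
        tli = min(tli, 1.0)
    else:
        tli = None
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))) if df > 0 \
        else None
    return FitIndices(chi_square=float(chi2), df=df, p_value=p_value,
                      cfi=float(cfi), tli=tli, rmsea=rmsea, srmr=srmr)


def significant_loadings(model: FactorModel, threshold: float = 0.4,
                         ) -> tuple[dict[str, list[str]], list[str]]:
    """Indicators loading beyond ``threshold`` (absolute pattern loading)
    per factor, plus the list of indicators loading on no factor."""
    mapping: dict[str, list[str]] = {}
    loaded = set()
    for fac in model.loadings.columns:
        hits = model.loadings.index[
            model.loadings[fac].abs() > threshold].tolist()
        mapping[fac] = hits
        loaded.update(hits)
    unloaded = [ind for ind in model.loadings.index if ind not in loaded]
    return mapping, unloaded


def efa_sweep(data: pd.DataFrame, m_range=range(1, 7),
              seed: int = 0) -> pd.DataFrame:
    """Fit a range of factor counts and tabulate their fit indices.

    Factor counts beyond the identification bound for the supplied
    indicator set are skipped.
    """
    X = data.dropna()
    S = np.corrcoef(X.to_numpy(), rowvar=False)
    rows = []
    cap = max_factors(X.shape[1])
    for m in m_range:
        if m > cap:
            continue
        model = fit_efa(data, m, seed=seed)
        fi = fit_indices(model, S=S)
        rows.append({"m": m, "F_min": model.f_min,
                     "chi_square": fi.chi_square, "df": fi.df,
                     "p_value": fi.p_value, "CFI": fi.cfi, "TLI": fi.tli,
                     "RMSEA": fi.rmsea, "SRMR": fi.srmr,
                     "heywood": model.heywood})
    return pd.DataFrame(rows)
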
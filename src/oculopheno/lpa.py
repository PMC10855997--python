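"""Latent profile analysis.

Multi-start EM for Gaussian profile mixtures (profile-specific means,
shared diagonal variances by default), model selection by BIC and the
parametric bootstrap likelihood ratio test, relative entropy and
classification diagnostics, and severity-labelled profile reports.

The fitting protocol mirrors common mixture-modelling practice: many
random starts run for a short burn-in, the best few run to convergence,
and the replication count of the best log-likelihood is reported so a
non-replicated (potentially local) solution is visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .derived import severity_label

_VAR_FLOOR = 1e-6
_LOG2PI = np.log(2 * np.pi)


@dataclass
class ProfileModel:
    """A fitted K-profile Gaussian mixture."""

    weights: np.ndarray            # K
    means: np.ndarray              # K x d
    variances: np.ndarray          # d (shared) or K x d (class-varying)
    log_likelihood: float
    posteriors: np.ndarray         # n x K
    columns: list[str]
    covariance: str = "shared_diagonal"
    n_starts_run: int = 0
    ll_replications: int = 1
    converged: bool = True

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def d(self) -> int:
        return self.means.shape[1]

    @property
    def n(self) -> int:
        return self.posteriors.shape[0]

    @property
    def n_parameters(self) -> int:
        var_par = self.d if self.covariance == "shared_diagonal" \
            else self.K * self.d
        return self.K * self.d + var_par + (self.K - 1)


def _log_density(X, weights, means, variances, covariance):
    """n x K matrix of log(pi_k) + log N(x_i | mu_k, V_k)."""
    n, d = X.shape
    if covariance == "shared_diagonal":
        iv = 1.0 / variances
        lv = np.sum(np.log(variances))
        # ||x - mu||^2_V expanded to avoid the n x K x d intermediate
        q = (X ** 2 @ iv)[:, None] - 2.0 * (X * iv) @ means.T \
            + np.sum(means ** 2 * iv, axis=1)
        out = -0.5 * (d * _LOG2PI + lv + q)
    else:
        K = len(weights)
        out = np.empty((n, K))
        for k in range(K):
            lv = np.sum(np.log(variances[k]))
            z = (X - means[k]) ** 2 / variances[k]
            out[:, k] = -0.5 * (d * _LOG2PI + lv + z.sum(axis=1))
    return out + np.log(weights)


def _em(X, weights, means, variances, covariance, max_iter, tol):
    """Run EM to convergence; returns parameters, LL and posteriors."""
    n, d = X.shape
    ll_prev = -np.inf
    for _ in range(max_iter):
        logp = _log_density(X, weights, means, variances, covariance)
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        R = np.exp(logp - norm[:, None])
        nk = R.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (R.T @ X) / nk[:, None]
        if covariance == "shared_diagonal":
            sq = np.sum(X ** 2, axis=0) - nk @ means ** 2
            variances = np.maximum(sq / n, _VAR_FLOOR)
        else:
            variances = np.empty_like(means)
            for k in range(len(nk)):
                diff = X - means[k]
                variances[k] = np.maximum(
                    (R[:, k] @ diff ** 2) / nk[k], _VAR_FLOOR)
        if ll - ll_prev < tol * max(1.0, abs(ll)) and ll >= ll_prev:
            ll_prev = ll
            break
        ll_prev = ll
    logp = _log_density(X, weights, means, variances, covariance)
    norm = logsumexp(logp, axis=1)
    R = np.exp(logp - norm[:, None])
    return weights, means, variances, float(norm.sum()), R


def _random_init(X, K, rng):
    n, d = X.shape
    idx = rng.choice(n, size=K, replace=False)
    means = X[idx] + rng.normal(scale=0.1, size=(K, d)) * X.std(axis=0)
    variances = np.maximum(X.var(axis=0), _VAR_FLOOR)
    weights = np.full(K, 1.0 / K)
    return weights, means, variances


def fit_lpa(data, K: int, n_starts: int = 250, n_final: int = 50,
            seed: int = 0, covariance: str = "shared_diagonal",
            burn_in: int = 20, max_iter: int = 1000,
            tol: float = 1e-8) -> ProfileModel:
    """Fit a K-profile mixture by multi-start EM.

    ``n_starts`` random initializations run for ``burn_in`` EM iterations;
    the ``n_final`` best then run to convergence (relative log-likelihood
    change below ``tol``).  The returned model carries the replication
    count of the best final-stage log-likelihood; a count of 1 triggers a
    warning since an unreplicated maximum may be local.  Profiles are
    reported in canonical order (descending mixing weight).
    """
    X, columns = _as_matrix(data)
    n, d = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError("K may not exceed the number of observations")
    if np.isnan(X).any():
        raise ValueError("input contains missing values; impute first "
                         "or drop incomplete rows")
    if n_final > n_starts:
        raise ValueError("n_final may not exceed n_starts")
    rng = np.random.default_rng(seed)

    if K == 1:
        w = np.ones(1)
        mu = X.mean(axis=0, keepdims=True)
        var = np.maximum(X.var(axis=0), _VAR_FLOOR)
        if covariance != "shared_diagonal":
            var = var[None, :].repeat(1, axis=0)
        w, mu, var, ll, R = _em(X, w, mu, var, covariance, 2, tol)
        return ProfileModel(weights=w, means=mu, variances=var,
                            log_likelihood=ll, posteriors=R, columns=columns,
                            covariance=covariance, n_starts_run=1,
                            ll_replications=1)

    stage1 = []
    for _ in range(n_starts):
        w, mu, var = _random_init(X, K, rng)
        if covariance != "shared_diagonal":
            var = np.tile(var, (K, 1))
        w, mu, var, ll, _ = _em(X, w, mu, var, covariance, burn_in, tol)
        stage1.append((ll, w, mu, var))
    stage1.sort(key=lambda t: t[0], reverse=True)

    finals = []
    for ll0, w, mu, var in stage1[:n_final]:
        w, mu, var, ll, R = _em(X, w, mu, var, covariance, max_iter, tol)
        finals.append((ll, w, mu, var, R))
    finals.sort(key=lambda t: t[0], reverse=True)
    best_ll = finals[0][0]
    reps = sum(1 for f in finals if abs(f[0] - best_ll) < 1e-4 * max(1, abs(best_ll)))
    if reps == 1 and n_final > 1:
        warnings.warn("best log-likelihood was not replicated across "
                      "final-stage starts; solution may be local",
                      stacklevel=2)
    ll, w, mu, var, R = finals[0]

    order = np.argsort(w)[::-1]          # canonical: largest profile first
    w, mu, R = w[order], mu[order], R[:, order]
    if covariance != "shared_diagonal":
        var = var[order]
    return ProfileModel(weights=w, means=mu, variances=var,
                        log_likelihood=ll, posteriors=R, columns=columns,
                        covariance=covariance, n_starts_run=n_starts,
                        ll_replications=reps)


def _as_matrix(data):
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.columns)
    X = np.asarray(data, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def bic(model: ProfileModel, n: int | None = None) -> float:
    """Bayesian information criterion, ``-2 LL + n_par ln(n)``."""
    n = n or model.n
    return -2.0 * model.log_likelihood + model.n_parameters * np.log(n)


def entropy(model: ProfileModel) -> float:
    """Relative entropy of the classification,
    ``1 - sum(-p ln p) / (n ln K)`` with ``0 ln 0 = 0``."""
    if model.K < 2:
        raise ValueError("entropy undefined for a single profile")
    P = model.posteriors
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, -P * np.log(P), 0.0)
    return float(1.0 - terms.sum() / (model.n * np.log(model.K)))


def sample_from(model: ProfileModel, n: int,
                rng: np.random.Generator) -> np.ndarray:
    """Parametric draw of ``n`` observations from a fitted mixture."""
    comp = rng.choice(model.K, size=n, p=model.weights)
    if model.covariance == "shared_diagonal":
        sd = np.sqrt(model.variances)
        return model.means[comp] + rng.normal(size=(n, model.d)) * sd
    sd = np.sqrt(model.variances)[comp]
    return model.means[comp] + rng.normal(size=(n, model.d)) * sd


def blrt(data, K: int, n_boot: int = 100, seed: int = 0,
         n_starts: int = 20, n_final: int = 4,
         covariance: str = "shared_diagonal",
         burn_in: int = 20, tol: float = 1e-8,
         max_failure_frac: float = 0.1) -> dict:
    """Bootstrap likelihood ratio test of K-1 vs K profiles.

    The observed statistic is ``2 (LL_K - LL_{K-1})``.  Bootstrap datasets
    are drawn from the fitted (K-1)-profile model and both models are
    refitted to each; the p-value is
    ``(1 + #{bootstrap stat >= observed}) / (n_boot + 1)``.  A bootstrap
    fit whose statistic is negative (the K-profile EM undershot the
    (K-1)-profile likelihood) is retried with double the starts and then
    clamped to zero; more than ``max_failure_frac`` unresolved fits abort.
    """
    if K < 2:
        raise ValueError("K must be >= 2 for the BLRT")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    X, _ = _as_matrix(data if not isinstance(data, pd.DataFrame) else data)
    rng = np.random.default_rng(seed)
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_boot + 2)

    null = fit_lpa(X, K - 1, n_starts=n_starts, n_final=n_final,
                   seed=int(seeds[0]), covariance=covariance,
                   burn_in=burn_in, tol=tol)
    alt = fit_lpa(X, K, n_starts=n_starts, n_final=n_final,
                  seed=int(seeds[1]), covariance=covariance,
                  burn_in=burn_in, tol=tol)
    observed = 2.0 * (alt.log_likelihood - null.log_likelihood)

    stats = np.empty(n_boot)
    failures = 0
    for b in range(n_boot):
        Xb = sample_from(null, len(X), rng)
        s0 = int(seeds[2 + 2 * b])
        s1 = int(seeds[3 + 2 * b])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m0 = fit_lpa(Xb, K - 1, n_starts=n_starts, n_final=n_final,
                         seed=s0, covariance=covariance,
                         burn_in=burn_in, tol=tol)
            m1 = fit_lpa(Xb, K, n_starts=n_starts, n_final=n_final,
                         seed=s1, covariance=covariance,
                         burn_in=burn_in, tol=tol)
            stat = 2.0 * (m1.log_likelihood - m0.log_likelihood)
            if stat < 0:
                m1 = fit_lpa(Xb, K, n_starts=2 * n_starts,
                             n_final=2 * n_final, seed=s1 + 1,
                             covariance=covariance,
                             burn_in=burn_in, tol=tol)
                stat = 2.0 * (m1.log_likelihood - m0.log_likelihood)
                if stat < 0:
                    failures += 1
                    stat = 0.0
        stats[b] = stat
    if failures > max_failure_frac * n_boot:
        raise RuntimeError(
            f"{failures}/{n_boot} bootstrap fits failed to converge")
    p = (1.0 + np.sum(stats >= observed)) / (n_boot + 1.0)
    return {"K": K, "statistic": observed, "p_value": float(p),
            "bootstrap_stats": stats, "n_boot": n_boot,
            "failures": failures}


def select_model(fits: dict[int, ProfileModel],
                 blrt_results: dict[int, dict] | None = None,
                 alpha: float = 0.05) -> tuple[ProfileModel, pd.DataFrame]:
    """Choose the profile count from a candidate sweep.

    Policy: the smallest K whose BIC attains the candidate minimum; when a
    BLRT for K+1 is available and significant at ``alpha`` the decision
    trace records the disagreement (BIC wins, ties toward smaller K).  If
    the minimum sits at the largest candidate with BIC still decreasing, a
    boundary warning is issued.
    """
    if not fits:
        raise ValueError("no fitted candidates supplied")
    ks = sorted(fits)
    rows = []
    for k in ks:
        model = fits[k]
        row = {"K": k, "LL": model.log_likelihood,
               "n_parameters": model.n_parameters, "BIC": bic(model),
               "entropy": entropy(model) if k > 1 else np.nan,
               "ll_replications": model.ll_replications}
        if blrt_results and k in blrt_results:
            row["BLRT_p"] = blrt_results[k]["p_value"]
        rows.append(row)
    trace = pd.DataFrame(rows).set_index("K")
    bics = trace["BIC"]
    best_k = int(bics.idxmin())
    for k in ks:                       # ties toward smaller K
        if np.isclose(bics.loc[k], bics.min()):
            best_k = k
            break
    if best_k == ks[-1] and len(ks) > 1 and \
            bics.loc[ks[-1]] < bics.loc[ks[-2]]:
        warnings.warn("BIC still decreasing at the largest candidate K; "
                      "the sweep may be too short", stacklevel=2)
    if blrt_results and (best_k + 1) in blrt_results and \
            blrt_results[best_k + 1]["p_value"] <= alpha:
        warnings.warn(
            f"BLRT favours {best_k + 1} profiles (p = "
            f"{blrt_results[best_k + 1]['p_value']:.3g}) while BIC selects "
            f"{best_k}; keeping the BIC choice", stacklevel=2)
    return fits[best_k], trace


def classify(model: ProfileModel,
             min_avg_probability: float = 0.9) -> dict:
    """Modal class assignments with classification diagnostics.

    Returns the modal assignment per row, the average posterior
    probability of the assigned class per profile, and flags profiles
    whose average falls below ``min_avg_probability``.
    """
    assign = model.posteriors.argmax(axis=1)
    avg = np.full(model.K, np.nan)
    for k in range(model.K):
        sel = assign == k
        if sel.any():
            avg[k] = model.posteriors[sel, k].mean()
    flagged = [int(k) for k in range(model.K)
               if np.isfinite(avg[k]) and avg[k] < min_avg_probability]
    return {"assignments": assign, "avg_class_probability": avg,
            "flagged_profiles": flagged}


def profile_report(model: ProfileModel, zscores: pd.DataFrame,
                   demographics: pd.DataFrame | None = None,
                   inverted: tuple[str, ...] = ("RNFL",),
                   profile_names: list[str] | None = None) -> pd.DataFrame:
    """Per-profile indicator summary with severity labels.

    For each modal profile: size, per-indicator mean z, standard error
    (ML, non-robust: posterior-weighted within-profile SD over sqrt(n)),
    median (for skew inspection) and a severity label.  RNFL is labelled
    on the inverted scale.  Empty profiles are omitted with a warning.
    """
    diag = classify(model)
    assign = diag["assignments"]
    rows = []
    for k in range(model.K):
        sel = assign == k
        n_k = int(sel.sum())
        if n_k == 0:
            warnings.warn(f"profile {k} has no modal members; omitted",
                          stacklevel=2)
            continue
        name = profile_names[k] if profile_names else f"profile_{k + 1}"
        sub = zscores.loc[sel]
        for col in zscores.columns:
            vals = sub[col].dropna()
            mean = float(vals.mean()) if len(vals) else np.nan
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) \
                if len(vals) > 1 else np.nan
            row = {
                "profile": name, "k": k, "n": n_k, "indicator": col,
                "mean_z": mean, "se": se,
                "median_z": float(vals.median()) if len(vals) else np.nan,
                "severity": severity_label(mean, inverted=col in inverted)
                if np.isfinite(mean) else "n/a",
                "exceeds_1sd": bool(np.isfinite(mean) and
                                    (mean < -1 if col in inverted
                                     else mean > 1)),
            }
            rows.append(row)
        if demographics is not None:
            dem = demographics.loc[sel]
            extra = {"profile": name, "k": k, "n": n_k}
            if "age" in dem:
                extra["mean_age"] = float(dem["age"].mean())
            if "sex" in dem:
                extra["pct_female"] = 100.0 * float((dem["sex"] == "F").mean())
            if "group" in dem:
                extra["pct_cdms"] = 100.0 * float((dem["group"] == "CDMS").mean())
            rows.append({**extra, "indicator": "_demographics",
                         "mean_z": np.nan, "se": np.nan,
                         "median_z": np.nan, "severity": "n/a",
                         "exceeds_1sd": False})
    return pd.DataFrame(rows)


def lpa_sweep(data, k_range=range(1, 7), n_starts: int = 250,
              n_final: int = 50, seed: int = 0,
              covariance: str = "shared_diagonal",
              ) -> dict[int, ProfileModel]:
    """Fit every candidate profile count with seeds derived from ``seed``."""
    seeds = np.random.SeedSequence(seed).generate_state(len(list(k_range)))
    fits = {}
    for s, k in zip(seeds, k_range):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits[k] = fit_lpa(data, k, n_starts=n_starts, n_final=n_final,
                              seed=int(s), covariance=covariance)
    return fits
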
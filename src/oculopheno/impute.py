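"""Multiple imputation of missing indicator values.

Chained-equation imputation with predictive mean matching (backed by
statsmodels' MICE machinery) and Rubin-rules pooling of per-dataset
estimates.  A pairwise-deletion sensitivity path is available downstream by
simply skipping imputation.
"""

from __future__ import annotations

import contextlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.imputation.mice import MICEData


@dataclass
class ImputationResult:
    """``m`` completed copies of the input table.

    Observed cells are identical across all datasets; ``missing_mask``
    flags the cells that were imputed.
    """

    datasets: list[pd.DataFrame]
    missing_mask: pd.DataFrame
    seed: int

    @property
    def m(self) -> int:
        return len(self.datasets)


@contextlib.contextmanager
def _legacy_numpy_seed(seed: int):
    """statsmodels' MICE draws from the legacy global RNG; scope it."""
    state = np.random.get_state()
    np.random.seed(seed % (2 ** 31))
    try:
        yield
    finally:
        np.random.set_state(state)


def impute(data: pd.DataFrame, m: int = 25, iterations: int = 10,
           seed: int = 0, k_pmm: int = 5) -> ImputationResult:
    """Multiply impute missing cells by chained equations.

    Each of the ``m`` completed datasets is produced by ``iterations``
    cycles of conditional draws with predictive mean matching (``k_pmm``
    donors).  Observed cells are never altered; the whole procedure is
    deterministic under ``seed``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    num = data.select_dtypes(include=[np.number])
    fully_missing = [c for c in num.columns if num[c].notna().sum() == 0]
    if fully_missing:
        raise ValueError(
            f"column(s) fully missing, cannot impute: {fully_missing}")
    mask = num.isna()

    if not mask.to_numpy().any():
        return ImputationResult([data.copy() for _ in range(m)], mask, seed)

    # MICEData requires patsy-friendly names; map and restore.
    safe = {c: f"v{j}" for j, c in enumerate(num.columns)}
    back = {v: k for k, v in safe.items()}
    seeds = np.random.SeedSequence(seed).generate_state(m)
    datasets = []
    for s in seeds:
        with _legacy_numpy_seed(int(s)):
            md = MICEData(num.rename(columns=safe).reset_index(drop=True),
                          k_pmm=k_pmm)
            md.update_all(iterations)
        done = md.data.rename(columns=back)
        done.index = num.index
        full = data.copy()
        full[num.columns] = done
        datasets.append(full)
    return ImputationResult(datasets, mask, seed)


def pool_estimates(estimates, variances=None):
    """Combine per-dataset estimates by Rubin's rules.

    Returns ``(pooled, total_variance)`` where the pooled estimate is the
    mean over datasets and the total variance is
    ``W + (1 + 1/m) * B`` with ``W`` the mean within-imputation variance
    and ``B`` the between-imputation variance of the estimates.  With
    ``variances=None`` the within component is taken as zero.
    """
    est = np.asarray(estimates, dtype=float)
    if est.ndim == 1:
        est = est[:, None]
        squeeze = True
    else:
        squeeze = False
    m = est.shape[0]
    if m < 1:
        raise ValueError("need at least one estimate")
    if variances is None:
        var = np.zeros_like(est)
    else:
        var = np.asarray(variances, dtype=float)
        if var.ndim == 1:
            var = var[:, None]
        if var.shape != est.shape:
            raise ValueError("estimates and variances have mismatched shapes")
    pooled = est.mean(axis=0)
    w = var.mean(axis=0)
    b = est.var(axis=0, ddof=1) if m > 1 else np.zeros_like(pooled)
    total = w + (1 + 1 / m) * b
    if squeeze:
        return float(pooled[0]), float(total[0])
    return pooled, total
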
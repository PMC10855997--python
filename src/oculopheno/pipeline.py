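"""End-to-end pipeline: simulate -> extract -> derive -> impute -> EFA ->
LPA -> report.

One master seed drives every stage through deterministically spawned child
seeds; a run manifest records the configuration hash, stage seeds and
output digests so a rerun with the same manifest reproduces identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import warnings

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic import (EFA_INDICATORS, apply_mar_missingness,
                        make_default_config, simulate_cohort)
from .saccades import extract_participant_metrics
from .derived import adjust_latencies, snellen_to_logmar, zscore_metrics
from .impute import impute
from .efa import significant_loadings
from .lpa import (bic, blrt, classify, entropy, lpa_sweep, profile_report,
                  select_model)
from .posthoc import phenotype_comparisons, phenotype_prevalence

log = logging.getLogger("oculopheno")

DEFAULT_CONFIG = {
    "seed": 7,
    "n_patients": 140,
    "n_controls": 25,
    "simulate": {"traces": False, "mg_missing_fraction": 0.2},
    "impute": {"strategy": "impute", "m": 5, "iterations": 10},
    "efa": {"factors": [1, 6], "threshold": 0.4},
    "lpa": {"k_min": 1, "k_max": 6, "n_starts": 250, "n_final": 50,
            "blrt_boot": 0},
}

_REQUIRED_KEYS = ["seed", "n_patients", "n_controls"]


def load_config(path_or_dict) -> dict:
    """Load and validate a run configuration (YAML/JSON path or dict)."""
    if isinstance(path_or_dict, (str, pathlib.Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(path_or_dict)
    missing = [k for k in _REQUIRED_KEYS if k not in cfg]
    if missing:
        raise KeyError(f"config missing required key(s): {missing}")
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in cfg.items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    if merged["n_patients"] <= 0:
        raise ValueError("n_patients must be positive for a pipeline run")
    return merged


def _stage_seeds(master: int, stages=("simulate", "extract", "derive",
                                      "impute", "efa", "lpa", "report")):
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(stages))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(stages, children)}


def _digest(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config, outdir) -> dict:
    """Execute the full phenotyping pipeline; returns the run manifest.

    Stages: cohort simulation (optionally with trace synthesis and
    extraction), latency adjustment and z-scoring, multiple imputation,
    exploratory factor analysis of the ocular-motor indicators, the latent
    profile sweep with BIC/BLRT selection, and the post-hoc phenotype
    report.  All tables are CSV, all models JSON.
    """
    cfg = load_config(config)
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(int(cfg["seed"]))
    manifest: dict = {"config": cfg, "stage_seeds": seeds,
                      "version": __version__, "warnings": [], "outputs": {}}
    caught: list[str] = []

    def note_warnings(wlist):
        for w in wlist:
            caught.append(str(w.message))

    # ---- simulate --------------------------------------------------------
    log.info("stage simulate: n_patients=%s n_controls=%s",
             cfg["n_patients"], cfg["n_controls"])
    ccfg = make_default_config(cfg["n_patients"], cfg["n_controls"],
                               seed=seeds["simulate"])
    with_traces = bool(cfg["simulate"].get("traces", False))
    cohort = simulate_cohort(ccfg, include_traces=with_traces,
                             trace_participants=cfg["simulate"].get(
                                 "trace_participants"))
    metrics = cohort.metrics.copy()

    # ---- extract ---------------------------------------------------------
    if with_traces and cohort.traces:
        log.info("stage extract: scoring %d traced participants",
                 len(cohort.traces))
        for pid, traces in cohort.traces.items():
            measured = extract_participant_metrics(traces)
            for k, v in measured.items():
                metrics.loc[pid, k] = v

    frac = float(cfg["simulate"].get("mg_missing_fraction", 0.0))
    if frac > 0:
        metrics = apply_mar_missingness(metrics, frac, seed=seeds["simulate"])
    metrics.to_csv(outdir / "metrics.csv")
    cohort.labels.to_frame().to_csv(outdir / "labels.csv")

    # ---- derive ----------------------------------------------------------
    log.info("stage derive: latency adjustment and z-scoring")
    adjusted = adjust_latencies(metrics)
    adjusted["acuity_logmar"] = [
        snellen_to_logmar(a, b) for a, b in
        zip(adjusted["snellen_num"], adjusted["snellen_den"])]
    is_control = adjusted["group"] == "control"
    zscores = zscore_metrics(adjusted[~is_control], adjusted[is_control])
    zscores.to_csv(outdir / "zscores.csv")

    # ---- impute ----------------------------------------------------------
    strategy = cfg["impute"].get("strategy", "impute")
    if strategy == "impute" and zscores.isna().any().any():
        log.info("stage impute: m=%s chained-equation datasets",
                 cfg["impute"]["m"])
        result = impute(zscores, m=int(cfg["impute"]["m"]),
                        iterations=int(cfg["impute"]["iterations"]),
                        seed=seeds["impute"])
        datasets = result.datasets
        for i, d in enumerate(datasets):
            d.to_csv(outdir / f"imputed_{i}.csv")
    elif strategy == "pairwise":
        log.info("stage impute: pairwise/complete-case sensitivity path")
        datasets = [zscores.dropna()]
    else:
        datasets = [zscores]
    manifest["imputation"] = {"strategy": strategy, "m": len(datasets)}

    # ---- efa -------------------------------------------------------------
    log.info("stage efa: ML factor sweep on %d indicators",
             len(EFA_INDICATORS))
    f_lo, f_hi = cfg["efa"].get("factors", [1, 6])
    # pooled correlation structure: average of per-dataset correlations
    efa_cols = [c for c in EFA_INDICATORS if c in zscores.columns]
    corr = np.mean([np.corrcoef(d[efa_cols].dropna().to_numpy(),
                                rowvar=False) for d in datasets], axis=0)
    from .efa import fit_efa_from_corr, fit_indices as efa_fit_indices
    n_efa = int(np.mean([len(d[efa_cols].dropna()) for d in datasets]))
    sweep_rows = []
    best_efa = None
    with warnings.catch_warnings(record=True) as wl:
        warnings.simplefilter("always")
        for m in range(int(f_lo), int(f_hi) + 1):
            try:
                model = fit_efa_from_corr(corr, n_obs=n_efa, m=m,
                                          names=efa_cols)
            except ValueError:
                continue
            fi = efa_fit_indices(model, S=corr)
            sweep_rows.append({"m": m, "chi_square": fi.chi_square,
                               "df": fi.df, "p_value": fi.p_value,
                               "CFI": fi.cfi, "TLI": fi.tli,
                               "RMSEA": fi.rmsea, "SRMR": fi.srmr,
                               "heywood": model.heywood})
            if m == 3:
                best_efa = model
        if best_efa is None and sweep_rows:
            best_efa = fit_efa_from_corr(corr, n_obs=n_efa,
                                         m=sweep_rows[-1]["m"],
                                         names=efa_cols)
    note_warnings(wl)
    pd.DataFrame(sweep_rows).to_csv(outdir / "efa_sweep.csv", index=False)
    if best_efa is not None:
        best_efa.loadings.to_csv(outdir / "efa_loadings.csv")
        mapping, unloaded = significant_loadings(
            best_efa, threshold=float(cfg["efa"].get("threshold", 0.4)))
        with open(outdir / "efa_model.json", "w") as fh:
            json.dump({"m": best_efa.m, "F_min": best_efa.f_min,
                       "factor_correlations":
                           best_efa.factor_correlations.tolist(),
                       "significant_loadings": mapping,
                       "unloaded_indicators": unloaded,
                       "estimator": best_efa.estimator}, fh, indent=2)

    # ---- lpa -------------------------------------------------------------
    lcfg = cfg["lpa"]
    k_range = range(int(lcfg["k_min"]), int(lcfg["k_max"]) + 1)
    log.info("stage lpa: K sweep %s over %d imputed dataset(s)",
             list(k_range), len(datasets))
    per_dataset = []
    with warnings.catch_warnings(record=True) as wl:
        warnings.simplefilter("always")
        for d_i, d in enumerate(datasets):
            fits = lpa_sweep(d, k_range, n_starts=int(lcfg["n_starts"]),
                             n_final=int(lcfg["n_final"]),
                             seed=seeds["lpa"] + d_i)
            best, trace = select_model(fits)
            per_dataset.append((best, trace, d))
    note_warnings(wl)
    ks = [b.K for b, _, _ in per_dataset]
    modal_k = int(pd.Series(ks).mode().iloc[0])
    agree = [(b, t, d) for b, t, d in per_dataset if b.K == modal_k]
    best, trace, dsel = agree[0]
    manifest["lpa"] = {
        "per_dataset_k": ks, "modal_k": modal_k,
        "bic": bic(best), "entropy": entropy(best) if best.K > 1 else None,
        "ll_replications": best.ll_replications,
    }
    trace.to_csv(outdir / "lpa_selection.csv")

    # pooled means across datasets agreeing on modal K (Rubin numerator)
    pooled_means = np.mean([b.means for b, _, _ in agree], axis=0)
    diag = classify(best)
    assignments = pd.Series(diag["assignments"], index=dsel.index,
                            name="profile")
    assignments.to_frame().to_csv(outdir / "assignments.csv")
    with open(outdir / "lpa_model.json", "w") as fh:
        json.dump({"K": best.K, "weights": best.weights.tolist(),
                   "means": best.means.tolist(),
                   "pooled_means": pooled_means.tolist(),
                   "variances": np.asarray(best.variances).tolist(),
                   "columns": best.columns,
                   "log_likelihood": best.log_likelihood,
                   "BIC": bic(best),
                   "entropy": entropy(best) if best.K > 1 else None,
                   "avg_class_probability":
                       diag["avg_class_probability"].tolist(),
                   "estimator": "ML (non-robust)"}, fh, indent=2)

    if int(lcfg.get("blrt_boot", 0)) > 0 and modal_k >= 2:
        log.info("stage lpa: BLRT at K=%d with %s bootstraps",
                 modal_k, lcfg["blrt_boot"])
        res = blrt(dsel, modal_k, n_boot=int(lcfg["blrt_boot"]),
                   seed=seeds["lpa"])
        manifest["lpa"]["blrt_p"] = res["p_value"]
        manifest["lpa"]["blrt_statistic"] = res["statistic"]

    # ---- report ----------------------------------------------------------
    log.info("stage report: profile summaries and post-hoc comparisons")
    with warnings.catch_warnings(record=True) as wl:
        warnings.simplefilter("always")
        report = profile_report(best, dsel,
                                demographics=adjusted.loc[dsel.index])
    note_warnings(wl)
    report.to_csv(outdir / "profile_report.csv", index=False)
    prev = phenotype_prevalence(assignments)
    prev.to_frame("percent").to_csv(outdir / "prevalence.csv")
    posthoc = phenotype_comparisons(
        adjusted.loc[dsel.index], assignments,
        ["age", "SDMT", "BDI", "NART", "EDSS", "symptom_duration",
         "acuity_logmar"])
    posthoc.to_csv(outdir / "posthoc.csv", index=False)

    manifest["warnings"] = caught
    cfg_blob = json.dumps(cfg, sort_keys=True).encode()
    manifest["config_hash"] = hashlib.sha256(cfg_blob).hexdigest()[:16]
    for f in sorted(outdir.glob("*.csv")) + sorted(outdir.glob("*.json")):
        if f.name != "manifest.json":
            manifest["outputs"][f.name] = _digest(f)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("pipeline complete: %s", outdir)
    return manifest
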
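"""Planted-truth recovery experiments and statistical calibration checks.

These drive the package end to end on synthetic studies and score each stage
against the generator's ledger; they are what the acceptance script and the
recovery tests run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .binding import call_peaks_simple, call_induced_binding, windows_table
from .classify import build_records
from .expression import DEFAULT_CONTRASTS, de_table
from .simulate import (
    SimulationConfig,
    build_truth,
    score_binding_recovery,
    score_de_recovery,
    score_mode_recovery,
    simulate_binding,
    simulate_expression,
)

RECOVERY_CONTRASTS = ("tnf_vs_ctr", "hs_vs_ctr", "hstnf_vs_tnf")


def recovery_experiment(
    n_genes: int = 5000,
    seeds=range(10),
    effect_log2fc: float = 2.0,
    noise_sd: float = 0.25,
    n_replicates: int = 3,
) -> dict:
    """Seed-averaged recovery of planted DE calls, combined-effect modes and
    induced HSF1 binding at the study's default conditions."""
    de_sens, de_fdr, mode_acc, bind_sens = [], [], [], []
    for seed in seeds:
        cfg = SimulationConfig(
            n_genes=n_genes,
            effect_log2fc=effect_log2fc,
            noise_sd=noise_sd,
            n_replicates_per_condition=n_replicates,
            rng_seed=int(seed),
        )
        truth = build_truth(cfg)
        expr = simulate_expression(cfg, truth)
        tables = {
            c.name: de_table(expr, c)
            for c in DEFAULT_CONTRASTS
            if c.name in RECOVERY_CONTRASTS
        }
        de_score = score_de_recovery(tables, truth)
        records = build_records(
            tables["tnf_vs_ctr"], tables["hs_vs_ctr"], tables["hstnf_vs_tnf"]
        )
        mode_score = score_mode_recovery(records, truth)
        annotation = truth.genes[["gene_id", "chrom", "tss", "strand"]]
        peaks = simulate_binding(cfg, truth, annotation)
        calls = call_induced_binding(peaks, windows_table(annotation))
        bind_score = score_binding_recovery(calls, truth)
        de_sens.append(de_score["sensitivity"])
        de_fdr.append(de_score["fdr"])
        mode_acc.append(mode_score["accuracy"])
        bind_sens.append(bind_score["sensitivity"])
    return {
        "de_sensitivity": float(np.mean(de_sens)),
        "de_fdr": float(np.mean(de_fdr)),
        "mode_accuracy": float(np.mean(mode_acc)),
        "binding_sensitivity": float(np.mean(bind_sens)),
        "n_seeds": len(de_sens),
        "n_genes": n_genes,
    }


def type_one_error_rate(n_genes: int = 2000, seed: int = 0, alpha: float = 0.05) -> dict:
    """Empirical type-I rate of the moderated test on pure-noise data."""
    from .expression import Contrast, ExpressionMatrix, fit_moderation, moderated_test

    rng = np.random.default_rng(seed)
    cols, cmap = {}, {}
    base = rng.normal(8.0, 1.0, size=n_genes)
    for cond in ("Ctr", "TNF"):
        for r in range(1, 4):
            name = f"{cond}_{r}"
            cols[name] = base + rng.normal(0.0, 0.25, size=n_genes)
            cmap[name] = cond
    matrix = ExpressionMatrix(
        pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)]), cmap
    )
    contrast = Contrast("tnf_vs_ctr", "TNF", "Ctr")
    params = fit_moderation(matrix, contrast)
    res = moderated_test(matrix, contrast, params)
    return {"rate": float((res["p"] < alpha).mean()), "alpha": alpha, "n_genes": n_genes}


def peak_caller_null_fp_fraction(
    n_seeds: int = 50, n_bins: int = 400, lam: float = 10.0, fdr: float = 0.05, seed0: int = 0
) -> dict:
    """Mean fraction of falsely significant bins when track and reference are
    i.i.d. Poisson with the same rate."""
    rates = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed0 + s)
        grid = pd.DataFrame({"chrom": "c", "start": np.arange(n_bins) * 100})
        obs = grid.assign(count=rng.poisson(lam, size=n_bins))
        ref = grid.assign(count=rng.poisson(lam, size=n_bins))
        peaks = call_peaks_simple(obs, ref, fdr=fdr)
        sig = int(sum((p.end - p.start) // 100 for p in peaks.itertuples(index=False)))
        rates.append(sig / n_bins)
    return {"fraction": float(np.mean(rates)), "fdr": fdr, "n_seeds": n_seeds}
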
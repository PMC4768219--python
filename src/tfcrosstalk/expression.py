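"""Per-gene differential-expression statistics for the four-condition design.

The design crosses TNFα stimulation with heat-shock (HS) pre-treatment:
conditions ``Ctr``, ``TNF``, ``HS`` and ``HS_TNF`` (1 h HS followed by TNFα).
Differential expression per contrast is called with the ratio + FDR rule
(linear signal ratio > 1.2 or < 0.8 and q < 0.05) on top of an empirical-Bayes
moderated t statistic: per-gene sample variances are shrunk towards a prior
variance s0² with prior degrees of freedom d0, both estimated from the data by
moment matching on the log variances.  d0 = 0 reduces to the ordinary pooled
two-sample t; d0 = ∞ means every gene shares s0².
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, special, stats

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    InputError,
    InsufficientReplicationError,
)

CONDITIONS = ("Ctr", "TNF", "HS", "HS_TNF")

#: Linear up-ratio, down-ratio and FDR level for a DE call.
DEFAULT_THRESHOLDS = (1.2, 0.8, 0.05)


@dataclass(frozen=True)
class Contrast:
    """A treated-vs-reference comparison between two conditions."""

    name: str
    treated: str
    reference: str

    def __post_init__(self):
        if self.treated == self.reference:
            raise ConfigurationError(
                f"contrast {self.name!r}: treated and reference conditions are equal"
            )


#: TNF-vs-Ctr = "TNF-modulated"; HS_TNF-vs-TNF = "affected by HS pre-treatment";
#: HS_TNF-vs-HS is the reverse analysis (effect of TNFα on HS-modulated genes).
DEFAULT_CONTRASTS = (
    Contrast("tnf_vs_ctr", "TNF", "Ctr"),
    Contrast("hs_vs_ctr", "HS", "Ctr"),
    Contrast("hstnf_vs_tnf", "HS_TNF", "TNF"),
    Contrast("hstnf_vs_hs", "HS_TNF", "HS"),
)


class ExpressionMatrix:
    """Log2 expression values (genes × samples) plus a sample→condition map."""

    def __init__(self, values: pd.DataFrame, condition_map: Mapping[str, str]):
        values = pd.DataFrame(values)
        cond = pd.Series(dict(condition_map), dtype=object)
        if values.index.duplicated().any():
            raise InputError("duplicate gene ids in expression matrix")
        if values.isna().any().any():
            raise InputError("expression matrix contains missing values")
        missing = [s for s in values.columns if s not in cond.index]
        if missing:
            raise InputError(f"samples without condition assignment: {missing}")
        cond = cond.loc[values.columns]
        counts = cond.value_counts()
        short = counts[counts < 2]
        if not short.empty:
            raise InputError(
                f"every condition needs >=2 samples; offending: {dict(short)}"
            )
        self.values = values.astype(float)
        self.condition_map = cond

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def conditions(self) -> list:
        return sorted(self.condition_map.unique())

    def samples_for(self, condition: str) -> list:
        sel = self.condition_map[self.condition_map == condition]
        if sel.empty:
            raise InputError(f"condition {condition!r} not present in sample map")
        return list(sel.index)

    def condition_values(self, condition: str) -> np.ndarray:
        return self.values[self.samples_for(condition)].to_numpy()

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_tsv(cls, expression_path, sample_map_path) -> "ExpressionMatrix":
        values = pd.read_csv(expression_path, sep="\t", index_col=0)
        smap = pd.read_csv(sample_map_path, sep="\t")
        if not {"sample_id", "condition"}.issubset(smap.columns):
            raise InputError("sample map needs columns sample_id, condition")
        return cls(values, dict(zip(smap["sample_id"], smap["condition"])))

    def to_tsv(self, expression_path, sample_map_path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(expression_path, sep="\t", float_format="%.6f")
        pd.DataFrame(
            {"sample_id": self.condition_map.index, "condition": self.condition_map.values}
        ).to_csv(sample_map_path, sep="\t", index=False)


@dataclass(frozen=True)
class ModerationParams:
    """Scaled inverse-chi-square prior on per-gene variances.

    ``prior_df`` (d0) may be 0 (no moderation), finite, or ``math.inf``
    (complete pooling: every gene is assigned ``prior_variance``).
    """

    prior_df: float
    prior_variance: float

    def __post_init__(self):
        if self.prior_df < 0:
            raise ConfigurationError("prior_df must be >= 0")
        if not self.prior_variance > 0:
            raise ConfigurationError("prior_variance must be > 0")


# --------------------------------------------------------------------------
# Ratios and group summaries
# --------------------------------------------------------------------------

def linear_ratio(matrix: ExpressionMatrix, contrast: Contrast, gene=None):
    """Linear fold change 2^(mean log2 treated − mean log2 reference).

    Returns a per-gene Series, or a float when ``gene`` is given.
    """
    mt = matrix.condition_values(contrast.treated).mean(axis=1)
    mr = matrix.condition_values(contrast.reference).mean(axis=1)
    ratio = pd.Series(np.exp2(mt - mr), index=matrix.genes, name="ratio")
    if gene is not None:
        if gene not in ratio.index:
            raise InputError(f"gene {gene!r} not in matrix")
        return float(ratio.loc[gene])
    return ratio


def _group_stats(matrix: ExpressionMatrix, contrast: Contrast):
    """Per-gene Δmean, pooled variance, residual df and group sizes."""
    a = matrix.condition_values(contrast.treated)
    b = matrix.condition_values(contrast.reference)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 + n2 < 3:
        raise InsufficientReplicationError(
            f"contrast {contrast.name!r}: need n1+n2 >= 3 samples, got {n1 + n2}"
        )
    delta = a.mean(axis=1) - b.mean(axis=1)
    rss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = n1 + n2 - 2
    s2 = rss / df
    return delta, s2, df, n1, n2


# --------------------------------------------------------------------------
# Empirical-Bayes moderation
# --------------------------------------------------------------------------

def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    # trigamma(x) ~ 1/x for large x, ~ 1/x^2 for small x
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        f = special.polygamma(1, x) - y
        fp = special.polygamma(2, x)
        step = f / fp
        x -= step
        if x <= 0:
            x = 1e-8
        if abs(step) < tol * x:
            break
    return float(x)


def fit_moderation(matrix: ExpressionMatrix, contrast: Contrast) -> ModerationParams:
    """Estimate (d0, s0²) by moment matching on the log sample variances.

    With s_g² ~ s0² · (χ²_d/d) · (d0/χ²_{d0}) the log variances satisfy
    Var(log s²) = ψ′(d/2) + ψ′(d0/2); the excess dispersion of log s² beyond
    the sampling term ψ′(d/2) identifies d0, and the mean identifies s0².
    Falls back to d0 = ∞ (shared variance) when there is no excess dispersion.
    """
    _, s2, df, _, _ = _group_stats(matrix, contrast)
    if len(s2) < 10:
        raise DegenerateDataError("need >= 10 genes to fit moderation")
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise DegenerateDataError("all per-gene variances are zero")
    e = np.log(pos)
    mean_e = float(e.mean())
    var_e = float(e.var(ddof=1)) if e.size > 1 else 0.0
    excess = var_e - float(special.polygamma(1, df / 2.0))
    if excess <= 1e-8:
        # no dispersion beyond sampling noise: one shared variance, estimated
        # unbiasedly by the plain mean (equal variances v give exactly v)
        return ModerationParams(prior_df=math.inf, prior_variance=float(pos.mean()))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        log_s0 = (
            mean_e
            - float(special.digamma(df / 2.0))
            + math.log(df / 2.0)
            + float(special.digamma(d0 / 2.0))
            - math.log(d0 / 2.0)
        )
    return ModerationParams(prior_df=d0, prior_variance=float(np.exp(log_s0)))


def moderated_test(
    matrix: ExpressionMatrix, contrast: Contrast, params: ModerationParams
) -> pd.DataFrame:
    """Moderated two-sample t test per gene.

    Posterior variance ŝ² = (d0·s0² + d_g·s_g²) / (d0 + d_g);
    t = Δmean / (ŝ · sqrt(1/n1 + 1/n2)), two-sided p from Student t with
    d0 + d_g degrees of freedom.  Genes with ŝ = 0 get p = 0 when Δmean ≠ 0
    and p = 1 otherwise (the zero-noise limit).
    """
    delta, s2, df, n1, n2 = _group_stats(matrix, contrast)
    d0, s02 = params.prior_df, params.prior_variance
    if math.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / np.where(se > 0, se, 1.0), np.where(delta != 0, np.inf * np.sign(delta), 0.0))
    p = np.where(
        np.isfinite(t),
        2.0 * stats.t.sf(np.abs(t), df_total) if np.isfinite(df_total) else 2.0 * stats.norm.sf(np.abs(t)),
        0.0,
    )
    p = np.where((se == 0) & (delta == 0), 1.0, p)
    return pd.DataFrame({"t": t, "df": df_total, "p": p}, index=matrix.genes)


# --------------------------------------------------------------------------
# FDR / q-values
# --------------------------------------------------------------------------

def _estimate_pi0(p: np.ndarray) -> float:
    """Storey's π0 via the λ-grid smoother, clipped to (0, 1]."""
    lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    try:
        spline = interpolate.UnivariateSpline(lambdas, pi0_l, k=3)
        pi0 = float(spline(lambdas[-1]))
    except Exception:
        pi0 = float(pi0_l[-1])
    if not np.isfinite(pi0) or pi0 <= 0:
        return 1.0
    return min(pi0, 1.0)


def estimate_qvalues(p_values: Sequence[float], method: str = "storey") -> np.ndarray:
    """q-values from p-values by the step-up rule with π0 scaling.

    ``method='bh'`` fixes π0 = 1 (Benjamini–Hochberg); ``method='storey'``
    estimates π0 from the λ-grid smoother and falls back to π0 = 1 when the
    estimate is unstable.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    if method == "bh":
        pi0 = 1.0
    elif method == "storey":
        pi0 = _estimate_pi0(p) if p.size >= 20 else 1.0
    else:
        raise ConfigurationError(f"unknown FDR method {method!r}")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


# --------------------------------------------------------------------------
# Calls
# --------------------------------------------------------------------------

def call_de(ratio, q, thresholds=DEFAULT_THRESHOLDS):
    """Apply the ratio + FDR rule: up iff ratio > up_thr and q < fdr;
    down iff ratio < down_thr and q < fdr; otherwise none.  Thresholds are
    strict inequalities.  Accepts scalars or aligned arrays."""
    up_thr, down_thr, fdr = thresholds
    if not (0 < down_thr < up_thr):
        raise ConfigurationError("need 0 < down_threshold < up_threshold")
    if not (0 < fdr <= 1):
        raise ConfigurationError("fdr level must lie in (0, 1]")
    r = np.asarray(ratio, dtype=float)
    qq = np.asarray(q, dtype=float)
    if np.any(r <= 0):
        raise InputError("ratios must be positive")
    call = np.where(
        (r > up_thr) & (qq < fdr), "up", np.where((r < down_thr) & (qq < fdr), "down", "none")
    )
    if call.ndim == 0:
        return str(call)
    return call


def de_table(
    matrix: ExpressionMatrix,
    contrast: Contrast,
    params: ModerationParams | None = None,
    fdr_method: str = "storey",
    thresholds=DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Full per-gene DE table for one contrast: ratio, t, p, q, call.

    ``params=None`` fits the moderation prior from this contrast's data;
    when every gene has zero residual variance (noise-free input) the test
    degenerates gracefully to d0 = 0 with p ∈ {0, 1} decided by Δmean.
    """
    try:
        if params is None:
            params = fit_moderation(matrix, contrast)
    except DegenerateDataError:
        params = ModerationParams(prior_df=0.0, prior_variance=1.0)
        # d0=0 keeps per-gene (zero) variances; moderated_test handles se=0.
    ratio = linear_ratio(matrix, contrast)
    test = moderated_test(matrix, contrast, params)
    q = estimate_qvalues(test["p"].to_numpy(), method=fdr_method)
    call = call_de(ratio.to_numpy(), q, thresholds)
    return pd.DataFrame(
        {
            "ratio": ratio.to_numpy(),
            "t": test["t"].to_numpy(),
            "p": test["p"].to_numpy(),
            "q": q,
            "call": call,
        },
        index=matrix.genes,
    )
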
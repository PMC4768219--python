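"""Hypergeometric overrepresentation of annotation terms in a gene subset.

Terms are flat labels (no ontology DAG propagation).  The background universe
is supplied explicitly — typically all genes with detected transcripts — and
the subset must be contained in it.  The upper-tail p-value is computed in
log space from log binomial coefficients for numerical stability.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import ConfigurationError, InputError


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P[X ≥ k] for X ~ Hypergeometric(N population, K marked, n drawn).

    k successes in a subset of size n, K background genes with the term,
    N background genes in total.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise InputError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    upper = min(n, K)
    if k > upper:
        return 0.0
    i = np.arange(k, upper + 1)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def enrich(
    subset: Iterable[str],
    background: Iterable[str],
    annotations: pd.DataFrame | Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    adjust: str = "none",
    term_labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Term overrepresentation of ``subset`` against ``background``.

    ``annotations`` maps genes to term sets (dict) or is a table with
    gene_id/term_id columns.  Annotated genes outside the background are
    ignored.  One row per term with K ≥ 1 in the background, sorted by p;
    ``significant`` flags (adjusted) p < alpha.
    """
    if not 0 < alpha <= 1:
        raise ConfigurationError("alpha must lie in (0, 1]")
    if adjust not in ("none", "bh"):
        raise ConfigurationError("adjust must be 'none' or 'bh'")
    subset = set(subset)
    background = set(background)
    stray = subset - background
    if stray:
        raise InputError(f"subset genes outside background: {sorted(stray)[:5]} ...")
    if isinstance(annotations, pd.DataFrame):
        if not {"gene_id", "term_id"}.issubset(annotations.columns):
            raise InputError("annotation table needs gene_id and term_id columns")
        gene2terms: dict[str, set] = {}
        for g, t in zip(annotations["gene_id"], annotations["term_id"]):
            gene2terms.setdefault(g, set()).add(t)
        if term_labels is None and "term_label" in annotations.columns:
            term_labels = dict(zip(annotations["term_id"], annotations["term_label"]))
    else:
        gene2terms = {g: set(ts) for g, ts in annotations.items()}
    term2background: dict[str, int] = {}
    term2subset: dict[str, int] = {}
    for gene, terms in gene2terms.items():
        if gene not in background:
            continue
        in_subset = gene in subset
        for term in terms:
            term2background[term] = term2background.get(term, 0) + 1
            if in_subset:
                term2subset[term] = term2subset.get(term, 0) + 1
    N, n = len(background), len(subset)
    rows = []
    for term in sorted(term2background):
        K = term2background[term]
        k = term2subset.get(term, 0)
        rows.append((term, k, n, K, N, hypergeom_tail(k, n, K, N)))
    out = pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "p"])
    if out.empty:
        out["p_adj"] = out["significant"] = []
        return out
    out["p_adj"] = _bh_adjust(out["p"].to_numpy()) if adjust == "bh" else out["p"]
    out["significant"] = out["p_adj" if adjust == "bh" else "p"] < alpha
    if term_labels:
        out.insert(1, "term_label", out["term_id"].map(term_labels).fillna(""))
    return out.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
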
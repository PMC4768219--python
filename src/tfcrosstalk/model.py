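"""Top-level modelling interface: :class:`CrosstalkModel` and its results.

The model is built from the study's data layers (expression matrix with its
condition map, gene annotation, promoter sequences, PWMs, per-condition HSF1
peak sets, optional term annotation).  ``fit()`` runs differential expression
for the default contrasts, scans promoters, assigns peaks and calls induced
binding, classifies the combined-effect mode of every TNF-modulated gene, and
tallies the figure-style subset counts; the returned
:class:`CrosstalkResults` carries all stage tables and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import binding as binding_mod
from . import classify as classify_mod
from . import enrich as enrich_mod
from . import motifs as motif_mod
from .errors import ConfigurationError, InputError
from .expression import (
    DEFAULT_CONTRASTS,
    DEFAULT_THRESHOLDS,
    ExpressionMatrix,
    de_table,
)
from .reports import rounded_percentage, write_json, write_tsv


@dataclass
class FitOptions:
    thresholds: tuple = DEFAULT_THRESHOLDS
    fdr_method: str = "storey"
    motif_rel_threshold: float = motif_mod.DEFAULT_REL_THRESHOLD
    window_upstream: int = binding_mod.UPSTREAM_BP
    window_downstream: int = binding_mod.DOWNSTREAM_BP
    binding_fdr: float = 0.05
    binding_score_ratio: float = binding_mod.DEFAULT_SCORE_RATIO
    enrichment_alpha: float = 0.05
    enrichment_adjust: str = "none"

    def validate(self) -> None:
        up, down, fdr = self.thresholds
        if not (0 < down < up):
            raise ConfigurationError("thresholds must satisfy 0 < down < up")
        for name, value in (("fdr", fdr), ("binding_fdr", self.binding_fdr),
                            ("enrichment_alpha", self.enrichment_alpha)):
            if not 0 < value <= 1:
                raise ConfigurationError(f"{name} must lie in (0, 1], got {value}")
        if not 0 < self.motif_rel_threshold <= 1:
            raise ConfigurationError("motif_rel_threshold must lie in (0, 1]")
        if self.window_upstream < 0 or self.window_downstream < 0:
            raise ConfigurationError("window extents must be >= 0")
        if self.fdr_method not in ("storey", "bh"):
            raise ConfigurationError("fdr_method must be 'storey' or 'bh'")


class CrosstalkModel:
    """Integrative cross-talk analysis of a four-condition stimulus study."""

    def __init__(
        self,
        expression: ExpressionMatrix,
        annotation: pd.DataFrame | None = None,
        promoters: Mapping[str, str] | None = None,
        pwms: Mapping[str, motif_mod.PWM] | None = None,
        peaks: Mapping[str, pd.DataFrame] | None = None,
        terms: pd.DataFrame | None = None,
    ):
        self.expression = expression
        self.annotation = annotation
        self.promoters = dict(promoters) if promoters is not None else None
        self.pwms = dict(pwms) if pwms else None
        self.peaks = dict(peaks) if peaks is not None else None
        self.terms = terms
        if self.peaks is not None and annotation is None:
            raise InputError("peak analysis needs a gene annotation")

    @classmethod
    def from_files(
        cls,
        expression_path,
        sample_map_path,
        annotation_path=None,
        promoters_path=None,
        pwm_path=None,
        peak_paths: Mapping[str, str] | None = None,
        terms_path=None,
    ) -> "CrosstalkModel":
        from .io import read_annotation, read_terms

        expr = ExpressionMatrix.from_tsv(expression_path, sample_map_path)
        annotation = read_annotation(annotation_path) if annotation_path else None
        promoters = motif_mod.read_promoters(promoters_path) if promoters_path else None
        pwms = None
        if pwm_path:
            pwms = {p.name: p for p in motif_mod.read_jaspar(pwm_path)}
        elif promoters is not None:
            pwms = {"kb": motif_mod.kb_pwm(), "hse": motif_mod.build_hse_pwm(3)}
        peaks = (
            {cond: binding_mod.read_bed(path) for cond, path in peak_paths.items()}
            if peak_paths
            else None
        )
        terms = read_terms(terms_path) if terms_path else None
        return cls(expr, annotation, promoters, pwms, peaks, terms)

    # ------------------------------------------------------------------ fit
    def fit(self, options: FitOptions | None = None) -> "CrosstalkResults":
        opts = options or FitOptions()
        opts.validate()
        de = {
            c.name: de_table(
                self.expression, c, fdr_method=opts.fdr_method, thresholds=opts.thresholds
            )
            for c in DEFAULT_CONTRASTS
        }
        motif_flags = hit_table = None
        if self.promoters is not None:
            pwms = self.pwms or {"kb": motif_mod.kb_pwm(), "hse": motif_mod.build_hse_pwm(3)}
            motif_flags, hit_table = motif_mod.motif_presence(
                self.promoters, pwms.values(), opts.motif_rel_threshold, return_hits=True
            )
            rename = {}
            for name in motif_flags.columns:
                low = name.lower()
                rename[name] = "kb" if "kb" in low else ("hse" if "hse" in low else name)
            motif_flags = motif_flags.rename(columns=rename)
        windows = binding_calls = None
        if self.peaks is not None:
            windows = binding_mod.windows_table(
                self.annotation, opts.window_upstream, opts.window_downstream
            )
            binding_calls = binding_mod.call_induced_binding(
                self.peaks,
                windows,
                fdr=opts.binding_fdr,
                score_ratio=opts.binding_score_ratio,
            )
        records = classify_mod.build_records(
            de["tnf_vs_ctr"],
            de["hs_vs_ctr"],
            de["hstnf_vs_tnf"],
            motif_flags=motif_flags,
            binding=binding_calls,
            thresholds=opts.thresholds,
        )
        tally = classify_mod.tally_subsets(records)
        enrichment = None
        if self.terms is not None:
            enrichment = self._enrich_subsets(records, opts)
        return CrosstalkResults(
            model=self,
            options=opts,
            de=de,
            motif_flags=motif_flags,
            motif_hits=hit_table,
            windows=windows,
            binding=binding_calls,
            records=records,
            tally=tally,
            enrichment=enrichment,
        )

    def _enrich_subsets(self, records: pd.DataFrame, opts: FitOptions):
        universe = set(records.index)
        tnf_mod = set(records.index[records["call_tnf"] != "none"])
        subsets = {
            "tnf_modulated_vs_universe": (tnf_mod, universe),
            "antagonized_vs_tnf_modulated": (
                set(records.index[records["mode"] == "suppressed_activation"]),
                tnf_mod,
            ),
            "up_both_vs_tnf_modulated": (
                set(records.index[(records["call_tnf"] == "up") & (records["call_hs"] == "up")]),
                tnf_mod,
            ),
        }
        out = {}
        for name, (subset, bg) in subsets.items():
            if not subset or not bg:
                continue
            out[name] = enrich_mod.enrich(
                subset, bg, self.terms, alpha=opts.enrichment_alpha, adjust=opts.enrichment_adjust
            )
        return out


@dataclass
class CrosstalkResults:
    """Fitted stage tables, subset tallies and reports."""

    model: CrosstalkModel
    options: FitOptions
    de: dict
    motif_flags: pd.DataFrame | None
    motif_hits: pd.DataFrame | None
    windows: pd.DataFrame | None
    binding: pd.DataFrame | None
    records: pd.DataFrame
    tally: classify_mod.SubsetTally
    enrichment: dict | None = None

    def table1_report(self) -> pd.DataFrame:
        return classify_mod.table1_report(self.records)

    def percentages(self) -> dict:
        """Printed-style percentages of the headline subset counts."""
        t = self.tally
        out = {}
        if t.n_genes:
            out["pct_tnf_modulated"] = rounded_percentage(t.tnf_modulated, t.n_genes)
            out["pct_hs_modulated"] = rounded_percentage(t.hs_modulated, t.n_genes)
        if t.tnf_modulated:
            out["pct_tnf_coaffected"] = rounded_percentage(t.co_affected, t.tnf_modulated)
            for mode, count in t.mode_counts.items():
                if mode != "unaffected":
                    out[f"pct_tnf_{mode}"] = rounded_percentage(count, t.tnf_modulated)
        return out

    def summary(self) -> str:
        t = self.tally
        lines = [
            "Cross-talk analysis summary",
            "===========================",
            f"genes analysed:            {t.n_genes}",
            f"TNF-modulated:             {t.tnf_modulated} (up {t.tnf_up} / down {t.tnf_down})",
            f"HS-modulated:              {t.hs_modulated} (up {t.hs_up} / down {t.hs_down})",
            f"modulated by both:         {t.overlap} (up both {t.up_both} / down both {t.down_both})",
            f"affected by HS pre-treat.: {t.co_affected} of {t.tnf_modulated} TNF-modulated",
            "combined-effect modes (of TNF-modulated):",
        ]
        for mode in classify_mod.MODES:
            lines.append(f"  {mode:<24} {t.mode_counts.get(mode, 0)}")
        lines += [
            f"co-activated (also HS-up): {t.coactivated}",
            f"co-repressed (also HS-dn): {t.corepressed}",
        ]
        if self.motif_flags is not None:
            lines += [
                f"TNF-modulated with kB motif:   {t.tnf_with_kb}",
                f"TNF-modulated with HSE motif:  {t.tnf_with_hse}",
            ]
        if self.binding is not None:
            lines += [
                f"TNF-modulated with HSF1 induction: {t.tnf_with_hsf1}",
                f"TNF-up with kB motif and HSF1:     {t.tnf_up_kb_hsf1}",
            ]
        return "\n".join(lines)

    def save(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, table in self.de.items():
            p = outdir / f"de_{name}.tsv"
            out = table.copy()
            out.index.name = "gene_id"
            write_tsv(out.reset_index(), p)
            paths[f"de_{name}"] = p
        rec = self.records.reset_index()
        write_tsv(rec, outdir / "records.tsv")
        paths["records"] = outdir / "records.tsv"
        write_json(self.tally.to_dict(), outdir / "tally.json")
        paths["tally"] = outdir / "tally.json"
        report = self.table1_report().reset_index()
        write_tsv(report, outdir / "table1_style_report.tsv")
        paths["table1"] = outdir / "table1_style_report.tsv"
        if self.motif_flags is not None:
            write_tsv(self.motif_flags.reset_index(), outdir / "motif_flags.tsv")
            write_tsv(self.motif_hits, outdir / "motif_hits.tsv")
            paths["motif_flags"] = outdir / "motif_flags.tsv"
        if self.binding is not None:
            write_tsv(self.binding, outdir / "binding_calls.tsv")
            paths["binding"] = outdir / "binding_calls.tsv"
        if self.enrichment:
            for name, table in self.enrichment.items():
                p = outdir / f"enrichment_{name}.tsv"
                write_tsv(table, p)
                paths[f"enrichment_{name}"] = p
        with open(outdir / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")
        paths["summary"] = outdir / "summary.txt"
        return paths
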